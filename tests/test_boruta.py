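import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestRegressor

from pcmaffinity import boruta_select as bs
from pcmaffinity.data_model import AffinityType
from pcmaffinity.featureset import FeatureTable
from pcmaffinity.synth import planted_selection_benchmark

FAST_FOREST = {"n_estimators": 60, "max_features": "sqrt"}


def small_signal(n=300, p=5, seed=0):
    rng = np.random.RandomState(seed)
    X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"f{i}" for i in range(p)])
    y = 2.0 * X["f0"].to_numpy() + 0.1 * rng.normal(size=n)
    return X, y


class TestShadowExtend:
    def test_doubles_columns_and_preserves_values(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("abcde"))
        sm = bs.shadow_extend(X, seed=1)
        assert sm.combined.shape[1] == 10
        for col in X.columns:
            assert sorted(sm.shadow["shadow__" + col]) == sorted(X[col])

    def test_seeded_reproducibility(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        a = bs.shadow_extend(X, seed=7).shadow
        b = bs.shadow_extend(X, seed=7).shadow
        assert a.equals(b)

    def test_column_order_invariant(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        a = bs.shadow_extend(X, seed=7).shadow
        b = bs.shadow_extend(X[["c", "a", "b"]], seed=7).shadow
        for col in a.columns:
            assert np.array_equal(a[col], b[col])

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            bs.shadow_extend(pd.DataFrame({"a": [1.0]}), seed=0)


class TestOOBImportance:
    def test_identity_permutation_gives_exact_zero(self):
        X, y = small_signal()
        scores = bs.oob_importance(
            X, y, forest=FAST_FOREST, seed=0,
            permutation_factory=lambda rng, n: np.arange(n))
        assert (scores == 0.0).all()

    def test_duplicated_response_attains_maximum(self):
        X, y = small_signal()
        X = X.copy()
        X["leak"] = y
        scores = bs.oob_importance(X, y, forest=FAST_FOREST, seed=0)
        assert scores.idxmax() == "leak"

    def test_pure_noise_score_near_zero(self):
        rng = np.random.RandomState(1)
        X = pd.DataFrame(rng.normal(size=(500, 4)), columns=list("abcd"))
        y = 3.0 * X["a"].to_numpy() + 0.1 * rng.normal(size=500)
        scores = bs.oob_importance(X, y, forest=FAST_FOREST, seed=1)
        for col in "bcd":
            assert abs(scores[col]) < 0.05
        assert scores["a"] > 0.5

    def test_oob_reconstruction_matches_sklearn(self):
        """The replayed bootstrap draws must reproduce sklearn's own OOB R^2."""
        X, y = small_signal(seed=3)
        forest = RandomForestRegressor(
            n_estimators=100, oob_score=True, random_state=3).fit(X.to_numpy(), y)
        masks = bs._inbag_oob_masks(forest, len(X))
        preds = np.zeros(len(X))
        counts = np.zeros(len(X))
        leaves = forest.apply(X.to_numpy())
        for t, tree in enumerate(forest.estimators_):
            oob = masks[t]
            preds[oob] += bs._leaf_values(tree)[leaves[oob, t]]
            counts[oob] += 1
        mask = counts > 0
        recon = bs._r2(y[mask], preds[mask] / counts[mask])
        assert recon == pytest.approx(forest.oob_score_, abs=1e-12)


class TestBorutaRun:
    def test_planted_benchmark_recovery(self):
        X, y, informative = planted_selection_benchmark(seed=11)
        res = bs.boruta_run(X, y, seed=11)
        confirmed = set(res.confirmed)
        assert set(informative) <= confirmed
        false_confirmed = confirmed - set(informative)
        assert len(false_confirmed) <= 5
        rejected = res.by_status(bs.Status.Rejected)
        assert len(rejected) >= 90

    def test_duplicated_response_confirmed(self):
        X, y = small_signal()
        X = X.copy()
        X["leak"] = y
        res = bs.boruta_run(X, y, forest=FAST_FOREST, seed=0)
        assert "leak" in res.confirmed

    def test_all_noise_confirms_almost_nothing(self):
        """With no signal at all, selection should confirm no feature in the
        vast majority of runs (an occasional single spurious confirmation is
        within the method's false-positive behaviour)."""
        rng = np.random.RandomState(5)
        n_confirmed = []
        for seed in range(3):
            X = pd.DataFrame(rng.normal(size=(400, 100)),
                             columns=[f"n{i}" for i in range(100)])
            y = rng.normal(size=400)
            res = bs.boruta_run(X, y, forest=FAST_FOREST, seed=seed)
            n_confirmed.append(len(res.confirmed))
        assert sum(n_confirmed) <= 1

    def test_column_reorder_keeps_signal_confirmed(self):
        X, y = small_signal(p=8)
        res_a = bs.boruta_run(X, y, forest=FAST_FOREST, seed=2)
        res_b = bs.boruta_run(X[list(reversed(X.columns))], y,
                              forest=FAST_FOREST, seed=2)
        assert "f0" in res_a.confirmed and "f0" in res_b.confirmed

    def test_constant_response_rejected(self):
        X, _ = small_signal(n=50)
        with pytest.raises(ValueError, match="constant"):
            bs.boruta_run(X, np.ones(50), seed=0)

    def test_nonfinite_features_rejected(self):
        X, y = small_signal(n=50)
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            bs.boruta_run(X, y, seed=0)

    def test_binomial_variant_confirms_signal(self):
        X, y = small_signal(p=6)
        res = bs.boruta_run(X, y, forest=FAST_FOREST, seed=4, variant="binomial")
        assert "f0" in res.confirmed


class TestFinalizeSubset:
    def table(self, X, y):
        X = X.copy()
        X.index = pd.MultiIndex.from_arrays(
            [[f"L{i}" for i in range(len(X))], ["T0"] * len(X)],
            names=["ligand_id", "target_id"])
        return FeatureTable(X=X, y=pd.Series(y, index=X.index),
                            origins={c: "mol" for c in X.columns},
                            affinity_type=AffinityType.Kd)

    def test_keeps_only_confirmed(self):
        X, y = small_signal(n=50)
        decisions = [bs.FeatureDecision(f, 0.9 if f in ("f0", "f1", "f2") else 0.1,
                                        bs.Status.Confirmed if f in ("f0", "f1", "f2")
                                        else bs.Status.Rejected)
                     for f in X.columns]
        res = bs.SelectionResult(decisions, 5, [0.1] * 5, 0.6, 0.05)
        out = bs.finalize_subset(res, self.table(X, y))
        assert list(out.X.columns) == ["f0", "f1", "f2"]
        # idempotent on the already-reduced table
        again = bs.finalize_subset(res, out)
        assert again.X.equals(out.X)

    def test_no_confirmed_is_error(self):
        X, y = small_signal(n=50)
        decisions = [bs.FeatureDecision(f, 0.5, bs.Status.Tentative) for f in X.columns]
        res = bs.SelectionResult(decisions, 5, [0.1] * 5, 0.6, 0.05)
        with pytest.raises(ValueError, match="Confirmed"):
            bs.finalize_subset(res, self.table(X, y))
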