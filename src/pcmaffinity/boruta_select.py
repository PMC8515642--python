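"""Shadow-feature (Boruta-style) selection driven by OOB permutation importance.

Each round copies every real feature into a "shadow" column whose values
are independently row-permuted, fits a random-forest regressor on the
combined matrix and measures, per column, the drop in out-of-bag R^2 when
that column is permuted over each tree's out-of-bag rows.  Importances are
quantile-normalised to [0, 1] over the real features within the round; the
largest normalised shadow importance is the round's Z-max.  A real feature
is marked Important in a round when its normalised score exceeds
max(Z-max, threshold) and Rejected when it falls below Z-max - margin.
After a fixed number of rounds features are Confirmed or Rejected by
majority vote, everything else staying Tentative.

This is the fixed-round, fixed-threshold variant of Boruta (threshold 0.6,
five rounds, no binomial test); the canonical dynamic-round binomial-test
flow is available via ``variant="binomial"``.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.ensemble import RandomForestRegressor

from pcmaffinity.featureset import FeatureTable

logger = logging.getLogger(__name__)

SHADOW_PREFIX = "shadow__"

#: forest used inside selection rounds; smaller and more randomised than the
#: final regression forest -- importance ranks stabilise well before 500 trees
DEFAULT_FOREST = {"n_estimators": 150, "max_features": "sqrt", "n_jobs": 1}

DEFAULT_THRESHOLD = 0.6
DEFAULT_ROUNDS = 5
DEFAULT_MARGIN = 0.05


class Status(str, Enum):
    Confirmed = "Confirmed"
    Tentative = "Tentative"
    Rejected = "Rejected"


@dataclass(frozen=True)
class FeatureDecision:
    feature: str
    score: float  # mean normalised importance over rounds, in [0, 1] scale
    status: Status


@dataclass
class SelectionResult:
    decisions: list[FeatureDecision]
    rounds: int
    zmax_per_round: list[float]
    threshold: float
    margin: float

    def by_status(self, status: Status) -> list[str]:
        return [d.feature for d in self.decisions if d.status is status]

    @property
    def confirmed(self) -> list[str]:
        return self.by_status(Status.Confirmed)

    def scores(self) -> pd.Series:
        return pd.Series({d.feature: d.score for d in self.decisions})

    def to_frame(self, origins: dict[str, str] | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "feature": [d.feature for d in self.decisions],
                "score": [d.score for d in self.decisions],
                "status": [d.status.value for d in self.decisions],
            }
        )
        if origins:
            df.insert(1, "origin", [origins.get(f, "") for f in df["feature"]])
        return df

    def to_csv(self, path, origins: dict[str, str] | None = None) -> None:
        self.to_frame(origins).to_csv(path, index=False)


@dataclass
class ShadowedMatrix:
    original: pd.DataFrame
    shadow: pd.DataFrame
    combined: pd.DataFrame = field(init=False)

    def __post_init__(self):
        self.combined = pd.concat([self.original, self.shadow], axis=1)


def _column_seed(seed: int, name: str) -> int:
    # stable per-column stream so decisions ignore column order
    return (int(seed) * 2654435761 + zlib.crc32(name.encode())) % (2**31 - 1)


def shadow_extend(X: pd.DataFrame, seed: int) -> ShadowedMatrix:
    """Append one independently row-permuted shadow column per real column.

    Each shadow's permutation is seeded from (seed, column name), so the
    construction is invariant under column reordering.
    """
    if len(X) < 2:
        raise ValueError("need at least 2 rows to build shadow features")
    shadow = {}
    for col in X.columns:
        rng = np.random.RandomState(_column_seed(seed, str(col)))
        shadow[SHADOW_PREFIX + str(col)] = X[col].to_numpy()[rng.permutation(len(X))]
    return ShadowedMatrix(original=X, shadow=pd.DataFrame(shadow, index=X.index))


def _inbag_oob_masks(forest: RandomForestRegressor, n: int) -> np.ndarray:
    """(T, n) boolean OOB masks, replaying sklearn's bootstrap draws."""
    masks = np.empty((len(forest.estimators_), n), dtype=bool)
    for t, tree in enumerate(forest.estimators_):
        idx = np.random.RandomState(tree.random_state).randint(0, n, n)
        masks[t] = True
        masks[t, idx] = False
    return masks


def _leaf_values(tree) -> np.ndarray:
    return tree.tree_.value.reshape(-1)


def _r2(y: np.ndarray, pred: np.ndarray) -> float:
    sst = np.square(y - y.mean()).sum()
    if sst == 0:
        return np.nan
    return 1.0 - np.square(y - pred).sum() / sst


def oob_importance(
    X: pd.DataFrame,
    y,
    forest: RandomForestRegressor | dict | None = None,
    seed: int = 0,
    permutation_factory: Callable[[np.random.RandomState, int], np.ndarray] | None = None,
) -> pd.Series:
    """Per-feature OOB permutation importance of a regression forest.

    For every tree with usable out-of-bag rows, the tree's OOB R^2 is
    compared with the OOB R^2 after permuting one column over the tree's
    OOB rows; the importance of that column is the mean decrease over
    trees.  Trees that never split on a column contribute a decrease of
    exactly zero for it, which makes the computation cheap: only trees
    actually using the column are re-evaluated.

    ``permutation_factory(rng, n_oob)`` overrides the within-tree shuffle
    (the default draws one permutation per tree, shared by all columns).
    """
    yarr = np.asarray(y, dtype=float)
    Xarr = np.ascontiguousarray(X.to_numpy(dtype=np.float32))
    n, p = Xarr.shape
    if isinstance(forest, RandomForestRegressor):
        model = forest
        if not hasattr(model, "estimators_"):
            model.fit(Xarr, yarr)
    else:
        params = {**DEFAULT_FOREST, **(forest or {})}
        model = RandomForestRegressor(random_state=seed, bootstrap=True, **params)
        model.fit(Xarr, yarr)

    masks = _inbag_oob_masks(model, n)
    rng = np.random.RandomState(seed % (2**31 - 1))
    sums = np.zeros(p)
    n_valid = 0
    for t, tree in enumerate(model.estimators_):
        oob = np.flatnonzero(masks[t])
        if len(oob) < 2:
            logger.warning("tree %d has fewer than 2 OOB rows; skipped", t)
            continue
        y_oob = yarr[oob]
        if np.square(y_oob - y_oob.mean()).sum() == 0:
            continue
        values = _leaf_values(tree)
        X_oob = np.ascontiguousarray(Xarr[oob])
        base_pred = values[tree.tree_.apply(X_oob)]
        base_r2 = _r2(y_oob, base_pred)
        if permutation_factory is None:
            perm = rng.permutation(len(oob))
        else:
            perm = permutation_factory(rng, len(oob))
        used = np.unique(tree.tree_.feature[tree.tree_.feature >= 0])
        n_valid += 1
        for j in used:
            backup = X_oob[:, j].copy()
            X_oob[:, j] = X_oob[perm, j]
            pred = values[tree.tree_.apply(X_oob)]
            X_oob[:, j] = backup
            sums[j] += base_r2 - _r2(y_oob, pred)
    if n_valid == 0:
        raise ValueError("no tree had usable out-of-bag rows")
    return pd.Series(sums / n_valid, index=X.columns, name="oob_importance")


def _normalize(imp: pd.Series, real_cols: list[str]) -> pd.Series:
    """Quantile-normalise importances to [0, 1] within a round.

    Each real feature's score is its empirical quantile among the real
    features (ties share averaged ranks); shadow importances are mapped
    through the same quantile function by interpolation.  A rank scale makes
    the scores comparable across rounds and matches reporting conventions
    where several top descriptors share the maximal score of 1.00.
    """
    from scipy.stats import rankdata

    real = imp[real_cols].to_numpy(dtype=float)
    n = len(real)
    if n < 2 or np.ptp(real) == 0:
        return pd.Series(0.0, index=imp.index)
    rnorm = (rankdata(real, method="average") - 1) / (n - 1)
    order = np.argsort(real, kind="mergesort")
    out = pd.Series(
        np.interp(imp.to_numpy(dtype=float), real[order], rnorm[order]),
        index=imp.index,
    )
    out[real_cols] = rnorm
    return out


def boruta_run(
    X: pd.DataFrame,
    y,
    threshold: float = DEFAULT_THRESHOLD,
    rounds: int = DEFAULT_ROUNDS,
    margin: float = DEFAULT_MARGIN,
    forest: dict | None = None,
    seed: int = 0,
    variant: str = "fixed",
) -> SelectionResult:
    """Run shadow-feature selection and label every real feature.

    ``variant="fixed"`` (default): the fixed-round majority-vote flow
    described in the module docstring.  ``variant="binomial"``: canonical
    Boruta -- a feature is Important in a round when it beats Z-max, and a
    two-sided binomial test at p < 0.05 over the rounds promotes/demotes it.
    """
    if variant not in {"fixed", "binomial"}:
        raise ValueError(f"unknown variant {variant!r}")
    yarr = np.asarray(y, dtype=float)
    if not np.isfinite(X.to_numpy(dtype=float)).all():
        raise ValueError("X must be finite (impute before selection)")
    if not np.isfinite(yarr).all():
        raise ValueError("y must be finite")
    if np.ptp(yarr) == 0:
        raise ValueError("degenerate response: y is constant")

    real_cols = [str(c) for c in X.columns]
    important_votes = pd.Series(0, index=real_cols)
    rejected_votes = pd.Series(0, index=real_cols)
    score_sum = pd.Series(0.0, index=real_cols)
    zmaxes: list[float] = []

    for r in range(rounds):
        round_seed = int(np.random.SeedSequence([seed, r]).generate_state(1)[0] % (2**31 - 1))
        shadowed = shadow_extend(X, seed=round_seed)
        imp = oob_importance(shadowed.combined, yarr, forest=forest, seed=round_seed)
        norm = _normalize(imp, real_cols)
        shadow_cols = [SHADOW_PREFIX + c for c in real_cols]
        zmax = float(norm[shadow_cols].max())
        zmaxes.append(zmax)
        real_norm = norm[real_cols]
        score_sum += real_norm
        if variant == "fixed":
            important_votes += (real_norm > max(zmax, threshold)).astype(int)
            rejected_votes += (real_norm < zmax - margin).astype(int)
        else:
            important_votes += (real_norm > zmax).astype(int)
        logger.info("selection round %d: Z-max %.3f", r + 1, zmax)

    mean_score = score_sum / rounds
    decisions = []
    for feat in real_cols:
        if variant == "fixed":
            if important_votes[feat] * 2 > rounds:
                status = Status.Confirmed
            elif rejected_votes[feat] * 2 > rounds:
                status = Status.Rejected
            else:
                status = Status.Tentative
        else:
            # two one-sided binomial tests at p < 0.05, as in canonical Boruta
            hits = int(important_votes[feat])
            if binomtest(hits, rounds, 0.5, alternative="greater").pvalue < 0.05:
                status = Status.Confirmed
            elif binomtest(hits, rounds, 0.5, alternative="less").pvalue < 0.05:
                status = Status.Rejected
            else:
                status = Status.Tentative
        decisions.append(
            FeatureDecision(feature=feat, score=float(mean_score[feat]), status=status)
        )
    counts = {s: sum(1 for d in decisions if d.status is s) for s in Status}
    logger.info(
        "selection: %d Confirmed, %d Tentative, %d Rejected",
        counts[Status.Confirmed], counts[Status.Tentative], counts[Status.Rejected],
    )
    return SelectionResult(
        decisions=decisions, rounds=rounds, zmax_per_round=zmaxes,
        threshold=threshold, margin=margin,
    )


def finalize_subset(result: SelectionResult, table: FeatureTable) -> FeatureTable:
    """Keep only Confirmed feature columns of a feature table."""
    decided = {d.feature for d in result.decisions}
    missing = set(map(str, table.X.columns)) - decided
    if missing:
        raise KeyError(f"selection result does not cover columns {sorted(missing)[:5]}")
    confirmed = [c for c in table.X.columns if str(c) in set(result.confirmed)]
    if not confirmed:
        raise ValueError("no feature was Confirmed; refusing to produce an empty table")
    return table.select_columns(confirmed)
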