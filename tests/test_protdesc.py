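import numpy as np
import pytest

from pcmaffinity import protdesc
from pcmaffinity._fixtures import (
    AA_ORDER,
    load_ctd_attributes,
    load_default_distance_matrices,
    load_property_scales,
    normalize_scale,
)
from pcmaffinity.data_model import TargetRecord, ValidationError
from tests.conftest import random_sequence
from tests.oracles import (
    geary_oracle,
    moran_oracle,
    moreau_broto_oracle,
    qso_oracle,
    socn_oracle,
)

SCALES = load_property_scales()
MATRICES = load_default_distance_matrices()


class TestComposition:
    def test_homopolymer_is_pure(self):
        vals = protdesc.aac("AAAA")
        assert vals["G1.A"] == 1.0
        assert sum(vals.values()) == pytest.approx(1.0)
        assert all(v == 0.0 for k, v in vals.items() if k != "G1.A")

    def test_uniform_alphabet(self):
        vals = protdesc.aac("ACDEFGHIKLMNPQRSTVWY")
        assert all(v == pytest.approx(0.05) for v in vals.values())

    def test_two_thirds_one_third(self):
        vals = protdesc.aac("AAC")
        assert vals["G1.A"] == pytest.approx(2 / 3)
        assert vals["G1.C"] == pytest.approx(1 / 3)

    def test_dipeptide_examples(self):
        assert protdesc.dipeptide("AAA")["G2.AA"] == 1.0
        vals = protdesc.dipeptide("ACA")
        assert vals["G2.AC"] == 0.5 and vals["G2.CA"] == 0.5

    def test_dipeptide_normalisation(self, rng):
        vals = protdesc.dipeptide(random_sequence(rng, 50))
        assert len(vals) == 400
        assert sum(vals.values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_or_short_sequences_rejected(self):
        with pytest.raises(ValidationError):
            protdesc.aac("")
        with pytest.raises(ValidationError):
            protdesc.dipeptide("A")


@pytest.mark.parametrize("seed", range(5))
def test_autocorrelation_matches_bruteforce(rng, seed):
    """Vectorised G3/G4/G5 equal plain-loop summation of their formulas."""
    seq = random_sequence(np.random.RandomState(seed), 35)
    maxlag = 5
    scale_name, scale = next(iter(SCALES.items()))
    mb = protdesc.moreau_broto(seq, {scale_name: scale}, maxlag=maxlag)
    mo = protdesc.moran(seq, {scale_name: scale}, maxlag=maxlag)
    ge = protdesc.geary(seq, {scale_name: scale}, maxlag=maxlag)
    np.testing.assert_allclose(
        [mb[f"G3.{scale_name}.d{d}"] for d in range(1, maxlag + 1)],
        moreau_broto_oracle(seq, scale, maxlag), atol=1e-9)
    np.testing.assert_allclose(
        [mo[f"G4.{scale_name}.d{d}"] for d in range(1, maxlag + 1)],
        moran_oracle(seq, scale, maxlag), atol=1e-9)
    np.testing.assert_allclose(
        [ge[f"G5.{scale_name}.d{d}"] for d in range(1, maxlag + 1)],
        geary_oracle(seq, scale, maxlag), atol=1e-9)


def test_sequence_order_matches_bruteforce(rng):
    seq = random_sequence(rng, 35)
    maxlag = 5
    name, df = MATRICES[0]
    so = protdesc.socn(seq, [(name, df)], maxlag=maxlag)
    np.testing.assert_allclose(
        [so[f"G8.{name}.tau{d}"] for d in range(1, maxlag + 1)],
        socn_oracle(seq, df, maxlag), atol=1e-9)
    q = protdesc.qso(seq, [(name, df)], maxlag=maxlag)
    expected = qso_oracle(seq, df, maxlag)
    got = [q[f"G9.{name}.f.{aa}"] for aa in AA_ORDER] + \
          [q[f"G9.{name}.tau{d}"] for d in range(1, maxlag + 1)]
    np.testing.assert_allclose(got, expected, atol=1e-9)


class TestHomopolymerConventions:
    SEQ = "A" * 40

    def test_moreau_broto_constant(self):
        p = normalize_scale(SCALES["hydrophobicity"])["A"]
        vals = protdesc.moreau_broto(self.SEQ, {"hydrophobicity": SCALES["hydrophobicity"]})
        assert all(v == pytest.approx(p * p) for v in vals.values())

    def test_moran_geary_zero_variance_convention(self):
        assert set(protdesc.moran(self.SEQ).values()) == {0.0}
        assert set(protdesc.geary(self.SEQ).values()) == {0.0}

    def test_socn_zero_diagonal(self):
        assert set(protdesc.socn(self.SEQ).values()) == {0.0}


def test_geary_concentrates_near_one_for_iid_sequence(rng):
    """For an i.i.d. sequence there is no spatial autocorrelation, so Geary's
    C should be close to 1 at large N."""
    seq = random_sequence(rng, 500)
    vals = protdesc.geary(seq, maxlag=5)
    assert np.allclose(list(vals.values()), 1.0, atol=0.2)


class TestCTD:
    def test_group_sizes(self, seq35):
        vals = protdesc.ctd(seq35)
        g6 = [k for k in vals if k.startswith("G6.")]
        g7 = [k for k in vals if k.startswith("G7.")]
        assert len(g6) == 21 and len(g7) == 126

    def test_alternating_transition_hand_count(self):
        # A is neutral, R polar under the hydrophobicity attribute; every one
        # of the 5 adjacent pairs in ARARAR is a polar/neutral transition.
        vals = protdesc.ctd("ARARAR")
        assert vals["G7.hydrophobicity.t12"] == pytest.approx(1.0)
        assert vals["G7.hydrophobicity.t13"] == 0.0
        assert vals["G7.hydrophobicity.t23"] == 0.0

    def test_distribution_first_occurrence_hand_count(self):
        # polar class (class 1) first occurs at position 2 of 6
        vals = protdesc.ctd("ARARAR")
        assert vals["G7.hydrophobicity.d1.p0"] == pytest.approx(2 / 6 * 100)
        # absent class (hydrophobic) yields zeros
        assert vals["G7.hydrophobicity.d3.p0"] == 0.0
        assert vals["G7.hydrophobicity.d3.p100"] == 0.0

    def test_composition_sums_to_one_per_attribute(self, seq35):
        vals = protdesc.ctd(seq35)
        for name, _ in load_ctd_attributes():
            assert sum(vals[f"G6.{name}.c{c}"] for c in (1, 2, 3)) == pytest.approx(1.0)


class TestFullVector:
    def test_group_sizes_match_contract(self, seq35):
        vec = protdesc.protein_descriptors(TargetRecord("t", seq35))
        assert vec.group_counts() == protdesc.GROUP_SIZES
        assert len(vec.values) == 1447

    def test_deterministic(self, seq35):
        a = protdesc.protein_descriptors(TargetRecord("t", seq35))
        b = protdesc.protein_descriptors(TargetRecord("t", seq35))
        assert a.values.equals(b.values)

    def test_shuffle_changes_order_sensitive_groups_only(self, rng):
        seq = random_sequence(rng, 60)
        shuffled = "".join(rng.permutation(list(seq)))
        assume_different = shuffled != seq
        assert assume_different
        a = protdesc.protein_descriptors(TargetRecord("t", seq)).values
        b = protdesc.protein_descriptors(TargetRecord("t", shuffled)).values
        g1 = [k for k in a.index if k.startswith("G1.")]
        assert a[g1].equals(b[g1])
        rest = [k for k in a.index if not k.startswith("G1.")]
        assert not a[rest].equals(b[rest])

    def test_normalisation_identities(self, seq35):
        vec = protdesc.protein_descriptors(TargetRecord("t", seq35)).values
        assert vec[[k for k in vec.index if k.startswith("G1.")]].sum() == pytest.approx(1, abs=1e-9)
        assert vec[[k for k in vec.index if k.startswith("G2.")]].sum() == pytest.approx(1, abs=1e-9)
        for mat, _ in MATRICES:
            block = vec[[k for k in vec.index if k.startswith(f"G9.{mat}.")]]
            assert len(block) == 50
            assert block.sum() == pytest.approx(1, abs=1e-9)

    def test_too_short_sequence_names_requirement(self):
        with pytest.raises(ValidationError, match="minimum"):
            protdesc.protein_descriptors(TargetRecord("short", "ACDEFGHIKL"))
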