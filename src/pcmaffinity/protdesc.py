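"""Protein sequence descriptors: nine families computed from sequence alone.

The families (with their column counts for 8 property scales, 7 CTD
attributes, 2 distance matrices and maximum lag 30):

=====  ==========================================  =====
group  family                                      count
=====  ==========================================  =====
G1     amino acid composition                         20
G2     dipeptide composition                         400
G3     normalised Moreau-Broto autocorrelation       240
G4     Moran autocorrelation                         240
G5     Geary autocorrelation                         240
G6     CTD composition                                21
G7     CTD transition + distribution                 126
G8     sequence-order-coupling numbers                60
G9     quasi-sequence-order descriptors              100
=====  ==========================================  =====

for a total of 1447 columns per target.  Column names are hierarchical
(``G3.hydrophobicity.d7``); the group tag is the prefix before the first
dot.  Autocorrelations use z-normalised scales; Moran and Geary return 0
for a property with zero sequence variance (the homopolymer convention),
keeping every sequence representable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from pcmaffinity._fixtures import (
    AA_ORDER,
    load_ctd_attributes,
    load_default_distance_matrices,
    load_property_scales,
    normalize_scale,
)
from pcmaffinity.data_model import STANDARD_RESIDUES, TargetRecord, ValidationError

MAXLAG = 30
QSO_WEIGHT = 0.1

GROUP_SIZES = {
    "G1": 20, "G2": 400, "G3": 240, "G4": 240, "G5": 240,
    "G6": 21, "G7": 126, "G8": 60, "G9": 100,
}
TOTAL_DESCRIPTORS = sum(GROUP_SIZES.values())  # 1447

_AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}


def group_of(column: str) -> str:
    """Group tag of a protein descriptor column name."""
    return column.split(".", 1)[0]


def _check_sequence(sequence: str, minimum: int, op: str) -> np.ndarray:
    bad = set(sequence) - STANDARD_RESIDUES
    if bad:
        raise ValidationError(f"{op}: non-standard residues {sorted(bad)} in sequence")
    if len(sequence) < minimum:
        raise ValidationError(
            f"{op}: sequence length {len(sequence)} below the required minimum {minimum}"
        )
    return np.fromiter((_AA_INDEX[c] for c in sequence), dtype=np.intp, count=len(sequence))


def aac(sequence: str) -> dict[str, float]:
    """G1: residue frequencies; sums to 1."""
    idx = _check_sequence(sequence, 1, "aac")
    counts = np.bincount(idx, minlength=20)
    freqs = counts / len(sequence)
    return {f"G1.{aa}": float(freqs[i]) for i, aa in enumerate(AA_ORDER)}

def dipeptide(sequence: str) -> dict[str, float]:
    """G2: adjacent-pair frequencies over (N-1) positions; sums to 1."""
    idx = _check_sequence(sequence, 2, "dipeptide")
    counts = np.bincount(idx[:-1] * 20 + idx[1:], minlength=400)
    freqs = counts / (len(sequence) - 1)
    return {
        f"G2.{a}{b}": float(freqs[i * 20 + j])
        for i, a in enumerate(AA_ORDER)
        for j, b in enumerate(AA_ORDER)
    }


def _scale_arrays(scales: Mapping[str, Mapping[str, float]]) -> dict[str, np.ndarray]:
    return {
        name: np.array([normalize_scale(dict(vals))[aa] for aa in AA_ORDER])
        for name, vals in scales.items()
    }


def moreau_broto(
    sequence: str,
    scales: Mapping[str, Mapping[str, float]] | None = None,
    maxlag: int = MAXLAG,
) -> dict[str, float]:
    """G3: AC(p,d) = sum_i p(r_i) p(r_(i+d)) / (N-d) on the z-normalised scale."""
    idx = _check_sequence(sequence, maxlag + 1, "moreau_broto")
    out: dict[str, float] = {}
    for name, arr in _scale_arrays(scales or load_property_scales()).items():
        p = arr[idx]
        for d in range(1, maxlag + 1):
            out[f"G3.{name}.d{d}"] = float(np.dot(p[:-d], p[d:]) / (len(p) - d))
    return out


def moran(
    sequence: str,
    scales: Mapping[str, Mapping[str, float]] | None = None,
    maxlag: int = MAXLAG,
) -> dict[str, float]:
    """G4: Moran I with the sequence mean as reference; 0 when variance is 0."""
    idx = _check_sequence(sequence, maxlag + 1, "moran")
    out: dict[str, float] = {}
    for name, arr in _scale_arrays(scales or load_property_scales()).items():
        p = arr[idx]
        centred = p - p.mean()
        denom = np.square(centred).sum() / len(p)
        if denom < 1e-12:  # zero sequence variance up to rounding
            denom = 0.0
        for d in range(1, maxlag + 1):
            if denom == 0:
                out[f"G4.{name}.d{d}"] = 0.0
            else:
                num = np.dot(centred[:-d], centred[d:]) / (len(p) - d)
                out[f"G4.{name}.d{d}"] = float(num / denom)
    return out


def geary(
    sequence: str,
    scales: Mapping[str, Mapping[str, float]] | None = None,
    maxlag: int = MAXLAG,
) -> dict[str, float]:
    """G5: Geary C with an (N-1) variance denominator; 0 when variance is 0."""
    idx = _check_sequence(sequence, maxlag + 1, "geary")
    out: dict[str, float] = {}
    for name, arr in _scale_arrays(scales or load_property_scales()).items():
        p = arr[idx]
        centred = p - p.mean()
        denom = np.square(centred).sum() / (len(p) - 1)
        if denom < 1e-12:  # zero sequence variance up to rounding
            denom = 0.0
        for d in range(1, maxlag + 1):
            if denom == 0:
                out[f"G5.{name}.d{d}"] = 0.0
            else:
                num = np.square(p[:-d] - p[d:]).sum() / (2 * (len(p) - d))
                out[f"G5.{name}.d{d}"] = float(num / denom)
    return out


def ctd(
    sequence: str,
    attributes: Sequence[tuple[str, Mapping[str, int]]] | None = None,
) -> dict[str, float]:
    """G6 + G7: composition, transition and distribution over 3-class partitions.

    Distribution reports, for each class, the 1-based position (as percent of
    sequence length) of its 1st, 25%-th, 50%-th, 75%-th and 100%-th occurrence,
    the occurrence index being ``ceil(fraction x class count)``; absent classes
    yield zeros.
    """
    _check_sequence(sequence, 2, "ctd")
    attributes = attributes if attributes is not None else load_ctd_attributes()
    n = len(sequence)
    out: dict[str, float] = {}
    for name, mapping in attributes:
        cls = np.fromiter((mapping[c] for c in sequence), dtype=np.intp, count=n)
        counts = np.bincount(cls, minlength=3)
        for c in range(3):
            out[f"G6.{name}.c{c + 1}"] = float(counts[c] / n)
        pairs = [(0, 1), (0, 2), (1, 2)]
        adj = np.stack([cls[:-1], cls[1:]])
        lo, hi = adj.min(axis=0), adj.max(axis=0)
        for a, b in pairs:
            t = int(np.sum((lo == a) & (hi == b)))
            out[f"G7.{name}.t{a + 1}{b + 1}"] = float(t / (n - 1))
        for c in range(3):
            positions = np.flatnonzero(cls == c) + 1  # 1-based
            for frac, label in [(0.0, "p0"), (0.25, "p25"), (0.5, "p50"),
                                (0.75, "p75"), (1.0, "p100")]:
                key = f"G7.{name}.d{c + 1}.{label}"
                if len(positions) == 0:
                    out[key] = 0.0
                else:
                    k = max(1, int(np.ceil(frac * len(positions))))
                    out[key] = float(positions[k - 1] / n * 100.0)
    return out


def _matrix_arrays(
    matrices: Sequence[tuple[str, pd.DataFrame]] | None,
) -> list[tuple[str, np.ndarray]]:
    matrices = matrices if matrices is not None else load_default_distance_matrices()
    return [(name, df.loc[list(AA_ORDER), list(AA_ORDER)].to_numpy(float))
            for name, df in matrices]


def socn(
    sequence: str,
    matrices: Sequence[tuple[str, pd.DataFrame]] | None = None,
    maxlag: int = MAXLAG,
) -> dict[str, float]:
    """G8: tau_d = sum_i d(r_i, r_(i+d))^2 for d = 1..maxlag, per matrix."""
    idx = _check_sequence(sequence, maxlag + 1, "socn")
    out: dict[str, float] = {}
    for name, mat in _matrix_arrays(matrices):
        for d in range(1, maxlag + 1):
            out[f"G8.{name}.tau{d}"] = float(np.square(mat[idx[:-d], idx[d:]]).sum())
    return out


def qso(
    sequence: str,
    matrices: Sequence[tuple[str, pd.DataFrame]] | None = None,
    maxlag: int = MAXLAG,
    weight: float = QSO_WEIGHT,
) -> dict[str, float]:
    """G9: 20 residue terms and 30 coupling terms per matrix, jointly normalised.

    With f_r the residue frequencies and tau_d the coupling numbers,
    residue terms are f_r / (sum f + w sum tau) and coupling terms
    w tau_d / (sum f + w sum tau); the 50 values per matrix sum to 1.
    """
    idx = _check_sequence(sequence, maxlag + 1, "qso")
    freqs = np.bincount(idx, minlength=20) / len(sequence)
    out: dict[str, float] = {}
    for name, mat in _matrix_arrays(matrices):
        taus = np.array([
            np.square(mat[idx[:-d], idx[d:]]).sum() for d in range(1, maxlag + 1)
        ])
        denom = freqs.sum() + weight * taus.sum()
        for i, aa in enumerate(AA_ORDER):
            out[f"G9.{name}.f.{aa}"] = float(freqs[i] / denom)
        for d in range(1, maxlag + 1):
            out[f"G9.{name}.tau{d}"] = float(weight * taus[d - 1] / denom)
    return out


@dataclass(frozen=True)
class ProteinDescriptorVector:
    target_id: str
    values: "pd.Series"  # index = hierarchical column names

    def group_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {g: 0 for g in GROUP_SIZES}
        for name in self.values.index:
            counts[group_of(name)] += 1
        return counts


def protein_descriptors(
    target: TargetRecord,
    scales: Mapping[str, Mapping[str, float]] | None = None,
    attributes: Sequence[tuple[str, Mapping[str, int]]] | None = None,
    matrices: Sequence[tuple[str, pd.DataFrame]] | None = None,
    maxlag: int = MAXLAG,
) -> ProteinDescriptorVector:
    """Concatenate all nine families for one target (1447 named values)."""
    target.validate()
    seq = target.sequence
    try:
        scales = scales or load_property_scales()
        matrices = matrices if matrices is not None else load_default_distance_matrices()
        values: dict[str, float] = {}
        values.update(aac(seq))
        values.update(dipeptide(seq))
        values.update(moreau_broto(seq, scales, maxlag))
        values.update(moran(seq, scales, maxlag))
        values.update(geary(seq, scales, maxlag))
        values.update(ctd(seq, attributes))
        values.update(socn(seq, matrices, maxlag))
        values.update(qso(seq, matrices, maxlag))
    except ValidationError as exc:
        raise ValidationError(f"target {target.target_id!r}: {exc}") from exc
    return ProteinDescriptorVector(
        target_id=target.target_id, values=pd.Series(values, dtype=float)
    )


def protein_descriptor_matrix(
    targets: Sequence[TargetRecord], **kwargs
) -> pd.DataFrame:
    """Rows = targets, columns = the 1447 protein descriptors."""
    # share fixture loads across targets
    kwargs.setdefault("scales", load_property_scales())
    kwargs.setdefault("attributes", load_ctd_attributes())
    kwargs.setdefault("matrices", load_default_distance_matrices())
    vecs = [protein_descriptors(t, **kwargs) for t in targets]
    return pd.DataFrame(
        {v.target_id: v.values for v in vecs}
    ).T.rename_axis("target_id")
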