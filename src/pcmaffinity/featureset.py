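"""Whole-system feature assembly and preprocessing.

One row per ligand-target interaction: the ligand's filtered molecular
descriptors concatenated with the target's sequence descriptors, the
response being log2 of the affinity value.  Preprocessing follows the
usual QSAR recipe: min-max scaling to [-1, 1] and median imputation, both
fitted on the training partition only and applied to held-out rows (a
``fit_on_all`` switch reproduces the leakage-prone variant that fits the
scaling on every row).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from pcmaffinity.data_model import AffinityType, InteractionTable

logger = logging.getLogger(__name__)

MOL_ORIGIN = "mol"
PROT_ORIGIN = "prot"


@dataclass
class FeatureTable:
    """Feature matrix keyed by (ligand_id, target_id) with a log2 response."""

    X: pd.DataFrame                 # index: MultiIndex (ligand_id, target_id)
    y: pd.Series                    # log2 affinity, same index
    origins: dict[str, str]         # column -> "mol" | "prot"
    affinity_type: AffinityType

    def __post_init__(self):
        if not self.X.index.equals(self.y.index):
            raise ValueError("feature matrix and response are not aligned")

    @property
    def n_rows(self) -> int:
        return len(self.X)

    def columns_of(self, origin: str) -> list[str]:
        return [c for c in self.X.columns if self.origins[c] == origin]

    def select_columns(self, columns: list[str]) -> "FeatureTable":
        return FeatureTable(
            X=self.X[columns],
            y=self.y,
            origins={c: self.origins[c] for c in columns},
            affinity_type=self.affinity_type,
        )

    def to_csv(self, path) -> None:
        """Serialise with a two-row header: origin tag, then column name."""
        header = pd.MultiIndex.from_tuples(
            [(self.origins[c], c) for c in self.X.columns] + [("response", "log2_affinity")]
        )
        out = pd.concat([self.X, self.y.rename("log2_affinity")], axis=1)
        out.columns = header
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path, affinity_type: AffinityType | str = AffinityType.Kd) -> "FeatureTable":
        df = pd.read_csv(path, header=[0, 1], index_col=[0, 1])
        origins = {name: origin for origin, name in df.columns if origin != "response"}
        y = df[("response", "log2_affinity")]
        X = df.drop(columns=[("response", "log2_affinity")])
        X.columns = [name for _, name in X.columns]
        return cls(X=X, y=y.rename("log2_affinity"), origins=origins,
                   affinity_type=AffinityType(affinity_type))


def transform_response(values, affinity_type: AffinityType | str = AffinityType.Kd):
    """Elementwise log2 of positive affinity values."""
    arr = np.asarray(values, dtype=float)
    if (arr <= 0).any() or not np.isfinite(arr).all():
        raise ValueError("affinity values must be positive and finite before log2")
    return np.log2(arr)


def integrate(
    mol: pd.DataFrame,
    prot: pd.DataFrame,
    interactions: InteractionTable,
) -> FeatureTable:
    """One row per interaction: ligand descriptor block + target block.

    ``mol`` is indexed by ligand_id, ``prot`` by target_id.  Every
    interaction id must have a descriptor row.
    """
    missing_l = sorted({r.ligand_id for r in interactions.records} - set(mol.index))
    missing_t = sorted({r.target_id for r in interactions.records} - set(prot.index))
    if missing_l or missing_t:
        raise KeyError(
            f"descriptor vectors missing for ligands {missing_l[:5]} "
            f"and targets {missing_t[:5]}"
        )
    overlap = set(mol.columns) & set(prot.columns)
    if overlap:
        raise ValueError(f"column name collision between blocks: {sorted(overlap)[:5]}")
    lig_ids = [r.ligand_id for r in interactions.records]
    tgt_ids = [r.target_id for r in interactions.records]
    index = pd.MultiIndex.from_arrays([lig_ids, tgt_ids], names=["ligand_id", "target_id"])
    X = pd.concat(
        [
            mol.loc[lig_ids].reset_index(drop=True),
            prot.loc[tgt_ids].reset_index(drop=True),
        ],
        axis=1,
    )
    X.index = index
    y = pd.Series(
        transform_response([r.affinity_value for r in interactions.records]),
        index=index,
        name="log2_affinity",
    )
    origins = {c: MOL_ORIGIN for c in mol.columns}
    origins.update({c: PROT_ORIGIN for c in prot.columns})
    return FeatureTable(X=X, y=y, origins=origins, affinity_type=interactions.affinity_type)


@dataclass(frozen=True)
class ScalingParams:
    """Per-column min/max (and imputation medians) from the fitting partition."""

    minima: pd.Series
    maxima: pd.Series
    medians: pd.Series

    @property
    def constant_columns(self) -> list[str]:
        return list(self.minima.index[self.maxima == self.minima])

    def to_csv(self, path) -> None:
        pd.DataFrame({"min": self.minima, "max": self.maxima, "median": self.medians}) \
            .rename_axis("column").to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "ScalingParams":
        df = pd.read_csv(path, index_col="column")
        return cls(minima=df["min"], maxima=df["max"], medians=df["median"])


def fit_scaling(X: pd.DataFrame, rows=None) -> ScalingParams:
    """Column ranges and medians observed on the fitting rows.

    Non-finite entries are ignored when fitting; a column that is entirely
    non-finite on the fitting rows gets median 0 and a degenerate range.
    """
    sub = X if rows is None else X.loc[rows]
    if len(sub) == 0:
        raise ValueError("fitting partition is empty")
    vals = sub.where(np.isfinite(sub))
    minima = vals.min(axis=0)
    maxima = vals.max(axis=0)
    medians = vals.median(axis=0)
    for s in (minima, maxima, medians):
        s.fillna(0.0, inplace=True)
    n_const = int((maxima == minima).sum())
    if n_const:
        logger.info("fit_scaling: %d constant columns map to 0", n_const)
    return ScalingParams(minima=minima, maxima=maxima, medians=medians)


def apply_scaling(X: pd.DataFrame, params: ScalingParams) -> pd.DataFrame:
    """Impute non-finite entries with fitted medians, then scale to [-1, 1].

    x' = 2 (x - min) / (max - min) - 1; constant columns map to 0; values
    outside the fitted range (held-out rows) clip to the interval ends.
    """
    X = X[params.minima.index]
    filled = X.where(np.isfinite(X), other=params.medians, axis=1)
    span = params.maxima - params.minima
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = 2 * (filled - params.minima) / span - 1
    scaled = scaled.clip(-1.0, 1.0)
    scaled.loc[:, span == 0] = 0.0
    return scaled


def invert_scaling(scaled: pd.DataFrame, params: ScalingParams) -> pd.DataFrame:
    """Inverse of :func:`apply_scaling` on in-range, non-constant columns."""
    span = params.maxima - params.minima
    return (scaled + 1) / 2 * span + params.minima


def split_tenfold(n_rows: int, seed: int, n_folds: int = 10) -> list[np.ndarray]:
    """Random partition of row indices into ``n_folds`` near-equal folds."""
    if n_rows < n_folds:
        raise ValueError(f"need at least {n_folds} rows, got {n_rows}")
    rng = np.random.RandomState(seed)
    perm = rng.permutation(n_rows)
    return [np.sort(fold) for fold in np.array_split(perm, n_folds)]
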