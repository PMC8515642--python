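"""Loaders for the editable text fixtures shipped with the package.

Amino-acid property scales, CTD class partitions and residue-pair distance
matrices live under ``pcmaffinity/data`` in plain TSV/CSV so they can be
swapped without touching code.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

AA_ORDER = tuple("ACDEFGHIKLMNPQRSTVWY")  # alphabetical; column order everywhere


def _data_path(name: str) -> Path:
    return Path(resources.files("pcmaffinity").joinpath("data", name))


def load_property_scales(path: str | Path | None = None) -> dict[str, dict[str, float]]:
    """Eight AAindex-style property scales keyed by scale name."""
    df = pd.read_csv(path or _data_path("aa_property_scales.tsv"), sep="\t", index_col=0)
    scales = {}
    for name, row in df.iterrows():
        vals = {aa: float(row[aa]) for aa in AA_ORDER}
        if len(vals) != 20:
            raise ValueError(f"scale {name!r}: expected 20 residues")
        scales[str(name)] = vals
    return scales


def normalize_scale(values: dict[str, float]) -> dict[str, float]:
    """Z-normalise a 20-residue scale (mean 0, SD 1 over the residue alphabet)."""
    arr = np.array([values[aa] for aa in AA_ORDER], dtype=float)
    sd = arr.std()  # population SD over the 20 residues
    if sd == 0:
        raise ValueError("degenerate property scale with zero spread")
    arr = (arr - arr.mean()) / sd
    return dict(zip(AA_ORDER, arr))


def load_ctd_attributes(path: str | Path | None = None) -> list[tuple[str, dict[str, int]]]:
    """Seven 3-class residue partitions: (attribute name, residue -> class 0/1/2)."""
    df = pd.read_csv(path or _data_path("ctd_attributes.tsv"), sep="\t")
    attributes = []
    for _, row in df.iterrows():
        mapping: dict[str, int] = {}
        for cls in range(3):
            for aa in row[f"class{cls + 1}"]:
                if aa in mapping:
                    raise ValueError(f"{row['attribute']}: residue {aa} in two classes")
                mapping[aa] = cls
        if set(mapping) != set(AA_ORDER):
            raise ValueError(f"{row['attribute']}: classes do not cover the 20 residues")
        attributes.append((str(row["attribute"]), mapping))
    return attributes


def load_distance_matrix(name_or_path: str | Path) -> tuple[str, pd.DataFrame]:
    """A 20x20 symmetric residue-pair distance matrix with zero diagonal.

    ``name_or_path`` is either one of the shipped names (``grantham``,
    ``schneider_wrede``) or a path to a compatible CSV.
    """
    shipped = {
        "grantham": "grantham.csv",
        "schneider_wrede": "schneider_wrede_synthetic.csv",
    }
    if str(name_or_path) in shipped:
        name = str(name_or_path)
        path = _data_path(shipped[name])
    else:
        path = Path(name_or_path)
        name = path.stem
    df = pd.read_csv(path, index_col=0)
    df = df.loc[list(AA_ORDER), list(AA_ORDER)].astype(float)
    if not np.allclose(df.values, df.values.T):
        raise ValueError(f"distance matrix {name!r} is not symmetric")
    if not np.allclose(np.diag(df.values), 0):
        raise ValueError(f"distance matrix {name!r} has a non-zero diagonal")
    if (df.values < 0).any():
        raise ValueError(f"distance matrix {name!r} has negative entries")
    return name, df


def load_default_distance_matrices() -> list[tuple[str, pd.DataFrame]]:
    return [load_distance_matrix("schneider_wrede"), load_distance_matrix("grantham")]
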