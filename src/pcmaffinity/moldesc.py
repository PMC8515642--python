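"""Molecular descriptors for ligands and the vibration-related whitelist filter.

The default engine computes every RDKit 2D descriptor plus an atom-type
E-state block (count / sum / min / max of the Kier-Hall E-state indices per
atom type, named in the ``nsCH3`` / ``SsCH3`` / ``minsCH3`` / ``maxsCH3``
convention).  Descriptors are then projected onto a whitelist of
vibration-related descriptor names -- descriptors tied to electronegativity,
atomic/bond charge and polarizability, the physicochemical drivers of
molecular vibration.  Whitelist entries with no counterpart in the engine's
vocabulary are reported, never silently discarded from the accounting.

3D descriptor families (CPSA, RDF, WHIM, geometrical) require conformer
generation and are deliberately not part of the default engine, which keeps
descriptor values deterministic.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors
from rdkit.Chem.EState import EState
from rdkit.Chem.EState.AtomTypes import TypeAtoms, _rawD as _ESTATE_RAW

from pcmaffinity._fixtures import _data_path
from pcmaffinity.data_model import LigandRecord, ValidationError

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

ESTATE_TYPES = tuple(name for name, _ in _ESTATE_RAW)


class DescriptorError(ValueError):
    """A ligand's descriptors could not be computed."""


def _categorize(name: str) -> str:
    """Coarse descriptor-family tag for an engine column name."""
    estate_prefixes = ("n", "S", "min", "max")
    for p in estate_prefixes:
        if name.startswith(p) and name[len(p):] in ESTATE_TYPES:
            return "estate_atom_type"
    if "EState" in name or name.startswith("EState_VSA") or name.startswith("VSA_EState"):
        return "estate"
    if name.startswith("BCUT2D"):
        return "bcut"
    if name.startswith("Chi"):
        return "connectivity"
    if name.startswith("Kappa") or name in {"HallKierAlpha"}:
        return "kappa"
    if "PartialCharge" in name:
        return "charge"
    if name.startswith(("PEOE_VSA", "SMR_VSA", "SlogP_VSA")):
        return "moe_vsa"
    if name.startswith("fr_"):
        return "fragment"
    if name in {"BalabanJ", "BertzCT", "Ipc", "AvgIpc", "Phi"}:
        return "topological"
    if name.startswith(("Num", "Heavy")) or name in {"RingCount", "NHOHCount", "NOCount",
                                                     "FractionCSP3"}:
        return "constitutional"
    if name in {"MolWt", "ExactMolWt", "HeavyAtomMolWt", "qed", "SPS", "MolLogP",
                "MolMR", "TPSA", "LabuteASA"}:
        return "property"
    return "other"


class RDKitDescriptorEngine:
    """Deterministic 2D descriptor provider backed by RDKit.

    ``include_estate_atom_types`` adds the PaDEL-style atom-type E-state
    block on top of RDKit's stock 2D descriptor list.
    """

    def __init__(self, include_estate_atom_types: bool = True):
        self.include_estate_atom_types = include_estate_atom_types
        self._stock_names = [name for name, _ in Descriptors._descList]

    @property
    def vocabulary(self) -> list[str]:
        names = list(self._stock_names)
        if self.include_estate_atom_types:
            for t in ESTATE_TYPES:
                names += [f"n{t}", f"S{t}", f"min{t}", f"max{t}"]
        return names

    def categories(self) -> dict[str, str]:
        return {name: _categorize(name) for name in self.vocabulary}

    def compute(self, mol: Chem.Mol) -> dict[str, float]:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            values = Descriptors.CalcMolDescriptors(mol, missingVal=float("nan"))
        if self.include_estate_atom_types:
            values.update(self._estate_block(mol))
        return {k: float(v) for k, v in values.items()}

    @staticmethod
    def _estate_block(mol: Chem.Mol) -> dict[str, float]:
        indices = EState.EStateIndices(mol)
        typed = TypeAtoms(mol)
        per_type: dict[str, list[float]] = {t: [] for t in ESTATE_TYPES}
        for atom_types, value in zip(typed, indices):
            for t in atom_types:
                if t in per_type:
                    per_type[t].append(float(value))
        out: dict[str, float] = {}
        for t, vals in per_type.items():
            out[f"n{t}"] = float(len(vals))
            out[f"S{t}"] = float(sum(vals))
            out[f"min{t}"] = min(vals) if vals else 0.0
            out[f"max{t}"] = max(vals) if vals else 0.0
        return out


@dataclass(frozen=True)
class MolecularDescriptorVector:
    ligand_id: str
    values: "pd.Series"
    categories: dict[str, str] = field(default_factory=dict, compare=False)

    @property
    def n_nonfinite(self) -> int:
        return int((~np.isfinite(self.values.to_numpy(float))).sum())


def compute_molecular_descriptors(
    ligand: LigandRecord,
    engine: RDKitDescriptorEngine | None = None,
) -> MolecularDescriptorVector:
    """Descriptor vector for one ligand; raises on unparseable SMILES."""
    engine = engine or RDKitDescriptorEngine()
    mol = Chem.MolFromSmiles(ligand.smiles)
    if mol is None:
        raise DescriptorError(
            f"ligand {ligand.ligand_id!r}: SMILES {ligand.smiles!r} does not parse"
        )
    values = engine.compute(mol)
    return MolecularDescriptorVector(
        ligand_id=ligand.ligand_id,
        values=pd.Series(values, dtype=float),
        categories=engine.categories(),
    )


def molecular_descriptor_matrix(
    ligands: list[LigandRecord],
    engine: RDKitDescriptorEngine | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Rows = ligands, columns = engine vocabulary.

    Ligands whose SMILES fail to parse are excluded and returned in the
    second element so a run can continue with an explicit exclusion list.
    """
    engine = engine or RDKitDescriptorEngine()
    rows, excluded = {}, []
    for lig in ligands:
        try:
            rows[lig.ligand_id] = compute_molecular_descriptors(lig, engine).values
        except DescriptorError as exc:
            logger.warning("%s", exc)
            excluded.append(lig.ligand_id)
    if not rows:
        raise DescriptorError("no ligand yielded descriptors")
    return pd.DataFrame(rows).T.rename_axis("ligand_id"), excluded


@dataclass(frozen=True)
class VibrationWhitelist:
    names: frozenset[str]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.names)


@dataclass(frozen=True)
class FilterReport:
    matched: tuple[str, ...]       # engine column names retained
    unmatched: tuple[str, ...]     # whitelist entries absent from the vocabulary
    policy: str


def load_whitelist(path: str | Path | None = None) -> VibrationWhitelist:
    """Load a descriptor-name whitelist (CSV: name plus optional meaning).

    With no path, the packaged 813-entry vibration-related list is used.
    Duplicated names are collapsed with a warning; an empty file is an error.
    """
    path = Path(path) if path is not None else _data_path("vibration_whitelist_synthetic.csv")
    df = pd.read_csv(path)
    if "name" not in df.columns:
        df = pd.read_csv(path, header=None, names=["name"])
    names = [str(n).strip() for n in df["name"] if str(n).strip()]
    if not names:
        raise ValidationError(f"whitelist {path.name}: no descriptor names found")
    unique = list(dict.fromkeys(names))
    if len(unique) < len(names):
        logger.warning("whitelist %s: %d duplicated names collapsed",
                       path.name, len(names) - len(unique))
    logger.info("whitelist %s: %d descriptor names", path.name, len(unique))
    return VibrationWhitelist(names=frozenset(unique), provenance=str(path))


def load_alias_map(path: str | Path | None = None) -> dict[str, str]:
    """Whitelist-name to engine-name alias map (editable CSV)."""
    path = Path(path) if path is not None else _data_path("padel_rdkit_aliases.csv")
    df = pd.read_csv(path)
    return dict(zip(df["whitelist_name"].astype(str), df["engine_name"].astype(str)))


def apply_vibration_filter(
    matrix: pd.DataFrame,
    whitelist: VibrationWhitelist,
    match_policy: str = "alias-map",
    alias_map: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Project descriptor columns onto the whitelist.

    ``match_policy``: ``exact`` compares names verbatim, ``case-insensitive``
    ignores case, ``alias-map`` additionally translates whitelist names
    through an alias table before exact matching.  A pure column projection:
    rows and retained values are untouched.  Zero matches is a hard error
    (wrong engine or alias map).
    """
    if match_policy not in {"exact", "case-insensitive", "alias-map"}:
        raise ValueError(f"unknown match_policy {match_policy!r}")
    columns = list(matrix.columns)
    resolved: dict[str, str] = {}  # whitelist entry -> engine column
    if match_policy == "case-insensitive":
        lower = {c.lower(): c for c in columns}
        for w in whitelist.names:
            if w.lower() in lower:
                resolved[w] = lower[w.lower()]
    else:
        colset = set(columns)
        aliases = (alias_map if alias_map is not None else load_alias_map()) \
            if match_policy == "alias-map" else {}
        for w in whitelist.names:
            if w in colset:
                resolved[w] = w
            elif w in aliases and aliases[w] in colset:
                resolved[w] = aliases[w]
    matched = [c for c in columns if c in set(resolved.values())]
    unmatched = sorted(w for w in whitelist.names if w not in resolved)
    if not matched:
        raise ValidationError(
            "vibration filter matched zero descriptor columns; "
            "check the engine choice and alias map"
        )
    logger.info("vibration filter: %d/%d whitelist entries matched; %d columns retained",
                len(resolved), len(whitelist), len(matched))
    return matrix[matched], FilterReport(
        matched=tuple(matched), unmatched=tuple(unmatched), policy=match_policy
    )
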