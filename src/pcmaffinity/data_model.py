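"""Domain types and loaders for ligand-target affinity data.

Affinity tables arrive as CSV/TSV with one row per measured ligand-target
pair (Kd or EC50, assumed nM unless configured otherwise), ligands as a
SMILES table and targets as multi-FASTA.  ``deduplicate`` applies the
redundancy rules used when curating such data: censored measurements are
dropped, replicated pairs collapse to their median when consistent on the
log2 scale and are discarded wholesale when not.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: minimum sequence length for the lag-30 descriptor families (maxlag + 1)
MIN_SEQUENCE_LENGTH = 31


class AffinityType(str, Enum):
    Kd = "Kd"
    EC50 = "EC50"


class Qualifier(str, Enum):
    exact = "exact"
    censored = "censored"


class SchemaError(ValueError):
    """The input table does not carry the expected columns."""


class ValidationError(ValueError):
    """A record violates a domain invariant (reported with its location)."""


@dataclass(frozen=True)
class LigandRecord:
    ligand_id: str
    smiles: str


@dataclass(frozen=True)
class TargetRecord:
    target_id: str
    sequence: str

    def validate(self) -> None:
        if len(self.sequence) < MIN_SEQUENCE_LENGTH:
            raise ValidationError(
                f"target {self.target_id!r}: sequence length {len(self.sequence)} "
                f"is below the minimum {MIN_SEQUENCE_LENGTH} required by lag-30 descriptors"
            )
        bad = set(self.sequence) - STANDARD_RESIDUES
        if bad:
            raise ValidationError(
                f"target {self.target_id!r}: non-standard residues {sorted(bad)}"
            )


@dataclass(frozen=True)
class InteractionRecord:
    ligand_id: str
    target_id: str
    affinity_value: float
    affinity_type: AffinityType
    qualifier: Qualifier = Qualifier.exact

    @property
    def pair(self) -> tuple[str, str]:
        return (self.ligand_id, self.target_id)


@dataclass
class InteractionTable:
    records: list[InteractionRecord]
    ligands: dict[str, LigandRecord] = field(default_factory=dict)
    targets: dict[str, TargetRecord] = field(default_factory=dict)
    affinity_type: AffinityType = AffinityType.Kd

    def __len__(self) -> int:
        return len(self.records)

    def pair_keys(self) -> set[tuple[str, str]]:
        return {r.pair for r in self.records}

    def restrict(self, records: list[InteractionRecord]) -> "InteractionTable":
        keep_l = {r.ligand_id for r in records}
        keep_t = {r.target_id for r in records}
        return InteractionTable(
            records=records,
            ligands={k: v for k, v in self.ligands.items() if k in keep_l},
            targets={k: v for k, v in self.targets.items() if k in keep_t},
            affinity_type=self.affinity_type,
        )


DEFAULT_SCHEMA = {
    "ligand_id": "ligand_id",
    "target_id": "target_id",
    "value": "value",
    "qualifier": "qualifier",  # optional in the file
}


def _parse_value(raw, row_idx: int) -> tuple[float, Qualifier]:
    qualifier = Qualifier.exact
    if isinstance(raw, str):
        stripped = raw.strip()
        if stripped[:1] in {">", "<"}:
            qualifier = Qualifier.censored
            stripped = stripped[1:]
        try:
            value = float(stripped)
        except ValueError as exc:
            raise ValidationError(f"row {row_idx}: unparseable affinity value {raw!r}") from exc
    else:
        value = float(raw)
    if not math.isfinite(value) or value <= 0:
        raise ValidationError(f"row {row_idx}: non-positive affinity value {raw!r}")
    return value, qualifier


def read_interaction_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    affinity_type: AffinityType | str = AffinityType.Kd,
) -> InteractionTable:
    """Parse a CSV/TSV affinity table into an :class:`InteractionTable`.

    ``schema`` maps the logical column roles (``ligand_id``, ``target_id``,
    ``value`` and optionally ``qualifier``) onto the file's column names.
    Censored values written as ``<5`` / ``>10000`` are flagged, not dropped.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    affinity_type = AffinityType(affinity_type)
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    for role in ("ligand_id", "target_id", "value"):
        if schema[role] not in df.columns:
            raise SchemaError(
                f"{path.name}: required column {schema[role]!r} (role {role}) missing; "
                f"found {list(df.columns)}"
            )
    has_qual = schema.get("qualifier") in df.columns
    records = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        rowd = dict(zip(df.columns, row))
        value, qualifier = _parse_value(rowd[schema["value"]], idx)
        if has_qual and isinstance(rowd[schema["qualifier"]], str):
            q = rowd[schema["qualifier"]].strip().lower()
            if q in {"censored", "<", ">"}:
                qualifier = Qualifier.censored
        records.append(
            InteractionRecord(
                ligand_id=str(rowd[schema["ligand_id"]]).strip(),
                target_id=str(rowd[schema["target_id"]]).strip(),
                affinity_value=value,
                affinity_type=affinity_type,
                qualifier=qualifier,
            )
        )
    logger.info("%s: parsed %d interaction records", path.name, len(records))
    return InteractionTable(records=records, affinity_type=affinity_type)


def read_smiles_table(
    path: str | Path,
    ligand_id_col: str = "ligand_id",
    smiles_col: str = "smiles",
) -> dict[str, LigandRecord]:
    """Read a two-column ligand table keyed by ligand id."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in (ligand_id_col, smiles_col):
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing column {col!r}")
    out = {}
    for _, row in df.iterrows():
        lid = str(row[ligand_id_col]).strip()
        if lid in out:
            raise ValidationError(f"{path.name}: duplicate ligand id {lid!r}")
        out[lid] = LigandRecord(ligand_id=lid, smiles=str(row[smiles_col]).strip())
    return out


def read_fasta(
    path: str | Path,
    nonstandard_policy: str = "drop",
) -> list[TargetRecord]:
    """Read targets from multi-FASTA; the first header token becomes the id.

    Sequences are uppercased.  Residues outside the 20 standard letters
    (B, J, O, U, X, Z, gaps) are handled per ``nonstandard_policy``:
    ``"drop"`` excludes the whole record with a warning, ``"keep"`` retains
    the record unmodified (descriptor computation will reject it later).
    """
    if nonstandard_policy not in {"drop", "keep"}:
        raise ValueError(f"unknown nonstandard_policy {nonstandard_policy!r}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("*", "")
        if not seq:
            raise ValidationError(f"empty sequence for FASTA header {rec.description!r}")
        nonstd = set(seq) - STANDARD_RESIDUES
        if nonstd and nonstandard_policy == "drop":
            logger.warning(
                "dropping target %s: non-standard residues %s", rec.id, sorted(nonstd)
            )
            continue
        records.append(TargetRecord(target_id=rec.id, sequence=seq))
    return records


def deduplicate(table: InteractionTable, tolerance: float = 1.0) -> InteractionTable:
    """Remove redundant affinity records.

    Censored records ("no definite value") are dropped first.  Exact records
    sharing a (ligand, target) pair collapse to the median of their linear
    values when their log2 spread is within ``tolerance`` log2 units;
    inconsistent pairs (spread above tolerance) are removed entirely.
    Idempotent, and never invents a value outside the pair's observed range.
    """
    exact = [r for r in table.records if r.qualifier is Qualifier.exact]
    n_censored = len(table.records) - len(exact)

    by_pair: dict[tuple[str, str], list[InteractionRecord]] = {}
    for r in exact:
        by_pair.setdefault(r.pair, []).append(r)

    kept: list[InteractionRecord] = []
    n_inconsistent = 0
    for recs in by_pair.values():
        if len(recs) == 1:
            kept.append(recs[0])
            continue
        logs = [math.log2(r.affinity_value) for r in recs]
        if max(logs) - min(logs) > tolerance:
            n_inconsistent += 1
            continue
        median = statistics.median(r.affinity_value for r in recs)
        kept.append(replace(recs[0], affinity_value=median))

    logger.info(
        "deduplicate: %d censored removed, %d inconsistent pairs removed, %d records kept",
        n_censored, n_inconsistent, len(kept),
    )
    return table.restrict(kept)


def attach(
    table: InteractionTable,
    ligands: Iterable[LigandRecord] | Mapping[str, LigandRecord],
    targets: Iterable[TargetRecord] | Mapping[str, TargetRecord],
    strict: bool = True,
) -> InteractionTable:
    """Attach ligand/target records to a parsed interaction table.

    With ``strict`` every interaction id must resolve; otherwise unresolved
    records are dropped with a warning.
    """
    lig = dict(ligands) if isinstance(ligands, Mapping) else {l.ligand_id: l for l in ligands}
    tgt = dict(targets) if isinstance(targets, Mapping) else {t.target_id: t for t in targets}
    missing_l = {r.ligand_id for r in table.records} - set(lig)
    missing_t = {r.target_id for r in table.records} - set(tgt)
    if (missing_l or missing_t) and strict:
        raise ValidationError(
            f"unresolved ids: ligands {sorted(missing_l)[:5]}, targets {sorted(missing_t)[:5]}"
        )
    records = [
        r for r in table.records if r.ligand_id in lig and r.target_id in tgt
    ]
    if len(records) < len(table.records):
        logger.warning("attach: dropped %d records with unresolved ids",
                       len(table.records) - len(records))
    return InteractionTable(
        records=records, ligands=lig, targets=tgt, affinity_type=table.affinity_type
    )
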