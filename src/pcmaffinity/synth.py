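"""Synthetic ligand/target/affinity generator with planted ground truth.

The generator emits the same artefacts the real loaders read -- a SMILES
table, a multi-FASTA of targets and a ligand-target affinity CSV -- but
with a known generating model: log2 affinity is a linear function of k
randomly chosen (molecular + protein) descriptor columns, standardised,
plus Gaussian noise.  Because the planted model is linear in descriptor
space rather than in chemical structure, the ground truth stays exact no
matter which descriptor engine produced the columns, which is what makes
end-to-end recovery testable.

All randomness flows from one seed through named substreams (targets,
ligands, pairs, coefficients, noise).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from pcmaffinity._fixtures import AA_ORDER
from pcmaffinity.data_model import (
    AffinityType,
    InteractionRecord,
    InteractionTable,
    LigandRecord,
    TargetRecord,
)
from pcmaffinity.featureset import MOL_ORIGIN, PROT_ORIGIN

_MID_SEGMENTS = [
    "C", "CC", "CCC", "C(C)C", "C(=O)", "O", "N", "S",
    "c1ccccc1", "c1ccncc1", "C1CCCCC1", "c1ccsc1", "C=C",
]
_TERMINALS = ["O", "N", "Cl", "F", "Br", "C#N", "C(=O)O", "C(=O)N", "C", "OC"]


@dataclass(frozen=True)
class SynthConfig:
    n_ligands: int = 120
    n_targets: int = 80
    n_pairs: int = 500
    sequence_length: tuple[int, int] = (40, 60)
    k_informative: int = 10
    beta: float = 1.0
    sigma: float = 0.3
    affinity_type: AffinityType = AffinityType.Kd
    seed: int = 0

    def __post_init__(self):
        if self.n_pairs > self.n_ligands * self.n_targets:
            raise ValueError("n_pairs exceeds the number of distinct ligand-target pairs")
        if self.sequence_length[0] < 31:
            raise ValueError("sequences must be at least 31 residues for lag-30 descriptors")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    informative_features: tuple[str, ...]
    coefficients: dict[str, float]
    sigma: float
    description: str = "log2_affinity = sum_j beta_j * z(x_j) + sigma * eps"

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "informative_features": list(self.informative_features),
            "coefficients": self.coefficients,
            "sigma": self.sigma,
            "description": self.description,
        }, indent=2))


def _stream(seed: int, name: str) -> np.random.RandomState:
    return np.random.RandomState(
        (int(seed) * 2654435761 + zlib.crc32(name.encode())) % (2**31 - 1)
    )


def generate_targets(config: SynthConfig) -> list[TargetRecord]:
    """I.i.d.-uniform random sequences over the 20 standard residues."""
    rng = _stream(config.seed, "targets")
    lo, hi = config.sequence_length
    records = []
    for i in range(config.n_targets):
        length = rng.randint(lo, hi + 1)
        seq = "".join(rng.choice(list(AA_ORDER), size=length))
        records.append(TargetRecord(target_id=f"T{i:04d}", sequence=seq))
    return records


def _random_smiles(rng: np.random.RandomState) -> str:
    n_seg = rng.randint(1, 5)
    parts = [str(rng.choice(_MID_SEGMENTS)) for _ in range(n_seg)]
    parts.append(str(rng.choice(_TERMINALS)))
    return "".join(parts)


def generate_ligands(config: SynthConfig) -> list[LigandRecord]:
    """Parseable SMILES from a segment-concatenation template family."""
    rng = _stream(config.seed, "ligands")
    records, seen = [], set()
    while len(records) < config.n_ligands:
        smi = _random_smiles(rng)
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        canonical = Chem.MolToSmiles(mol)
        if canonical in seen:
            continue
        seen.add(canonical)
        records.append(LigandRecord(ligand_id=f"L{len(records):04d}", smiles=smi))
    return records


def generate_affinities(
    ligands: list[LigandRecord],
    targets: list[TargetRecord],
    config: SynthConfig,
    mol_matrix: pd.DataFrame | None = None,
    prot_matrix: pd.DataFrame | None = None,
) -> tuple[InteractionTable, GroundTruth]:
    """Sample unique pairs and plant a linear descriptor model in the response.

    Descriptor matrices are computed with the package defaults (whitelisted
    molecular block, full protein block) unless supplied.  Informative
    columns are drawn half from the molecular and half from the protein
    block, restricted to finite, non-constant columns over the sampled rows;
    degenerate draws are resampled.  Affinities are stored on the linear
    scale as 2**y.
    """
    from pcmaffinity.moldesc import (
        apply_vibration_filter, load_whitelist, molecular_descriptor_matrix,
    )
    from pcmaffinity.protdesc import protein_descriptor_matrix

    if mol_matrix is None:
        full, excluded = molecular_descriptor_matrix(ligands)
        if excluded:
            raise ValueError(f"generated ligands failed descriptor computation: {excluded}")
        mol_matrix, _ = apply_vibration_filter(full, load_whitelist())
    if prot_matrix is None:
        prot_matrix = protein_descriptor_matrix(targets)

    rng_pairs = _stream(config.seed, "pairs")
    all_pairs = [(l.ligand_id, t.target_id) for l in ligands for t in targets]
    chosen = [all_pairs[i] for i in
              rng_pairs.choice(len(all_pairs), size=config.n_pairs, replace=False)]

    lig_rows = mol_matrix.loc[[p[0] for p in chosen]].reset_index(drop=True)
    tgt_rows = prot_matrix.loc[[p[1] for p in chosen]].reset_index(drop=True)
    blocks = {MOL_ORIGIN: lig_rows, PROT_ORIGIN: tgt_rows}

    rng_coef = _stream(config.seed, "coefficients")
    k = config.k_informative
    n_mol = k // 2
    quota = {MOL_ORIGIN: n_mol, PROT_ORIGIN: k - n_mol}
    informative, zcols = [], []
    for origin, block in blocks.items():
        arr = block.to_numpy(float)
        finite = np.isfinite(arr).all(axis=0)
        sd = np.nanstd(arr, axis=0)
        usable = np.flatnonzero(finite & (sd > 1e-9))
        if len(usable) < quota[origin]:
            raise ValueError(f"not enough usable {origin} descriptor columns")
        picks = rng_coef.choice(usable, size=quota[origin], replace=False)
        for j in picks:
            col = arr[:, j]
            informative.append(str(block.columns[j]))
            zcols.append((col - col.mean()) / col.std())

    signs = rng_coef.choice([-1.0, 1.0], size=k)
    coefficients = dict(zip(informative, (signs * config.beta).tolist()))
    y = np.zeros(config.n_pairs)
    for z, name in zip(zcols, informative):
        y += coefficients[name] * z
    rng_noise = _stream(config.seed, "noise")
    y += config.sigma * rng_noise.normal(size=config.n_pairs)

    records = [
        InteractionRecord(
            ligand_id=l, target_id=t, affinity_value=float(2.0**yi),
            affinity_type=config.affinity_type,
        )
        for (l, t), yi in zip(chosen, y)
    ]
    table = InteractionTable(
        records=records,
        ligands={l.ligand_id: l for l in ligands},
        targets={t.target_id: t for t in targets},
        affinity_type=config.affinity_type,
    )
    truth = GroundTruth(
        informative_features=tuple(informative),
        coefficients=coefficients,
        sigma=config.sigma,
    )
    return table, truth


def planted_selection_benchmark(
    n: int = 400,
    k: int = 10,
    n_noise: int = 100,
    beta: float = 1.0,
    sigma: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Matrix-level planted benchmark for feature selection.

    k informative standard-normal columns drive a linear response; the
    noise block holds row-permuted copies of the informative columns
    (cycled), so marginals match but association with y is destroyed.
    Returns (X, y, informative column names).
    """
    rng = _stream(seed, "planted")
    info = rng.normal(size=(n, k))
    noise = np.empty((n, n_noise))
    for j in range(n_noise):
        noise[:, j] = info[rng.permutation(n), j % k]
    signs = rng.choice([-1.0, 1.0], size=k)
    y = info @ (signs * beta) + sigma * rng.normal(size=n)
    cols = [f"info_{j}" for j in range(k)] + [f"noise_{j}" for j in range(n_noise)]
    X = pd.DataFrame(np.hstack([info, noise]), columns=cols)
    return X, y, cols[:k]


def write_dataset(config: SynthConfig, outdir: str | Path) -> dict[str, Path]:
    """Write interactions.csv, ligands.csv, targets.fasta and ground_truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ligands = generate_ligands(config)
    targets = generate_targets(config)
    table, truth = generate_affinities(ligands, targets, config)

    paths = {
        "interactions": outdir / "interactions.csv",
        "ligands": outdir / "ligands.csv",
        "targets": outdir / "targets.fasta",
        "ground_truth": outdir / "ground_truth.json",
    }
    pd.DataFrame(
        {
            "ligand_id": [r.ligand_id for r in table.records],
            "target_id": [r.target_id for r in table.records],
            "value": [r.affinity_value for r in table.records],
        }
    ).to_csv(paths["interactions"], index=False)
    pd.DataFrame(
        {"ligand_id": [l.ligand_id for l in ligands],
         "smiles": [l.smiles for l in ligands]}
    ).to_csv(paths["ligands"], index=False)
    with open(paths["targets"], "w") as fh:
        for t in targets:
            fh.write(f">{t.target_id}\n{t.sequence}\n")
    truth.to_json(paths["ground_truth"])
    return paths
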