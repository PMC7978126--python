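"""Reading and writing cohorts, and run configuration.

On-disk layout of a cohort directory::

    phenotypes.csv   subject_id, group, age, sex, <confounders/scores...>
    parcels.csv      node_id, label, module
    matrices/<subject_id>.txt   whitespace-delimited square Fisher-z matrix
    manifest.json    subject -> matrix file map, seed, node count

Empty phenotype cells are missing values. Matrices asymmetric beyond a
tolerance are rejected with the offending indices; asymmetry within
tolerance is symmetrized by averaging. Subjects present in the phenotype
table without a matrix are retained for phenotype-only analyses and
reported.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort

SYMMETRY_TOL = 1e-8


def write_cohort(cohort: Cohort, directory) -> dict:
    """Write a cohort to ``directory``; returns (and writes) the manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pheno = cohort.phenotypes.copy()
    pheno.index.name = "subject_id"
    pheno.to_csv(directory / "phenotypes.csv")
    if cohort.parcels is not None:
        cohort.parcels.to_csv(directory / "parcels.csv", index=False)
    matrix_files = {}
    if cohort.matrices:
        (directory / "matrices").mkdir(exist_ok=True)
        for sid, mat in cohort.matrices.items():
            fname = f"matrices/{sid}.txt"
            np.savetxt(directory / fname, mat, fmt="%.17g")
            matrix_files[sid] = fname
    manifest = {
        "phenotypes": "phenotypes.csv",
        "parcels": "parcels.csv" if cohort.parcels is not None else None,
        "matrices": matrix_files,
        "seed": cohort.seed,
        "n_subjects": len(cohort.phenotypes),
        "n_nodes": cohort.n_nodes,
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="subject_id")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate subject ids in phenotype table: {dups}")
    return df


def read_parcels(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"node_id", "label", "module"} - set(df.columns)
    if missing:
        raise ValueError(f"parcel table missing columns: {sorted(missing)}")
    return df


def read_matrix(path, n_nodes: int | None = None, tol: float = SYMMETRY_TOL) -> np.ndarray:
    """One delimited square matrix; symmetrized by averaging within ``tol``."""
    mat = np.loadtxt(path, delimiter="," if str(path).endswith(".csv") else None)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{path}: expected a square matrix, got {mat.shape}")
    if n_nodes is not None and mat.shape[0] != n_nodes:
        raise ValueError(
            f"{path}: {mat.shape[0]} nodes does not match parcel table ({n_nodes})"
        )
    delta = np.abs(mat - mat.T)
    if delta.max(initial=0.0) > tol:
        i, j = np.unravel_index(np.argmax(delta), delta.shape)
        raise ValueError(
            f"{path}: asymmetric beyond {tol:g} at ({i}, {j}): "
            f"{mat[i, j]!r} vs {mat[j, i]!r}"
        )
    sym = (mat + mat.T) / 2.0
    np.fill_diagonal(sym, 0.0)
    return sym


def read_cohort(directory) -> tuple[Cohort, dict]:
    """Load a cohort directory; returns the cohort and a reconciliation
    report listing subjects without matrices and orphan matrix files."""
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    pheno = read_phenotypes(directory / manifest["phenotypes"])
    parcels = (
        read_parcels(directory / manifest["parcels"]) if manifest.get("parcels") else None
    )
    n_nodes = len(parcels) if parcels is not None else None
    matrices = {}
    orphans = []
    for sid, fname in manifest.get("matrices", {}).items():
        if sid not in pheno.index:
            orphans.append(sid)
            continue
        matrices[sid] = read_matrix(directory / fname, n_nodes=n_nodes)
    no_matrix = [s for s in pheno.index if s not in matrices]
    report = {"subjects_without_matrix": no_matrix, "orphan_matrices": orphans}
    cohort = Cohort(
        phenotypes=pheno, matrices=matrices, parcels=parcels, seed=manifest.get("seed")
    )
    return cohort, report


@dataclass
class RunConfig:
    """End-to-end analysis configuration (YAML-serialisable)."""

    data_dir: str = "."
    output_dir: str = "netphen_out"
    # preparation
    confounders: tuple[str, ...] = ()
    transforms: dict[str, str] = field(default_factory=dict)
    measures: tuple[str, ...] = ()          # phenotype columns to compare
    anchor_test: str | None = None          # sign anchor for the g factor
    sd_cut: float = 4.0
    subject_cut: int | None = None          # None = scale with edge count
    # inference
    family_priors: dict[str, float] = field(default_factory=dict)
    nbs_thresholds: tuple[float, ...] = (15.0, 16.0, 17.0)
    nbs_statistic: str = "intensity"
    nbs_n_perm: int = 5000
    density_max: int = 40
    curve_n_perm: int = 50000
    louvain_restarts: int = 10
    seed: int = 0
    run_graph_metrics: bool = True
    graph_metrics: tuple[str, ...] = (
        "global_efficiency",
        "modularity",
        "clustering",
        "strength",
        "degree",
        "participation",
    )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for name in ("confounders", "measures", "nbs_thresholds", "graph_metrics"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def validate_columns(self, phenotypes: pd.DataFrame) -> None:
        cols = set(phenotypes.columns)
        referenced = set(self.confounders) | set(self.measures) | set(self.transforms)
        if self.anchor_test:
            referenced.add(self.anchor_test)
        missing = referenced - cols
        if missing:
            raise ValueError(
                f"config references missing phenotype columns: {sorted(missing)}"
            )
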