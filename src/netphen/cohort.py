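"""In-memory containers for a two-group connectome/phenotype cohort.

A :class:`Cohort` couples a phenotype table (one row per subject: group
label, covariates, cognitive scores) with optional per-subject
:class:`Connectome` matrices on the Fisher-z scale and a parcel table
assigning each node to a resting-state module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import check_symmetric

GROUP_CASE = "case"
GROUP_CONTROL = "control"


@dataclass
class Connectome:
    """Symmetric Fisher-z connectivity matrix over labeled parcels.

    The diagonal is undefined and never read; it is stored as zero by
    convention. ``modules`` maps each node to a module id.
    """

    z: np.ndarray
    node_labels: list[str] = field(default_factory=list)
    modules: np.ndarray | None = None

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        check_symmetric(self.z)
        n = self.z.shape[0]
        if not self.node_labels:
            self.node_labels = [f"node{i:03d}" for i in range(n)]
        if len(self.node_labels) != n:
            raise ValueError(
                f"{len(self.node_labels)} labels for {n} nodes"
            )
        if self.modules is not None:
            self.modules = np.asarray(self.modules)
            if self.modules.shape != (n,):
                raise ValueError("module assignment length must match node count")

    @property
    def n_nodes(self) -> int:
        return self.z.shape[0]


@dataclass
class Cohort:
    """Phenotype table plus optional per-subject connectomes.

    ``phenotypes`` is indexed by subject id and must contain a ``group``
    column with values ``"case"``/``"control"``; remaining columns are
    covariates, confounders and test scores (NaN = missing).
    ``parcels`` has columns ``node_id``, ``label``, ``module``.
    """

    phenotypes: pd.DataFrame
    matrices: dict[str, np.ndarray] = field(default_factory=dict)
    parcels: pd.DataFrame | None = None
    seed: int | None = None

    def __post_init__(self):
        idx = self.phenotypes.index
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].tolist()
            raise ValueError(f"duplicate subject ids: {dups}")
        if "group" not in self.phenotypes.columns:
            raise ValueError("phenotype table must have a 'group' column")
        bad = set(self.phenotypes["group"]) - {GROUP_CASE, GROUP_CONTROL}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        unknown = set(self.matrices) - set(idx)
        if unknown:
            raise ValueError(f"matrices for unknown subjects: {sorted(unknown)}")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.phenotypes.index)

    @property
    def groups(self) -> pd.Series:
        return self.phenotypes["group"]

    @property
    def n_nodes(self) -> int | None:
        if self.parcels is not None:
            return len(self.parcels)
        if self.matrices:
            return next(iter(self.matrices.values())).shape[0]
        return None

    @property
    def module_of(self) -> np.ndarray | None:
        if self.parcels is None:
            return None
        return self.parcels["module"].to_numpy()

    def imaging_subset(self) -> "Cohort":
        """Subjects that have a connectome, in phenotype-table order."""
        ids = [s for s in self.subject_ids if s in self.matrices]
        return Cohort(
            phenotypes=self.phenotypes.loc[ids],
            matrices={s: self.matrices[s] for s in ids},
            parcels=self.parcels,
            seed=self.seed,
        )

    def connectome_stack(self) -> tuple[list[str], np.ndarray]:
        """Subject ids and a (n_subjects, n_nodes, n_nodes) array of matrices."""
        sub = self.imaging_subset()
        ids = sub.subject_ids
        if not ids:
            raise ValueError("cohort has no connectomes")
        return ids, np.stack([sub.matrices[s] for s in ids])
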