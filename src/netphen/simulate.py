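"""Synthetic two-group connectome/phenotype cohorts.

The generator produces data with the statistical structure the downstream
analysis assumes: modular Fisher-z connectivity with independent Gaussian
edge noise, an additive covariate signal, a group effect planted on one
connected edge component, heavy-tailed edge outliers, an optional
subject-level global additive term (its absence emulates global-signal-
regressed data), and multi-test phenotype scores loading on a single
latent general factor that is shifted in cases.

Defaults mirror the study conditions the analysis was designed for: a
community sample with roughly a 1:2.6 case:control ratio, ages 18-70, and
a 382-parcel connectome organised into resting-state modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import as_rng, n_edges, triu_indices, vec_to_sym
from .cohort import GROUP_CASE, GROUP_CONTROL, Cohort

_DEFAULT_PHENOTYPES = {
    # latent-factor loadings for a compact multi-domain battery
    "verbal_iq": 0.7,
    "verbal_memory": 0.65,
    "working_memory": 0.6,
    "processing_speed": 0.55,
    "attention": 0.5,
    "motor_speed": 0.45,
}


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort generator.

    Connectivity units are Fisher-z throughout. ``effect_delta`` is added
    to the planted edges of cases only, so the control expectation of a
    planted edge stays at its base value. ``covariate_betas`` are slopes
    per standard deviation of the named covariate, applied additively to
    every edge. ``global_amp_sd`` is the SD of a subject-level constant
    added to all edges (0 = GSR-like data). ``phenotype_effect`` shifts
    the latent general factor of cases, in factor-SD units.
    """

    n_case: int = 39
    n_control: int = 92
    n_nodes: int = 382
    module_sizes: tuple[int, ...] | None = None
    n_modules: int = 12
    base_within_z: float = 0.30
    base_between_z: float = 0.05
    planted_edges: tuple[tuple[int, int], ...] = ()
    effect_delta: float = 0.0
    edge_noise_sd: float = 0.10
    covariate_betas: dict[str, float] = field(default_factory=dict)
    global_amp_sd: float = 0.0
    outlier_rate: float = 0.0
    phenotype_loadings: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PHENOTYPES)
    )
    phenotype_effect: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.module_sizes is None:
            base, rem = divmod(self.n_nodes, self.n_modules)
            self.module_sizes = tuple(
                base + (1 if k < rem else 0) for k in range(self.n_modules)
            )
        self.module_sizes = tuple(int(s) for s in self.module_sizes)
        self.n_modules = len(self.module_sizes)
        if sum(self.module_sizes) != self.n_nodes:
            raise ValueError(
                f"module_sizes sum to {sum(self.module_sizes)}, expected {self.n_nodes}"
            )
        if any(s <= 0 for s in self.module_sizes):
            raise ValueError("module sizes must be positive")
        self.planted_edges = tuple(
            (min(i, j), max(i, j)) for i, j in self.planted_edges
        )
        for i, j in self.planted_edges:
            if i == j or not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes):
                raise ValueError(f"planted edge ({i}, {j}) is not a valid node pair")
        if self.planted_edges and not _is_connected(self.planted_edges):
            raise ValueError("planted edges must induce a single connected component")
        if not 0.0 <= self.outlier_rate < 1.0:
            raise ValueError("outlier_rate must lie in [0, 1)")
        if min(self.n_case, self.n_control) < 1:
            raise ValueError("both groups must be nonempty")

    @property
    def module_assignment(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_modules), self.module_sizes)


def _is_connected(edges) -> bool:
    nodes = sorted({v for e in edges for v in e})
    parent = {v: v for v in nodes}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for i, j in edges:
        parent[find(i)] = find(j)
    return len({find(v) for v in nodes}) == 1


def simulate_cohort(spec: CohortSpec) -> Cohort:
    """Draw one cohort. Deterministic given ``spec.seed``.

    Edge model per subject s and edge e::

        z[s, e] = base[e] + delta * planted[e] * case[s]
                  + sum_c beta_c * x_sc + g_s + noise

    with ``x_sc`` the z-scored covariate, ``g_s ~ N(0, global_amp_sd)``
    the subject-global term, and noise either ``N(0, edge_noise_sd)`` or,
    for the ``outlier_rate`` fraction of subject-edges, a heavy-tailed
    Student-t(2) deviate scaled by ``4 * edge_noise_sd`` so that >4 SD
    events occur at a controllable rate.
    """
    rng = as_rng(spec.seed)
    n = spec.n_case + spec.n_control
    ids = [f"sub{k:04d}" for k in range(n)]
    group = np.array([GROUP_CASE] * spec.n_case + [GROUP_CONTROL] * spec.n_control)
    is_case = (group == GROUP_CASE).astype(float)

    age = rng.uniform(18.0, 70.0, size=n)
    sex = rng.binomial(1, 0.45, size=n).astype(float)

    covariates = {"age": age, "sex": sex}
    for name in spec.covariate_betas:
        if name not in covariates:
            covariates[name] = rng.standard_normal(n)

    # --- phenotypes: single latent general factor -------------------------
    latent = rng.standard_normal(n) + spec.phenotype_effect * is_case
    scores = {}
    for test, loading in spec.phenotype_loadings.items():
        unique_sd = np.sqrt(max(0.0, 1.0 - loading**2))
        scores[test] = loading * latent + unique_sd * rng.standard_normal(n)

    # --- connectomes ------------------------------------------------------
    modules = spec.module_assignment
    ii, jj = triu_indices(spec.n_nodes)
    within = modules[ii] == modules[jj]
    base = np.where(within, spec.base_within_z, spec.base_between_z)
    m = n_edges(spec.n_nodes)
    edge_index = {(int(a), int(b)): k for k, (a, b) in enumerate(zip(ii, jj))}
    planted_idx = np.array(
        [edge_index[e] for e in spec.planted_edges], dtype=int
    )

    def zscore(x):
        sd = x.std(ddof=0)
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    covar_shift = np.zeros(n)
    for name, beta in spec.covariate_betas.items():
        covar_shift += beta * zscore(covariates[name])

    matrices = {}
    for s in range(n):
        ez = base.copy()
        if planted_idx.size and is_case[s]:
            ez[planted_idx] += spec.effect_delta
        noise = rng.normal(0.0, spec.edge_noise_sd, size=m)
        if spec.outlier_rate > 0:
            mask = rng.random(m) < spec.outlier_rate
            k = int(mask.sum())
            if k:
                noise[mask] = rng.standard_t(df=2, size=k) * 4 * spec.edge_noise_sd
        vec = ez + covar_shift[s] + noise
        if spec.global_amp_sd > 0:
            vec = vec + rng.normal(0.0, spec.global_amp_sd)
        matrices[ids[s]] = vec_to_sym(vec, spec.n_nodes)

    pheno = pd.DataFrame({"group": group, "age": age, "sex": sex}, index=ids)
    pheno.index.name = "subject_id"
    for name in spec.covariate_betas:
        if name not in ("age", "sex"):
            pheno[name] = covariates[name]
    for test, vals in scores.items():
        pheno[test] = vals

    parcels = pd.DataFrame(
        {
            "node_id": np.arange(spec.n_nodes),
            "label": [f"node{i:03d}" for i in range(spec.n_nodes)],
            "module": modules,
        }
    )
    return Cohort(phenotypes=pheno, matrices=matrices, parcels=parcels, seed=spec.seed)
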