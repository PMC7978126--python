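"""Density-thresholded signed graph metrics and the area-between-curves
group comparison.

Graph metrics depend strongly on density, so graphs are matched across
subjects by retaining the same number of strongest positive (or
negative) edges at each density in a 1-40% grid. Efficiency, degree and
clustering are computed on the binarized thresholded graph, strength on
the magnitudes of retained weights. Modularity (signed Louvain with the
asymmetric negative penalty) and participation coefficient are computed
on the union of the positive and negative thresholded graphs, whose
density is therefore twice that of the single-sign metrics.

Each metric traced over the density grid forms a curve per subject; the
group difference is the area between group mean curves, tested by
permutation of group membership, with regional (per-node) p-values
FDR-corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from ._utils import as_rng, n_edges, sym_to_vec, triu_indices
from .cohort import GROUP_CASE, GROUP_CONTROL
from .compare import bh_fdr, cohens_d

GLOBAL_METRICS = ("global_efficiency", "modularity")
REGIONAL_METRICS = ("degree", "strength", "clustering", "participation")
ALL_METRICS = GLOBAL_METRICS + REGIONAL_METRICS

DEFAULT_MAX_DENSITY = 40


@dataclass
class DensityGrid:
    """Density percentages and edge sign for thresholded-graph analysis."""

    percents: tuple[int, ...] = tuple(range(1, DEFAULT_MAX_DENSITY + 1))
    sign: str = "positive"

    def __post_init__(self):
        self.percents = tuple(int(p) for p in self.percents)
        if not self.percents or any(p < 1 for p in self.percents):
            raise ValueError("density percents must be positive integers")
        if list(self.percents) != sorted(self.percents):
            raise ValueError("density percents must be increasing")
        if self.sign not in ("positive", "negative", "union"):
            raise ValueError("sign must be 'positive', 'negative' or 'union'")

    def edges_at(self, percent: int, n_nodes: int) -> int:
        k = int(np.floor(percent / 100 * n_edges(n_nodes)))
        return 2 * k if self.sign == "union" else k


def density_upper_bound(matrices, sign: str, cap: int = DEFAULT_MAX_DENSITY) -> int:
    """Largest whole-percent density feasible for *every* subject.

    A subject's feasible density for a sign is the fraction of possible
    edges carrying that sign; the bound is the floor of the cohort
    minimum, capped. Guarantees each subject has enough same-sign edges
    at every grid density up to the bound.
    """
    if isinstance(matrices, dict):
        matrices = list(matrices.values())
    if len(matrices) == 0:
        raise ValueError("need at least one subject")
    signs = ("positive", "negative") if sign == "union" else (sign,)
    bound = cap
    for s, mat in enumerate(matrices):
        v = sym_to_vec(np.asarray(mat))
        for sg in signs:
            frac = (v > 0).mean() if sg == "positive" else (v < 0).mean()
            if frac == 0:
                raise ValueError(
                    f"subject index {s} has no {sg} edges; cannot build {sg} graphs"
                )
            bound = min(bound, int(np.floor(100 * frac)))
    return bound


@dataclass
class ThresholdedGraph:
    """Top-k same-sign edges of one connectome at a density threshold."""

    n_nodes: int
    sign: str
    density_percent: int
    edge_idx: np.ndarray       # indices into the upper-triangle edge vector
    edge_values: np.ndarray    # signed Fisher-z of retained edges

    @property
    def adjacency(self) -> np.ndarray:
        ii, jj = triu_indices(self.n_nodes)
        A = np.zeros((self.n_nodes, self.n_nodes))
        A[ii[self.edge_idx], jj[self.edge_idx]] = 1.0
        return A + A.T

    @property
    def weight_matrix(self) -> np.ndarray:
        ii, jj = triu_indices(self.n_nodes)
        W = np.zeros((self.n_nodes, self.n_nodes))
        W[ii[self.edge_idx], jj[self.edge_idx]] = self.edge_values
        return W + W.T


def threshold_graph(z: np.ndarray, density_percent: int, sign: str) -> ThresholdedGraph:
    """Retain the k = floor(density% x possible) strongest same-sign edges.

    Strength is signed magnitude (most positive / most negative first);
    exact ties at the cutoff are broken by lexicographic edge index, so
    the result is reproducible. For ``sign='union'`` the positive and
    negative edge sets are merged (2k edges).
    """
    z = np.asarray(z, dtype=float)
    n = z.shape[0]
    if sign == "union":
        pos = threshold_graph(z, density_percent, "positive")
        neg = threshold_graph(z, density_percent, "negative")
        idx = np.concatenate([pos.edge_idx, neg.edge_idx])
        vals = np.concatenate([pos.edge_values, neg.edge_values])
        order = np.argsort(idx)
        return ThresholdedGraph(n, "union", density_percent, idx[order], vals[order])
    v = sym_to_vec(z)
    m = v.size
    k = int(np.floor(density_percent / 100 * m))
    if k < 1:
        raise ValueError(
            f"density {density_percent}% retains zero edges on {n} nodes"
        )
    eligible = np.flatnonzero(v > 0) if sign == "positive" else np.flatnonzero(v < 0)
    if k > eligible.size:
        raise ValueError(
            f"density {density_percent}% needs {k} {sign} edges, "
            f"subject has only {eligible.size}"
        )
    key = -v[eligible] if sign == "positive" else v[eligible]
    order = np.lexsort((eligible, key))  # primary: strength; tie: edge index
    idx = np.sort(eligible[order[:k]])
    return ThresholdedGraph(n, sign, density_percent, idx, v[idx])


# ---------------------------------------------------------------------------
# metrics on a thresholded graph


def degree(adj: np.ndarray) -> np.ndarray:
    return np.asarray(adj, dtype=float).sum(axis=1)


def strength(weights: np.ndarray) -> np.ndarray:
    """Sum of retained |weights| per node (sign-agnostic magnitude)."""
    return np.abs(np.asarray(weights, dtype=float)).sum(axis=1)


def clustering(adj: np.ndarray) -> np.ndarray:
    """Binary clustering coefficient: triangle density around each node."""
    A = np.asarray(adj, dtype=float)
    k = A.sum(axis=1)
    tri = ((A @ A) * A).sum(axis=1) / 2.0
    denom = k * (k - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = tri / denom
    return np.where(denom > 0, c, 0.0)


def global_efficiency(adj: np.ndarray) -> float:
    """Mean inverse shortest-path length over ordered node pairs
    (disconnected pairs contribute zero)."""
    A = csr_matrix(np.asarray(adj, dtype=float))
    n = A.shape[0]
    if n < 2:
        return 0.0
    D = shortest_path(A, method="D", unweighted=True, directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum() / (n * (n - 1)))


# ---------------------------------------------------------------------------
# signed modularity (asymmetric) and participation


def _signed_quality_matrix(W: np.ndarray, gamma: float = 1.0) -> np.ndarray:
    Wp = np.where(W > 0, W, 0.0)
    Wn = np.where(W < 0, -W, 0.0)
    vp, vn = Wp.sum(), Wn.sum()
    if vp == 0 and vn == 0:
        raise ValueError("all-zero graph has no modular structure")
    B = np.zeros_like(W, dtype=float)
    if vp > 0:
        kp = Wp.sum(axis=1)
        B += (Wp - gamma * np.outer(kp, kp) / vp) / vp
    if vn > 0:
        kn = Wn.sum(axis=1)
        B -= (Wn - gamma * np.outer(kn, kn) / vn) / (vp + vn)
    return B


def _quality(B: np.ndarray, part: np.ndarray) -> float:
    same = part[:, None] == part[None, :]
    return float(B[same].sum())


def _one_level(B: np.ndarray, rng) -> np.ndarray:
    n = B.shape[0]
    comm = np.arange(n)
    Bn = B - np.diag(np.diag(B))
    M = Bn.copy()  # M[i, c] = sum of Bn[i, j] over j currently in community c
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            ci = comm[i]
            gains = M[i] - M[i, ci]
            best = int(np.argmax(gains))
            if gains[best] > 1e-12 and best != ci:
                M[:, ci] -= Bn[:, i]
                M[:, best] += Bn[:, i]
                comm[i] = best
                improved = True
    return comm


def _relabel(part: np.ndarray) -> np.ndarray:
    _, labels = np.unique(part, return_inverse=True)
    # stable relabeling by first occurrence
    order = {}
    out = np.empty_like(labels)
    nxt = 0
    for k, lab in enumerate(labels):
        if lab not in order:
            order[lab] = nxt
            nxt += 1
        out[k] = order[lab]
    return out


def signed_louvain(
    W: np.ndarray,
    seed=None,
    n_restarts: int = 10,
    gamma: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Louvain community detection maximizing the asymmetric signed quality

        Q* = Q+ - (v-/(v+ + v-)) * Q-

    where Q+/Q- are the modularities of the positive/negative subgraphs and
    v+/v- their total weights, so negative within-module weight is
    penalised but down-weighted. Runs ``n_restarts`` seeded restarts with
    randomized sweep order and keeps the best-quality partition.

    Returns ``(Q*, partition)`` with consecutive community labels.
    """
    W = np.asarray(W, dtype=float)
    B = _signed_quality_matrix(W, gamma)
    rng = as_rng(seed)
    best_q, best_part = -np.inf, None
    for _ in range(max(1, n_restarts)):
        assign = np.arange(B.shape[0])
        Bl = B
        while True:
            comm = _relabel(_one_level(Bl, rng))
            n_comm = comm.max() + 1
            if n_comm == Bl.shape[0]:
                break
            assign = comm[assign]
            S = np.zeros((Bl.shape[0], n_comm))
            S[np.arange(Bl.shape[0]), comm] = 1.0
            Bl = S.T @ Bl @ S
        part = _relabel(assign)
        q = _quality(B, part)
        if q > best_q:
            best_q, best_part = q, part
    return best_q, best_part


def participation(W: np.ndarray, part: np.ndarray) -> np.ndarray:
    """Participation coefficient P_i = 1 - sum_m (k_im / k_i)^2 on the
    positive weights, given a module partition. Nodes with no positive
    strength get 0 (fully within-module by convention)."""
    W = np.asarray(W, dtype=float)
    Wp = np.where(W > 0, W, 0.0)
    part = np.asarray(part)
    k = Wp.sum(axis=1)
    out = np.zeros(W.shape[0])
    nz = k > 0
    for m in np.unique(part):
        km = Wp[:, part == m].sum(axis=1)
        out[nz] += (km[nz] / k[nz]) ** 2
    out[nz] = 1.0 - out[nz]
    return out


# ---------------------------------------------------------------------------
# curves over the density grid


def metric_curves(
    matrices,
    grid: DensityGrid,
    metric: str,
    seed=None,
    n_restarts: int = 10,
) -> np.ndarray:
    """Evaluate one metric at every grid density for every subject.

    Returns ``(n_subjects, n_densities)`` for global metrics and
    ``(n_subjects, n_nodes, n_densities)`` for regional ones. Modularity
    and participation use the union graph and seeded Louvain restarts;
    everything else is deterministic.
    """
    if metric not in ALL_METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {ALL_METRICS}")
    if isinstance(matrices, dict):
        matrices = list(matrices.values())
    mats = [np.asarray(m, dtype=float) for m in matrices]
    n_nodes = mats[0].shape[0]
    need_union = metric in ("modularity", "participation")
    sign = "union" if need_union else grid.sign
    rng = as_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=len(mats))

    rows = []
    for s, z in enumerate(mats):
        vals = []
        for d in grid.percents:
            g = threshold_graph(z, d, sign)
            if metric == "global_efficiency":
                vals.append(global_efficiency(g.adjacency))
            elif metric == "degree":
                vals.append(degree(g.adjacency))
            elif metric == "strength":
                vals.append(strength(g.weight_matrix))
            elif metric == "clustering":
                vals.append(clustering(g.adjacency))
            elif metric == "modularity":
                q, _ = signed_louvain(
                    g.weight_matrix, seed=sub_seeds[s], n_restarts=n_restarts
                )
                vals.append(q)
            else:  # participation, on each subject's own partition
                _, part = signed_louvain(
                    g.weight_matrix, seed=sub_seeds[s], n_restarts=n_restarts
                )
                vals.append(participation(g.weight_matrix, part))
        rows.append(np.stack(vals, axis=-1))
    return np.stack(rows)


def modularity_participation_curves(
    matrices,
    grid: DensityGrid,
    seed=None,
    n_restarts: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Modularity and participation curves from a single Louvain pass per
    union graph (both metrics share the partition, as in
    :func:`metric_curves`, at half the cost)."""
    if isinstance(matrices, dict):
        matrices = list(matrices.values())
    mats = [np.asarray(m, dtype=float) for m in matrices]
    rng = as_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=len(mats))
    mod_rows, part_rows = [], []
    for s, z in enumerate(mats):
        qs, ps = [], []
        for d in grid.percents:
            W = threshold_graph(z, d, "union").weight_matrix
            q, part = signed_louvain(W, seed=sub_seeds[s], n_restarts=n_restarts)
            qs.append(q)
            ps.append(participation(W, part))
        mod_rows.append(np.array(qs))
        part_rows.append(np.stack(ps, axis=-1))
    return np.stack(mod_rows), np.stack(part_rows)


# ---------------------------------------------------------------------------
# area-between-curves permutation test


@dataclass
class CurveTestResult:
    """Area-between-curves comparison for one curve (global or one node)."""

    scope: str
    area: float
    p_perm: float
    cohens_d: float
    mean_case: float
    mean_control: float
    q: float | None = None


@dataclass
class CurveTestResults:
    metric: str
    n_perm: int
    results: list[CurveTestResult]
    regional: bool

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "metric": self.metric,
                    "scope": r.scope,
                    "area": r.area,
                    "p": r.p_perm,
                    "q": np.nan if r.q is None else r.q,
                    "cohens_d": r.cohens_d,
                    "mean_case": r.mean_case,
                    "mean_control": r.mean_control,
                }
                for r in self.results
            ]
        )


class CurveComparison:
    """Permutation test on the area between group mean metric curves.

    ``curves_case`` / ``curves_control`` are per-subject curves with the
    density grid on the last axis: shape (n_subjects, n_densities) for a
    global metric or (n_subjects, n_nodes, n_densities) for regional
    metrics (regional p-values are FDR-corrected across nodes).
    """

    def __init__(self, curves_case, curves_control, metric: str = "metric",
                 node_labels=None):
        a = np.asarray(curves_case, dtype=float)
        b = np.asarray(curves_control, dtype=float)
        if a.shape[1:] != b.shape[1:]:
            raise ValueError("case and control curves must share the grid")
        self.regional = a.ndim == 3
        if a.ndim not in (2, 3):
            raise ValueError("curves must be 2-D (global) or 3-D (regional)")
        self.case, self.control = a, b
        self.metric = metric
        self.n_density = a.shape[-1]
        self.node_labels = node_labels

    def fit(self, n_perm: int = 50000, seed=None) -> CurveTestResults:
        """Signed area (unit density step) with a two-sided permutation
        p-value on |area|, add-one estimator; Cohen's d on the per-subject
        density-averaged metric."""
        if n_perm < 100:
            raise ValueError("n_perm must be at least 100")
        rng = as_rng(seed)
        # the area between mean curves is linear in per-subject curve sums
        sa = self.case.sum(axis=-1)     # (n_case,) or (n_case, n_nodes)
        sb = self.control.sum(axis=-1)
        if not self.regional:
            sa, sb = sa[:, None], sb[:, None]
        n1, n2 = sa.shape[0], sb.shape[0]
        pooled = np.concatenate([sa, sb], axis=0)
        n = n1 + n2
        obs = sa.mean(axis=0) - sb.mean(axis=0)

        total = pooled.sum(axis=0)
        masks = np.zeros((n_perm, n), dtype=bool)
        for r in range(n_perm):
            masks[r, rng.choice(n, n1, replace=False)] = True
        null = np.empty((n_perm, pooled.shape[1]))
        for start in range(0, n_perm, 2048):
            L = masks[start : start + 2048].astype(float)
            s1 = L @ pooled
            null[start : start + L.shape[0]] = s1 / n1 - (total - s1) / n2
        tol = 1e-9 * np.maximum(1.0, np.abs(obs))
        exceed = (np.abs(null) >= np.abs(obs) - tol).sum(axis=0)
        p = (1 + exceed) / (1 + n_perm)

        results = []
        for k in range(pooled.shape[1]):
            mc = sa[:, k] / self.n_density
            mt = sb[:, k] / self.n_density
            diff = mc.mean() - mt.mean()
            if mc.std(ddof=1) == 0 and mt.std(ddof=1) == 0:
                # degenerate constant curve (e.g. isolated node): no spread
                d = 0.0 if diff == 0 else np.sign(diff) * np.inf
            else:
                d = cohens_d(
                    mc.mean(), mc.std(ddof=1), n1, mt.mean(), mt.std(ddof=1), n2
                )
            scope = "global"
            if self.regional:
                scope = (
                    self.node_labels[k] if self.node_labels is not None else f"node{k:03d}"
                )
            results.append(
                CurveTestResult(
                    scope=scope,
                    area=float(obs[k]),
                    p_perm=float(p[k]),
                    cohens_d=float(d),
                    mean_case=float(mc.mean()),
                    mean_control=float(mt.mean()),
                )
            )
        if self.regional:
            q = bh_fdr([r.p_perm for r in results])
            for r, qv in zip(results, q):
                r.q = float(qv)
        return CurveTestResults(
            metric=self.metric, n_perm=n_perm, results=results, regional=self.regional
        )


# ---------------------------------------------------------------------------
# block-level functional connectivity means


@dataclass
class BlockMeans:
    """Module-pair mean FC summaries of one connectome."""

    pair: pd.DataFrame      # module x module mean FC (within on the diagonal)
    within: pd.Series       # mean FC inside each module
    to_rest: pd.Series      # mean FC from each module to all other nodes
    whole: float            # mean FC over the entire matrix


def block_means(z: np.ndarray, module_of) -> BlockMeans:
    """Unweighted means of Fisher-z edges per module pair; the within-
    module mean excludes the diagonal."""
    z = np.asarray(z, dtype=float)
    module_of = np.asarray(module_of)
    if module_of.shape[0] != z.shape[0]:
        raise ValueError("module assignment length must match node count")
    mods = np.unique(module_of)
    ii, jj = triu_indices(z.shape[0])
    v = z[ii, jj]
    mi, mj = module_of[ii], module_of[jj]
    pair = pd.DataFrame(np.nan, index=mods, columns=mods)
    for a_pos, a in enumerate(mods):
        if (module_of == a).sum() == 0:
            raise ValueError(f"module {a!r} has no nodes")
        for b in mods[a_pos:]:
            sel = ((mi == a) & (mj == b)) | ((mi == b) & (mj == a))
            if a == b and sel.sum() == 0:
                raise ValueError(f"module {a!r} has a single node; no within edges")
            mean = float(v[sel].mean())
            pair.loc[a, b] = mean
            pair.loc[b, a] = mean
    within = pd.Series({a: pair.loc[a, a] for a in mods}, name="within")
    to_rest = pd.Series(
        {a: float(v[((mi == a) ^ (mj == a))].mean()) for a in mods}, name="to_rest"
    )
    return BlockMeans(pair=pair, within=within, to_rest=to_rest, whole=float(v.mean()))
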