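"""Small shared helpers: edge vectorization and RNG plumbing."""

from __future__ import annotations

import numpy as np


def n_edges(n_nodes: int) -> int:
    return n_nodes * (n_nodes - 1) // 2


def triu_indices(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the strict upper triangle, edge order = lexicographic."""
    return np.triu_indices(n_nodes, k=1)


def sym_to_vec(mat: np.ndarray) -> np.ndarray:
    """Flatten a symmetric matrix to its strict upper triangle (diagonal ignored)."""
    i, j = triu_indices(mat.shape[0])
    return np.asarray(mat)[i, j]


def vec_to_sym(vec: np.ndarray, n_nodes: int, diag: float = 0.0) -> np.ndarray:
    mat = np.full((n_nodes, n_nodes), float(diag))
    i, j = triu_indices(n_nodes)
    mat[i, j] = vec
    mat[j, i] = vec
    return mat


def check_symmetric(mat: np.ndarray, tol: float = 1e-8) -> None:
    """Raise with offending indices if ``mat`` is asymmetric beyond ``tol``."""
    mat = np.asarray(mat)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {mat.shape}")
    delta = np.abs(mat - mat.T)
    if delta.max(initial=0.0) > tol:
        i, j = np.unravel_index(np.argmax(delta), delta.shape)
        raise ValueError(
            f"matrix asymmetric beyond tolerance {tol:g} at ({i}, {j}): "
            f"{mat[i, j]!r} vs {mat[j, i]!r}"
        )


def as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
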