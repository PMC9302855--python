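"""Similarity handling: graph Laplacians and multi-view fusion (SNF).

Each entity class (drugs, targets, diseases) carries one symmetric
nonnegative similarity matrix S.  The manifold penalty used by the model
is gamma * tr(F' L F) with the combinatorial Laplacian L = D - S, where D
is diagonal with the column sums of S.  When several similarity views are
available for one entity class they are merged into a single matrix with
Similarity Network Fusion (SNF), the cross-diffusion scheme of Wang et al.:
each view is split into a row-normalized full kernel P and a k-nearest-
neighbour local kernel S_loc, and the full kernels are iteratively diffused
through the local kernels of the other views.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimilaritySet",
    "build_laplacian",
    "snf_fuse",
    "read_similarity",
    "write_similarity",
]

_SYM_TOL = 1e-8


def _check_similarity(S: np.ndarray, name: str = "S") -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError(f"{name} must be square, got shape {S.shape}")
    if not np.isfinite(S).all():
        raise ValueError(f"{name} contains non-finite entries")
    if (S < 0).any():
        raise ValueError(f"{name} contains negative entries")
    # file round-trips and asymmetric sources are tolerated up to symmetrization
    return (S + S.T) / 2.0


def build_laplacian(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(L, D)`` for a symmetric nonnegative similarity matrix.

    ``D`` is diagonal with ``D[i, i]`` the i-th column sum of S and
    ``L = D - S``.  The input is symmetrized as ``(S + S') / 2`` first, so
    L has zero row sums and is positive semidefinite.
    """
    S = _check_similarity(S)
    D = np.diag(S.sum(axis=0))
    return D - S, D


@dataclass(frozen=True)
class SimilaritySet:
    """Fused similarity matrices for drugs (S_C), targets (S_T) and
    diseases (S_D), with their degree matrices and Laplacians."""

    S_C: np.ndarray
    S_T: np.ndarray
    S_D: np.ndarray

    def __post_init__(self) -> None:
        for name in ("S_C", "S_T", "S_D"):
            object.__setattr__(self, name, _check_similarity(getattr(self, name), name))

    @property
    def dims(self) -> tuple[int, int, int]:
        return (self.S_C.shape[0], self.S_T.shape[0], self.S_D.shape[0])

    def _lap(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        return build_laplacian(getattr(self, which))

    @property
    def L_C(self) -> np.ndarray:
        return self._lap("S_C")[0]

    @property
    def L_T(self) -> np.ndarray:
        return self._lap("S_T")[0]

    @property
    def L_D(self) -> np.ndarray:
        return self._lap("S_D")[0]

    @property
    def D_C(self) -> np.ndarray:
        return self._lap("S_C")[1]

    @property
    def D_T(self) -> np.ndarray:
        return self._lap("S_T")[1]

    @property
    def D_D(self) -> np.ndarray:
        return self._lap("S_D")[1]

    @classmethod
    def zeros(cls, dims: tuple[int, int, int]) -> "SimilaritySet":
        I, J, K = dims
        return cls(np.zeros((I, I)), np.zeros((J, J)), np.zeros((K, K)))


def _full_kernel(W: np.ndarray) -> np.ndarray:
    """Row-normalized full kernel P: off-diagonal row mass 1/2, diagonal 1/2.

    All-zero off-diagonal rows normalize to a uniform row, so downstream
    diffusion never divides by zero.
    """
    n = W.shape[0]
    off = W.copy()
    np.fill_diagonal(off, 0.0)
    rs = off.sum(axis=1)
    P = np.full((n, n), np.nan)
    zero = rs <= 0
    with np.errstate(invalid="ignore"):
        P[~zero] = off[~zero] / (2.0 * rs[~zero, None])
    P[zero] = 1.0 / n
    np.fill_diagonal(P, np.where(zero, 1.0 / n, 0.5))
    return P


def _knn_kernel(W: np.ndarray, k: int) -> np.ndarray:
    """Local kernel: each row keeps its k strongest neighbours (self
    excluded) renormalized to sum 1; all-zero rows become uniform."""
    n = W.shape[0]
    k = min(k, n - 1)
    off = W.copy()
    np.fill_diagonal(off, -np.inf)
    # stable selection of the k largest per row
    order = np.argsort(-off, axis=1, kind="stable")[:, :k]
    S = np.zeros_like(W)
    rows = np.repeat(np.arange(n), k)
    S[rows, order.ravel()] = W[rows, order.ravel()]
    rs = S.sum(axis=1)
    zero = rs <= 0
    S[~zero] /= rs[~zero, None]
    S[zero] = 1.0 / n
    return S


def snf_fuse(
    views: Sequence[np.ndarray],
    k_neighbors: int = 20,
    iterations: int = 20,
) -> np.ndarray:
    """Fuse multiple similarity views of the same entities into one matrix.

    Runs the SNF cross-diffusion recurrence
    ``P(v) <- S(v) @ mean(P(u), u != v) @ S(v)'`` for the given number of
    iterations and returns the symmetrized mean of the final full kernels.
    A single view (or several identical views) carries nothing to fuse and
    is returned symmetrized and otherwise untouched, preserving the ranking
    of its off-diagonal entries.
    """
    if len(views) < 1:
        raise ValueError("need at least one similarity view")
    mats = [_check_similarity(V, f"view {i}") for i, V in enumerate(views)]
    n = mats[0].shape[0]
    for i, M in enumerate(mats):
        if M.shape[0] != n:
            raise ValueError(
                f"view {i} has dimension {M.shape[0]}, expected {n}"
            )
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    if len(mats) == 1 or all(np.array_equal(mats[0], M) for M in mats[1:]):
        return mats[0].copy()

    P = [_full_kernel(W) for W in mats]
    Sloc = [_knn_kernel(W, k_neighbors) for W in mats]
    m = len(mats)
    for _ in range(iterations):
        P = [
            Sloc[v] @ (sum(P[u] for u in range(m) if u != v) / (m - 1)) @ Sloc[v].T
            for v in range(m)
        ]
    out = sum(P) / m
    out = (out + out.T) / 2.0
    return np.clip(out, 0.0, None)


def read_similarity(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a square labeled similarity table (TSV, header row + first
    column of identifiers).  Returns the matrix and the identifier list."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(x) for x in df.index]
    if ids != [str(c) for c in df.columns]:
        raise ValueError(f"{path}: row and column identifiers disagree")
    return df.to_numpy(dtype=float), ids


def write_similarity(path: str | Path, S: np.ndarray, ids: Sequence[str]) -> None:
    S = np.asarray(S, dtype=float)
    if S.shape != (len(ids), len(ids)):
        raise ValueError("similarity shape does not match identifier count")
    pd.DataFrame(S, index=list(ids), columns=list(ids)).to_csv(
        path, sep="\t", float_format="%.10g"
    )
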