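"""Third-order tensor kernels: Khatri-Rao product, mode-n matricization,
CP reconstruction, and Frobenius norms.

The package works with rank-R CANDECOMP/PARAFAC (CP) models of a
drugs x targets x diseases tensor,

    Y[i, j, k] = sum_r A[i, r] * B[j, r] * C[k, r],

written ``Y = [A, B, C]``.  All kernels here share one index convention:
when two factor indices are flattened together, the index belonging to the
*second* Khatri-Rao argument varies fastest.  Concretely the mode-1
unfolding of ``Y`` satisfies ``unfold(Y, 1) == A @ khatri_rao(C, B).T``
exactly, with mode-1 columns ordered j-fastest / k-slowest.  Only internal
consistency of this convention matters; every routine below adheres to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as _sla
from scipy import sparse as _sp

__all__ = [
    "AssociationTensor",
    "FactorSet",
    "khatri_rao",
    "matricize",
    "cp_reconstruct",
    "frobenius_sq",
]


@dataclass(frozen=True)
class AssociationTensor:
    """Sparse binary drugs x targets x diseases association tensor.

    Entries are stored as a coordinate list of (i, j, k) triples whose value
    is 1; every other cell is implicitly 0.

    Parameters
    ----------
    coords : (nnz, 3) integer array of the known triplet associations.
    dims : (I, J, K) tensor extents.
    drug_ids, target_ids, disease_ids : ordered identifier lists, lengths
        I, J and K.  Optional; synthesized positional labels are used when
        omitted.
    """

    coords: np.ndarray
    dims: tuple[int, int, int]
    drug_ids: tuple[str, ...] = field(default=())
    target_ids: tuple[str, ...] = field(default=())
    disease_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=np.intp)
        if coords.size == 0:
            coords = coords.reshape(0, 3)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must be an (nnz, 3) array of index triples")
        dims = tuple(int(d) for d in self.dims)
        if len(dims) != 3 or any(d <= 0 for d in dims):
            raise ValueError(f"dims must be three positive extents, got {self.dims!r}")
        if coords.shape[0]:
            if coords.min() < 0 or (coords.max(axis=0) >= np.array(dims)).any():
                raise ValueError("tensor coordinates fall outside dims")
            coords = np.unique(coords, axis=0)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "dims", dims)
        for name, n in zip(("drug_ids", "target_ids", "disease_ids"), dims):
            ids = tuple(getattr(self, name))
            if not ids:
                prefix = {"drug_ids": "DR", "target_ids": "TG", "disease_ids": "DS"}[name]
                ids = tuple(f"{prefix}{i:04d}" for i in range(n))
            if len(ids) != n:
                raise ValueError(f"{name} has length {len(ids)}, expected {n}")
            if len(set(ids)) != len(ids):
                raise ValueError(f"{name} contains duplicate identifiers")
            object.__setattr__(self, name, ids)

    @property
    def nnz(self) -> int:
        return int(self.coords.shape[0])

    @property
    def density(self) -> float:
        return self.nnz / float(np.prod(self.dims))

    def to_dense(self) -> np.ndarray:
        X = np.zeros(self.dims)
        if self.nnz:
            X[self.coords[:, 0], self.coords[:, 1], self.coords[:, 2]] = 1.0
        return X

    @classmethod
    def from_dense(cls, X: np.ndarray, **ids) -> "AssociationTensor":
        X = np.asarray(X)
        if X.ndim != 3:
            raise ValueError("expected a third-order array")
        bad = np.setdiff1d(np.unique(X), [0, 1])
        if bad.size:
            raise ValueError(f"tensor values must be 0/1, found {bad[:5]}")
        return cls(coords=np.argwhere(X == 1), dims=X.shape, **ids)


@dataclass(frozen=True)
class FactorSet:
    """Nonnegative CP factors A (I x R), B (J x R), C (K x R)."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray

    def __post_init__(self) -> None:
        for name in ("A", "B", "C"):
            M = np.ascontiguousarray(np.asarray(getattr(self, name), dtype=float))
            if M.ndim != 2:
                raise ValueError(f"factor {name} must be a matrix")
            if not np.isfinite(M).all():
                raise ValueError(f"factor {name} contains non-finite entries")
            if (M < 0).any():
                raise ValueError(f"factor {name} contains negative entries")
            object.__setattr__(self, name, M)
        if not (self.A.shape[1] == self.B.shape[1] == self.C.shape[1]):
            raise ValueError("factors must share the same number of columns")

    @property
    def rank(self) -> int:
        return int(self.A.shape[1])

    @property
    def dims(self) -> tuple[int, int, int]:
        return (self.A.shape[0], self.B.shape[0], self.C.shape[0])


def khatri_rao(M: np.ndarray, N: np.ndarray) -> np.ndarray:
    """Column-wise Kronecker (Khatri-Rao) product of ``M`` (p x R) and
    ``N`` (q x R); the result is (p*q) x R with ``out[i*q + j, r] =
    M[i, r] * N[j, r]`` (second argument's index varies fastest)."""
    M = np.asarray(M, dtype=float)
    N = np.asarray(N, dtype=float)
    if M.ndim != 2 or N.ndim != 2:
        raise ValueError("khatri_rao expects two matrices")
    if M.shape[1] != N.shape[1]:
        raise ValueError(
            f"column counts differ: {M.shape[1]} vs {N.shape[1]}"
        )
    return _sla.khatri_rao(M, N)


def _as_dense(X) -> np.ndarray:
    if isinstance(X, AssociationTensor):
        return X.to_dense()
    X = np.asarray(X, dtype=float)
    if X.ndim != 3:
        raise ValueError("expected a third-order tensor")
    return X


def matricize(X, mode: int) -> np.ndarray:
    """Mode-n unfolding of a third-order tensor.

    Mode 1 gives I x (J*K) with column index k*J + j, so that
    ``matricize(cp_reconstruct(F), 1) == F.A @ khatri_rao(F.C, F.B).T``;
    modes 2 and 3 pair with khatri_rao(C, A) and khatri_rao(B, A)
    respectively.
    """
    Xd = _as_dense(X)
    I, J, K = Xd.shape
    if mode == 1:
        return Xd.transpose(0, 2, 1).reshape(I, K * J)
    if mode == 2:
        return Xd.transpose(1, 2, 0).reshape(J, K * I)
    if mode == 3:
        return Xd.transpose(2, 1, 0).reshape(K, J * I)
    raise ValueError(f"mode must be 1, 2 or 3, got {mode!r}")


def sparse_matricize(X: AssociationTensor, mode: int) -> _sp.csr_matrix:
    """Mode-n unfolding of a sparse binary tensor as a CSR matrix, with the
    same column ordering as :func:`matricize`."""
    I, J, K = X.dims
    i, j, k = (X.coords[:, 0], X.coords[:, 1], X.coords[:, 2]) if X.nnz else (
        np.empty(0, int), np.empty(0, int), np.empty(0, int))
    ones = np.ones(X.nnz)
    if mode == 1:
        return _sp.csr_matrix((ones, (i, k * J + j)), shape=(I, K * J))
    if mode == 2:
        return _sp.csr_matrix((ones, (j, k * I + i)), shape=(J, K * I))
    if mode == 3:
        return _sp.csr_matrix((ones, (k, j * I + i)), shape=(K, J * I))
    raise ValueError(f"mode must be 1, 2 or 3, got {mode!r}")


def cp_reconstruct(F: FactorSet) -> np.ndarray:
    """Dense rank-R CP reconstruction Y[i,j,k] = sum_r A[i,r] B[j,r] C[k,r]."""
    return np.einsum("ir,jr,kr->ijk", F.A, F.B, F.C, optimize=True)


def frobenius_sq(T) -> float:
    """Squared Frobenius norm: the sum of squared entries."""
    if isinstance(T, AssociationTensor):
        return float(T.nnz)
    if _sp.issparse(T):
        return float(T.power(2).sum())
    return float(np.square(np.asarray(T, dtype=float)).sum())
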