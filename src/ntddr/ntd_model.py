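"""NTD-DR: coupled nonnegative CP decomposition with pairwise-association
and graph-Laplacian regularization, solved by multiplicative updates.

The estimator factorizes a binary drug-target-disease association tensor
X (I x J x K) into nonnegative factors A (I x R), B (J x R), C (K x R)
minimizing

    L(A, B, C) = alpha * ||X - [A, B, C]||_F^2                     (tensor fit)
               + lambda_ct * ||A_CT - A B'||_F^2
               + lambda_cd * ||A_CD - A C'||_F^2
               + lambda_td * ||A_TD - B C'||_F^2                   (pairwise fit)
               + gamma_c * tr(A' L_C A) + gamma_t * tr(B' L_T B)
               + gamma_d * tr(C' L_D C)                            (manifold)

subject to A, B, C >= 0, where L_* = D_* - S_* are similarity-graph
Laplacians.  Each factor update multiplies the factor elementwise by the
ratio of the negative to the positive part of its gradient, which keeps
iterates nonnegative; iteration stops when the relative objective change
falls below ``tol``.  Prediction matrices are read off the fitted factors:
A B' scores drug-target pairs, A C' drug-disease pairs, B C' target-disease
pairs, and the reconstructed tensor scores triplets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse as _sp

from .similarity import SimilaritySet
from .tensor_algebra import (
    AssociationTensor,
    FactorSet,
    cp_reconstruct,
    frobenius_sq,
    khatri_rao,
    matricize,
    sparse_matricize,
)

__all__ = [
    "Hyperparameters",
    "PairwiseAssociations",
    "PredictionSet",
    "FitTrace",
    "objective",
    "gradients",
    "update_step",
    "fit",
    "kkt_residual",
    "predict",
    "initial_factors",
    "structured_init",
    "save_factors",
    "load_factors",
]


@dataclass(frozen=True)
class Hyperparameters:
    """Model and solver controls.

    Defaults follow the regime that performed best for drug-disease
    prediction: the drug-disease coupling and the drug/disease manifold
    penalties are pinned at 1, the remaining couplings are weak
    (lambda_ct = lambda_td = 1e-3, gamma_t = 1e-4) and alpha = 0.7.
    """

    rank: int
    alpha: float = 0.7
    lambda_ct: float = 1e-3
    lambda_cd: float = 1.0
    lambda_td: float = 1e-3
    gamma_c: float = 1.0
    gamma_t: float = 1e-4
    gamma_d: float = 1.0
    tol: float = 1e-6
    max_iter: int = 500
    seed: int = 0
    eps: float = 1e-12
    update_order: str = "sequential"  # or "jacobi", for ablation
    init: str = "svd"  # or "uniform"

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        for name in ("lambda_ct", "lambda_cd", "lambda_td",
                     "gamma_c", "gamma_t", "gamma_d"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.tol <= 0 or self.eps <= 0 or self.max_iter < 1:
            raise ValueError("tol and eps must be positive, max_iter >= 1")
        if self.update_order not in ("sequential", "jacobi"):
            raise ValueError("update_order must be 'sequential' or 'jacobi'")
        if self.init not in ("svd", "uniform"):
            raise ValueError("init must be 'svd' or 'uniform'")


@dataclass(frozen=True)
class PairwiseAssociations:
    """Binary drug-target (A_CT), drug-disease (A_CD) and target-disease
    (A_TD) association matrices over a shared entity indexing."""

    A_CT: np.ndarray
    A_CD: np.ndarray
    A_TD: np.ndarray
    drug_ids: tuple[str, ...] = field(default=())
    target_ids: tuple[str, ...] = field(default=())
    disease_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        for name in ("A_CT", "A_CD", "A_TD"):
            M = np.asarray(getattr(self, name), dtype=float)
            bad = np.setdiff1d(np.unique(M), [0.0, 1.0])
            if bad.size:
                raise ValueError(f"{name} must be binary, found values {bad[:5]}")
            object.__setattr__(self, name, M)
        I, J = self.A_CT.shape
        I2, K = self.A_CD.shape
        J2, K2 = self.A_TD.shape
        if I != I2 or J != J2 or K != K2:
            raise ValueError(
                f"inconsistent dims: A_CT {self.A_CT.shape}, "
                f"A_CD {self.A_CD.shape}, A_TD {self.A_TD.shape}"
            )
        for name, n, prefix in (("drug_ids", I, "DR"), ("target_ids", J, "TG"),
                                ("disease_ids", K, "DS")):
            ids = tuple(getattr(self, name))
            if not ids:
                ids = tuple(f"{prefix}{i:04d}" for i in range(n))
            if len(ids) != n or len(set(ids)) != len(ids):
                raise ValueError(f"{name} must be {n} unique identifiers")
            object.__setattr__(self, name, ids)

    @property
    def dims(self) -> tuple[int, int, int]:
        I, J = self.A_CT.shape
        return (I, J, self.A_CD.shape[1])


@dataclass(frozen=True)
class PredictionSet:
    """Association scores from fitted factors: Y for triplets, P_CT = AB',
    P_CD = AC', P_TD = BC' for the three pairwise association types."""

    Y: np.ndarray
    P_CT: np.ndarray
    P_CD: np.ndarray
    P_TD: np.ndarray


@dataclass
class FitTrace:
    """Per-iteration solver diagnostics."""

    initial_objective: float = 0.0
    objective_history: list[float] = field(default_factory=list)
    component_history: list[dict[str, float]] = field(default_factory=list)
    kkt_residual_history: list[float] = field(default_factory=list)
    iterations_run: int = 0
    converged: bool = False

    @property
    def final_objective(self) -> float:
        return self.objective_history[-1] if self.objective_history else self.initial_objective


def _check_dims(X, F: FactorSet, P: PairwiseAssociations, S: SimilaritySet) -> None:
    dims = X.dims if isinstance(X, AssociationTensor) else tuple(np.shape(X))
    if dims != F.dims or dims != P.dims or dims != S.dims:
        raise ValueError(
            f"dimension mismatch: tensor {dims}, factors {F.dims}, "
            f"pairwise {P.dims}, similarities {S.dims}"
        )


def objective(
    X,
    F: FactorSet,
    P: PairwiseAssociations,
    S: SimilaritySet,
    H: Hyperparameters,
) -> tuple[float, dict[str, float]]:
    """Evaluate the coupled objective; returns the total and its three
    components ``{"L_T": ..., "L_A": ..., "L_S": ...}``."""
    _check_dims(X, F, P, S)
    Xd = X.to_dense() if isinstance(X, AssociationTensor) else np.asarray(X, float)
    A, B, C = F.A, F.B, F.C
    L_T = H.alpha * frobenius_sq(Xd - cp_reconstruct(F))
    L_A = (
        H.lambda_ct * frobenius_sq(P.A_CT - A @ B.T)
        + H.lambda_cd * frobenius_sq(P.A_CD - A @ C.T)
        + H.lambda_td * frobenius_sq(P.A_TD - B @ C.T)
    )
    L_S = (
        H.gamma_c * float(np.trace(A.T @ S.L_C @ A))
        + H.gamma_t * float(np.trace(B.T @ S.L_T @ B))
        + H.gamma_d * float(np.trace(C.T @ S.L_D @ C))
    )
    total = L_T + L_A + L_S
    return total, {"L_T": L_T, "L_A": L_A, "L_S": L_S}


class _Workspace:
    """Precomputed quantities reused across iterations of one fit: the three
    sparse unfoldings of X and the Laplacian pieces."""

    def __init__(self, X, P: PairwiseAssociations, S: SimilaritySet):
        if isinstance(X, AssociationTensor):
            self.X1 = sparse_matricize(X, 1)
            self.X2 = sparse_matricize(X, 2)
            self.X3 = sparse_matricize(X, 3)
            self.norm_x_sq = float(X.nnz)
        else:
            Xd = np.asarray(X, dtype=float)
            self.X1 = matricize(Xd, 1)
            self.X2 = matricize(Xd, 2)
            self.X3 = matricize(Xd, 3)
            self.norm_x_sq = frobenius_sq(Xd)
        self.P = P
        self.S_C, self.S_T, self.S_D = S.S_C, S.S_T, S.S_D
        self.d_C = self.S_C.sum(axis=0)  # degree vectors
        self.d_T = self.S_T.sum(axis=0)
        self.d_D = self.S_D.sum(axis=0)

    def mttkrp(self, mode: int, F: FactorSet) -> np.ndarray:
        """X(n) times the matching Khatri-Rao factor product."""
        if mode == 1:
            K = khatri_rao(F.C, F.B)
            return np.asarray(self.X1 @ K)
        if mode == 2:
            K = khatri_rao(F.C, F.A)
            return np.asarray(self.X2 @ K)
        K = khatri_rao(F.B, F.A)
        return np.asarray(self.X3 @ K)


def _factor_parts(ws: _Workspace, F: FactorSet, H: Hyperparameters,
                  which: str) -> tuple[np.ndarray, np.ndarray]:
    """Negative and positive gradient parts for one factor; the gradient is
    2*(pos - neg) and the multiplicative update multiplies by neg/pos."""
    A, B, C = F.A, F.B, F.C
    P = ws.P
    if which == "A":
        BtB, CtC = B.T @ B, C.T @ C
        neg = (H.alpha * ws.mttkrp(1, F) + H.gamma_c * (ws.S_C @ A)
               + H.lambda_ct * (P.A_CT @ B) + H.lambda_cd * (P.A_CD @ C))
        pos = (A @ (H.alpha * (CtC * BtB) + H.lambda_ct * BtB + H.lambda_cd * CtC)
               + H.gamma_c * ws.d_C[:, None] * A)
    elif which == "B":
        AtA, CtC = A.T @ A, C.T @ C
        neg = (H.alpha * ws.mttkrp(2, F) + H.gamma_t * (ws.S_T @ B)
               + H.lambda_ct * (P.A_CT.T @ A) + H.lambda_td * (P.A_TD @ C))
        pos = (B @ (H.alpha * (CtC * AtA) + H.lambda_ct * AtA + H.lambda_td * CtC)
               + H.gamma_t * ws.d_T[:, None] * B)
    else:
        AtA, BtB = A.T @ A, B.T @ B
        neg = (H.alpha * ws.mttkrp(3, F) + H.gamma_d * (ws.S_D @ C)
               + H.lambda_cd * (P.A_CD.T @ A) + H.lambda_td * (P.A_TD.T @ B))
        pos = (C @ (H.alpha * (BtB * AtA) + H.lambda_cd * AtA + H.lambda_td * BtB)
               + H.gamma_d * ws.d_D[:, None] * C)
    return neg, pos


def _gradients_ws(ws: _Workspace, F: FactorSet, H: Hyperparameters):
    return tuple(_factor_parts(ws, F, H, w) for w in "ABC")


def gradients(
    X,
    F: FactorSet,
    P: PairwiseAssociations,
    S: SimilaritySet,
    H: Hyperparameters,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic gradients of the objective w.r.t. A, B and C.

    Each gradient splits as ``2 * (positive part - negative part)``; the
    two parts are the numerator and denominator of the multiplicative
    update for that factor.
    """
    _check_dims(X, F, P, S)
    ws = _Workspace(X, P, S)
    (nA, pA), (nB, pB), (nC, pC) = _gradients_ws(ws, F, H)
    return 2.0 * (pA - nA), 2.0 * (pB - nB), 2.0 * (pC - nC)


def _step_ws(ws: _Workspace, F: FactorSet, H: Hyperparameters,
             iteration: int | None = None) -> FactorSet:
    cur = F
    if H.update_order == "sequential":
        # A, then B, then C, each seeing the freshest co-factors
        for which in "ABC":
            num, den = _factor_parts(ws, cur, H, which)
            new = _mu_ratio(getattr(cur, which), num, den, H.eps, iteration)
            cur = replace(cur, **{which: new})
        return cur
    (nA, pA), (nB, pB), (nC, pC) = _gradients_ws(ws, cur, H)
    return FactorSet(
        A=_mu_ratio(cur.A, nA, pA, H.eps, iteration),
        B=_mu_ratio(cur.B, nB, pB, H.eps, iteration),
        C=_mu_ratio(cur.C, nC, pC, H.eps, iteration),
    )


def _mu_ratio(M: np.ndarray, num: np.ndarray, den: np.ndarray,
              eps: float, iteration: int | None) -> np.ndarray:
    out = M * (num / np.maximum(den, eps))
    if not np.isfinite(out).all():
        where = f" at iteration {iteration}" if iteration is not None else ""
        raise FloatingPointError(f"non-finite factor entries{where}")
    return np.maximum(out, 0.0)


def update_step(
    F: FactorSet,
    X,
    P: PairwiseAssociations,
    S: SimilaritySet,
    H: Hyperparameters,
) -> FactorSet:
    """One multiplicative update sweep.

    Each factor entry is multiplied by (negative gradient part) /
    (positive gradient part), denominators floored at ``H.eps``.  The
    update depends only on ratios of the regularization coefficients:
    scaling alpha, all lambdas and all gammas by one positive constant
    leaves it unchanged.  Zero entries stay zero.
    """
    _check_dims(X, F, P, S)
    return _step_ws(_Workspace(X, P, S), F, H)


def kkt_residual(F: FactorSet, G_A: np.ndarray, G_B: np.ndarray,
                 G_C: np.ndarray) -> float:
    """First-order stationarity measure for the nonnegativity-constrained
    problem: max over entries of abs(min(factor, gradient)).  Zero exactly
    when factors are nonnegative, gradients nonnegative, and their
    elementwise product vanishes (complementary slackness)."""
    res = 0.0
    for M, G in ((F.A, G_A), (F.B, G_B), (F.C, G_C)):
        if M.size:
            res = max(res, float(np.abs(np.minimum(M, G)).max()))
    return res


def initial_factors(dims: tuple[int, int, int], rank: int, seed: int,
                    offset: float = 1e-3) -> FactorSet:
    """Seeded uniform(0,1) + offset initialization; strictly positive so
    multiplicative updates start interior."""
    rng = np.random.default_rng(seed)
    I, J, K = dims
    return FactorSet(
        A=rng.uniform(size=(I, rank)) + offset,
        B=rng.uniform(size=(J, rank)) + offset,
        C=rng.uniform(size=(K, rank)) + offset,
    )


def structured_init(X, rank: int, floor_frac: float = 1e-3) -> FactorSet:
    """Deterministic data-driven initialization.

    A nonnegative matrix factorization of the mode-1 unfolding (NNDSVD-
    seeded) yields the drug factor and R mixing rows; each mixing row,
    reshaped to diseases x targets, is split by a rank-1 SVD into the
    matching disease and target columns, so components stay aligned across
    the three modes.  Entries are floored at ``floor_frac`` times the mean
    positive entry: multiplicative updates freeze exact zeros, and a
    strictly positive start lets mass move between components.

    Random uniform starts frequently collapse two components onto one
    dense block of a sparse association tensor and can never repopulate
    the starved component; seeding from the unfolding avoids that trap.
    Falls back to a seed-0 uniform draw when the rank exceeds what the
    unfolding supports.
    """
    from sklearn.decomposition import NMF

    if isinstance(X, AssociationTensor):
        I, J, K = X.dims
        X1 = sparse_matricize(X, 1)
    else:
        Xd = np.asarray(X, dtype=float)
        I, J, K = Xd.shape
        X1 = matricize(Xd, 1)
    if rank > min(I, J * K):
        return initial_factors((I, J, K), rank, seed=0)
    nmf = NMF(n_components=rank, init="nndsvda", max_iter=500, tol=1e-6,
              random_state=0)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # NMF max_iter warnings are benign here
        A0 = nmf.fit_transform(X1)
    mix = nmf.components_
    B0 = np.zeros((J, rank))
    C0 = np.zeros((K, rank))
    for r in range(rank):
        Hr = mix[r].reshape(K, J)  # mode-1 columns are ordered j-fastest
        U, s, Vt = np.linalg.svd(Hr, full_matrices=False)
        C0[:, r] = np.sqrt(s[0]) * np.abs(U[:, 0])
        B0[:, r] = np.sqrt(s[0]) * np.abs(Vt[0])

    def _floor(M: np.ndarray) -> np.ndarray:
        pos = M[M > 0]
        scale = pos.mean() if pos.size else 1.0
        return np.maximum(M, floor_frac * scale)

    return FactorSet(A=_floor(A0), B=_floor(B0), C=_floor(C0))


def fit(
    X,
    P: PairwiseAssociations,
    S: SimilaritySet,
    H: Hyperparameters,
    F0: FactorSet | None = None,
    track_kkt: bool = True,
) -> tuple[FactorSet, FitTrace]:
    """Run multiplicative updates until the relative objective change
    drops below ``H.tol`` or ``H.max_iter`` is reached.

    The start point is ``F0`` if given, otherwise the deterministic
    data-driven initialization (``H.init == "svd"``, the default) or a
    seeded uniform draw (``H.init == "uniform"``).

    Returns the fitted factors and a :class:`FitTrace` with per-iteration
    objective components and KKT residuals.  Two runs with identical
    inputs and seed produce identical traces.
    """
    dims = X.dims if isinstance(X, AssociationTensor) else tuple(np.shape(X))
    if F0 is None:
        F0 = (structured_init(X, H.rank) if H.init == "svd"
              else initial_factors(dims, H.rank, H.seed))
    F = F0
    _check_dims(X, F, P, S)
    ws = _Workspace(X, P, S)

    trace = FitTrace()
    prev, comps = objective(X, F, P, S, H)
    trace.initial_objective = prev
    if not np.isfinite(prev):
        raise FloatingPointError("initial objective is non-finite")

    for t in range(1, H.max_iter + 1):
        F = _step_ws(ws, F, H, iteration=t)
        total, comps = objective(X, F, P, S, H)
        if not np.isfinite(total):
            trace.iterations_run = t
            raise FloatingPointError(f"objective diverged at iteration {t}")
        trace.objective_history.append(total)
        trace.component_history.append(comps)
        if track_kkt:
            (nA, pA), (nB, pB), (nC, pC) = _gradients_ws(ws, F, H)
            trace.kkt_residual_history.append(
                kkt_residual(F, 2 * (pA - nA), 2 * (pB - nB), 2 * (pC - nC))
            )
        trace.iterations_run = t
        rel = abs(total - prev) / max(prev, H.eps)
        prev = total
        if rel <= H.tol:
            trace.converged = True
            break
    return F, trace


def predict(F: FactorSet) -> PredictionSet:
    """Score all associations from fitted factors."""
    return PredictionSet(
        Y=cp_reconstruct(F),
        P_CT=F.A @ F.B.T,
        P_CD=F.A @ F.C.T,
        P_TD=F.B @ F.C.T,
    )


def save_factors(outdir: str | Path, F: FactorSet, H: Hyperparameters,
                 trace: FitTrace | None = None,
                 ids: tuple | None = None) -> None:
    """Serialize factors as labeled TSVs with a JSON sidecar recording the
    hyperparameters and solver outcome."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    labels = ids if ids is not None else (
        [f"DR{i:04d}" for i in range(F.A.shape[0])],
        [f"TG{i:04d}" for i in range(F.B.shape[0])],
        [f"DS{i:04d}" for i in range(F.C.shape[0])],
    )
    for name, M, idx in zip(("A", "B", "C"), (F.A, F.B, F.C), labels):
        pd.DataFrame(M, index=list(idx)).to_csv(
            outdir / f"factor_{name}.tsv", sep="\t", float_format="%.12g")
    side = {"hyperparameters": asdict(H)}
    if trace is not None:
        side["iterations_run"] = trace.iterations_run
        side["converged"] = bool(trace.converged)
        side["final_objective"] = trace.final_objective
        if trace.component_history:
            side["final_components"] = trace.component_history[-1]
    (outdir / "fit.json").write_text(json.dumps(side, indent=2))


def load_factors(outdir: str | Path) -> tuple[FactorSet, Hyperparameters]:
    outdir = Path(outdir)
    mats = {
        name: pd.read_csv(outdir / f"factor_{name}.tsv", sep="\t", index_col=0)
        .to_numpy(dtype=float)
        for name in ("A", "B", "C")
    }
    side = json.loads((outdir / "fit.json").read_text())
    H = Hyperparameters(**side["hyperparameters"])
    return FactorSet(**mats), H
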