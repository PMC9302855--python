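"""Self-contained synthetic instances with the coupled structure the model
assumes: sparse nonnegative low-rank factors, pairwise association
matrices and a triplet tensor that are mutually consistent, and
factor-derived similarity matrices.

Ground-truth factors are sparse exponential draws, so each entity loads
on a small subset of latent components (think drug classes / target
families / disease groups).  Continuous association scores A B', A C',
B C' are thresholded at a quantile to give binary pairwise matrices;
optional independent label flips add noise.  The tensor is then re-derived
from the (possibly noisy) binarized matrices through the same triangle
rule the data pipeline uses, so every emitted artifact is consistent with
every other.  Similarities are Gaussian kernels on ground-truth factor
rows, which makes them genuinely informative about the latent structure
(the manifold assumption behind the Laplacian penalty), not recomputed
from the binarized matrices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .data_pipeline import EdgeList, build_tensor, write_edge_list
from .ntd_model import PairwiseAssociations
from .similarity import SimilaritySet, write_similarity
from .tensor_algebra import AssociationTensor, FactorSet

__all__ = ["GeneratorConfig", "SyntheticInstance", "generate", "write_instance"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic instance generator.

    dims : (drugs, targets, diseases); defaults are desk-scale.
    true_rank : number of latent components shared by all artifacts.
    factor_sparsity : fraction of zero entries per factor row.  Each row
        keeps ``max(1, round(R * (1 - factor_sparsity)))`` randomly chosen
        active components; at the default 0.8 with rank 5 every entity
        belongs to exactly one latent component, so the noiseless tensor
        is an exact union of disjoint rank-1 blocks (exactly rank <= R).
    binarization_quantile : quantile of each continuous score matrix used
        as the 0/1 threshold.  At the default 0.5 the threshold falls on
        the zero mass of the sparse scores, so the binary matrices equal
        the supports of the low-rank products.
    flip_noise : independent 0<->1 flip probability applied to the
        pairwise matrices after binarization.
    similarity_kernel_width : bandwidth multiplier of the Gaussian kernel
        on factor rows (relative to the median pairwise distance).
    """

    dims: tuple[int, int, int] = (30, 20, 25)
    true_rank: int = 5
    factor_sparsity: float = 0.8
    binarization_quantile: float = 0.5
    flip_noise: float = 0.0
    similarity_kernel_width: float = 1.0
    seed: int = 0
    max_retries: int = 10

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(d < 1 for d in self.dims):
            raise ValueError("dims must be three positive extents")
        if self.true_rank < 1 or self.true_rank > min(self.dims):
            raise ValueError("true_rank must be in [1, min(dims)]")
        if not 0 <= self.factor_sparsity < 1:
            raise ValueError("factor_sparsity must be in [0, 1)")
        if not 0 < self.binarization_quantile < 1:
            raise ValueError("binarization_quantile must be in (0, 1)")
        if not 0 <= self.flip_noise < 0.5:
            raise ValueError("flip_noise must be in [0, 0.5)")
        if self.similarity_kernel_width <= 0:
            raise ValueError("similarity_kernel_width must be positive")


@dataclass(frozen=True)
class SyntheticInstance:
    factors: FactorSet
    tensor: AssociationTensor
    pairwise: PairwiseAssociations
    similarities: SimilaritySet
    manifest: dict


def _sparse_exponential(rng, n: int, r: int, sparsity: float) -> np.ndarray:
    """Exponential factor rows with a fixed number of active components.

    Zeroing per row (rather than iid over entries) keeps every entity on
    max(1, round(r*(1-sparsity))) components and never produces dead
    all-zero rows; with one active component per row the latent structure
    is a clean partition into communities.
    """
    M = rng.exponential(scale=1.0, size=(n, r))
    m_active = max(1, int(round(r * (1.0 - sparsity))))
    if m_active < r:
        # per-row random choice of which components stay active
        drop = np.argsort(rng.uniform(size=(n, r)), axis=1)[:, m_active:]
        np.put_along_axis(M, drop, 0.0, axis=1)
    return M


def _binarize(M: np.ndarray, q: float) -> np.ndarray:
    return (M > np.quantile(M, q)).astype(float)


def _flip(M: np.ndarray, rate: float, rng) -> np.ndarray:
    if rate <= 0:
        return M
    flips = rng.uniform(size=M.shape) < rate
    return np.abs(M - flips.astype(float))


def _factor_kernel(M: np.ndarray, width: float) -> np.ndarray:
    """Gaussian kernel on factor rows, bandwidth = width * median pairwise
    Euclidean distance (falls back to 1 when degenerate)."""
    d = pdist(M)
    med = np.median(d[d > 0]) if (d > 0).any() else 1.0
    sigma = width * med
    K = np.exp(-squareform(d) ** 2 / (2.0 * sigma**2))
    np.fill_diagonal(K, 1.0)
    return K


def generate(cfg: GeneratorConfig) -> SyntheticInstance:
    """Draw one synthetic instance; retries with a shifted stream on the
    rare degenerate draw (an all-zero matrix or an empty tensor)."""
    last = None
    for attempt in range(cfg.max_retries):
        inst = _generate_once(cfg, cfg.seed + attempt * 7919)
        if inst is not None:
            return inst
        last = attempt
    raise RuntimeError(
        f"generator produced degenerate instances for {cfg.max_retries} "
        f"attempts from seed {cfg.seed} (last attempt {last})"
    )


def _generate_once(cfg: GeneratorConfig, seed: int) -> SyntheticInstance | None:
    rng = np.random.default_rng(seed)
    I, J, K = cfg.dims
    R = cfg.true_rank
    A = _sparse_exponential(rng, I, R, cfg.factor_sparsity)
    B = _sparse_exponential(rng, J, R, cfg.factor_sparsity)
    C = _sparse_exponential(rng, K, R, cfg.factor_sparsity)

    q = cfg.binarization_quantile
    A_CT = _flip(_binarize(A @ B.T, q), cfg.flip_noise, rng)
    A_CD = _flip(_binarize(A @ C.T, q), cfg.flip_noise, rng)
    A_TD = _flip(_binarize(B @ C.T, q), cfg.flip_noise, rng)
    if not (A_CT.sum() and A_CD.sum() and A_TD.sum()):
        return None

    pairwise = PairwiseAssociations(A_CT=A_CT, A_CD=A_CD, A_TD=A_TD)
    tensor = build_tensor(pairwise, rule="triangle")
    if tensor.nnz == 0:
        return None

    sims = SimilaritySet(
        S_C=_factor_kernel(A, cfg.similarity_kernel_width),
        S_T=_factor_kernel(B, cfg.similarity_kernel_width),
        S_D=_factor_kernel(C, cfg.similarity_kernel_width),
    )
    manifest = {
        "generator": asdict(cfg),
        "effective_seed": seed,
        "counts": {
            "drug_target": int(A_CT.sum()),
            "drug_disease": int(A_CD.sum()),
            "target_disease": int(A_TD.sum()),
            "triplets": tensor.nnz,
        },
        "tensor_density": tensor.density,
    }
    return SyntheticInstance(
        factors=FactorSet(A=A, B=B, C=C),
        tensor=tensor,
        pairwise=pairwise,
        similarities=sims,
        manifest=manifest,
    )


def write_instance(instance: SyntheticInstance, outdir: str | Path) -> None:
    """Write edge lists, similarity TSVs, ground-truth factor TSVs and the
    manifest into a directory."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    P = instance.pairwise
    pairs = {
        "drug_target.tsv": ("drug-target", P.A_CT, P.drug_ids, P.target_ids),
        "drug_disease.tsv": ("drug-disease", P.A_CD, P.drug_ids, P.disease_ids),
        "target_disease.tsv": ("target-disease", P.A_TD, P.target_ids, P.disease_ids),
    }
    for fname, (kind, M, rows, cols) in pairs.items():
        records = tuple((rows[i], cols[j]) for i, j in np.argwhere(M == 1))
        write_edge_list(outdir / fname, EdgeList(records=records, kind=kind))
    S = instance.similarities
    write_similarity(outdir / "similarity_drug.tsv", S.S_C, P.drug_ids)
    write_similarity(outdir / "similarity_target.tsv", S.S_T, P.target_ids)
    write_similarity(outdir / "similarity_disease.tsv", S.S_D, P.disease_ids)
    F = instance.factors
    for name, M, ids in (("A", F.A, P.drug_ids), ("B", F.B, P.target_ids),
                         ("C", F.C, P.disease_ids)):
        pd.DataFrame(M, index=list(ids)).to_csv(
            outdir / f"true_factor_{name}.tsv", sep="\t", float_format="%.12g")
    (outdir / "manifest.json").write_text(json.dumps(instance.manifest, indent=2))
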