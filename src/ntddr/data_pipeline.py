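"""Ingest pairwise association edge lists, filter low-degree entities,
construct the binary drug-target-disease tensor, and split positives into
the P/S/I subsets (train-test / parameter-setting / case-study).

Edge lists are 2-column tab-separated files of identifier pairs;
'#'-prefixed lines are comments.  A drug-target-disease triplet (i, j, k)
enters the tensor when all three pairwise edges i-j, i-k and j-k are
present ("triangle" rule); an "any_two" variant is available for
sensitivity analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ntd_model import PairwiseAssociations
from .tensor_algebra import AssociationTensor

__all__ = [
    "EdgeList",
    "DatasetSplit",
    "read_edge_list",
    "write_edge_list",
    "build_matrices",
    "degree_filter",
    "build_tensor",
    "split_psi",
    "write_manifest",
]

EDGE_KINDS = ("drug-target", "drug-disease", "target-disease")


@dataclass(frozen=True)
class EdgeList:
    """Deduplicated list of (source_id, target_id) association pairs."""

    records: tuple[tuple[str, str], ...]
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in EDGE_KINDS:
            raise ValueError(f"kind must be one of {EDGE_KINDS}, got {self.kind!r}")
        seen = set()
        out = []
        for a, b in self.records:
            a, b = str(a).strip(), str(b).strip()
            if not a or not b:
                raise ValueError(f"empty identifier in {self.kind} edge ({a!r}, {b!r})")
            if (a, b) not in seen:
                seen.add((a, b))
                out.append((a, b))
        object.__setattr__(self, "records", tuple(out))

    def __len__(self) -> int:
        return len(self.records)


def read_edge_list(path: str | Path, kind: str) -> EdgeList:
    records = []
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
        records.append((parts[0], parts[1]))
    return EdgeList(records=tuple(records), kind=kind)


def write_edge_list(path: str | Path, edges: EdgeList) -> None:
    lines = [f"# {edges.kind} associations", *(f"{a}\t{b}" for a, b in edges.records)]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def build_matrices(
    ct: EdgeList, cd: EdgeList, td: EdgeList
) -> PairwiseAssociations:
    """Assemble binary association matrices from three edge lists.

    The drug index space is the union of drug identifiers across the
    drug-target and drug-disease files (likewise for targets and
    diseases), sorted for determinism; entities missing from one matrix
    simply get all-zero rows or columns there.
    """
    if ct.kind != "drug-target" or cd.kind != "drug-disease" or td.kind != "target-disease":
        raise ValueError("edge lists must be (drug-target, drug-disease, target-disease)")
    if not (len(ct) and len(cd) and len(td)):
        raise ValueError("all three edge lists must be nonempty")
    drugs = sorted({a for a, _ in ct.records} | {a for a, _ in cd.records})
    targets = sorted({b for _, b in ct.records} | {a for a, _ in td.records})
    diseases = sorted({b for _, b in cd.records} | {b for _, b in td.records})
    clash = (set(drugs) & set(targets)) | (set(drugs) & set(diseases)) | (
        set(targets) & set(diseases))
    if clash:
        raise ValueError(
            "identifiers used in more than one entity role: "
            + ", ".join(sorted(clash)[:10])
        )
    di = {d: i for i, d in enumerate(drugs)}
    ti = {t: j for j, t in enumerate(targets)}
    si = {s: k for k, s in enumerate(diseases)}
    A_CT = np.zeros((len(drugs), len(targets)))
    A_CD = np.zeros((len(drugs), len(diseases)))
    A_TD = np.zeros((len(targets), len(diseases)))
    for a, b in ct.records:
        A_CT[di[a], ti[b]] = 1.0
    for a, b in cd.records:
        A_CD[di[a], si[b]] = 1.0
    for a, b in td.records:
        A_TD[ti[a], si[b]] = 1.0
    return PairwiseAssociations(
        A_CT=A_CT, A_CD=A_CD, A_TD=A_TD,
        drug_ids=tuple(drugs), target_ids=tuple(targets), disease_ids=tuple(diseases),
    )


def degree_filter(
    P: PairwiseAssociations, min_degree: int = 5
) -> tuple[PairwiseAssociations, dict[str, list[str]]]:
    """Iteratively drop entities with fewer than ``min_degree`` total
    associations across the two matrices they participate in.

    Removals can push neighbours below threshold, so the filter repeats
    until a fixed point; removing all below-threshold entities at once each
    round makes the result independent of any removal order.  Returns the
    filtered matrices and a report of removed identifiers per class.
    """
    if min_degree < 1:
        raise ValueError("min_degree must be >= 1")
    A_CT, A_CD, A_TD = P.A_CT.copy(), P.A_CD.copy(), P.A_TD.copy()
    keep_d = np.arange(A_CT.shape[0])
    keep_t = np.arange(A_CT.shape[1])
    keep_k = np.arange(A_CD.shape[1])
    while True:
        deg_d = A_CT.sum(axis=1) + A_CD.sum(axis=1)
        deg_t = A_CT.sum(axis=0) + A_TD.sum(axis=1)
        deg_k = A_CD.sum(axis=0) + A_TD.sum(axis=0)
        ok_d, ok_t, ok_k = deg_d >= min_degree, deg_t >= min_degree, deg_k >= min_degree
        if ok_d.all() and ok_t.all() and ok_k.all():
            break
        if not (ok_d.any() and ok_t.any() and ok_k.any()):
            raise ValueError(
                f"degree filter at min_degree={min_degree} removed an entire entity class"
            )
        A_CT = A_CT[np.ix_(ok_d, ok_t)]
        A_CD = A_CD[np.ix_(ok_d, ok_k)]
        A_TD = A_TD[np.ix_(ok_t, ok_k)]
        keep_d, keep_t, keep_k = keep_d[ok_d], keep_t[ok_t], keep_k[ok_k]
    removed = {
        "drugs": [P.drug_ids[i] for i in sorted(set(range(len(P.drug_ids))) - set(keep_d))],
        "targets": [P.target_ids[i] for i in sorted(set(range(len(P.target_ids))) - set(keep_t))],
        "diseases": [P.disease_ids[i] for i in sorted(set(range(len(P.disease_ids))) - set(keep_k))],
    }
    out = PairwiseAssociations(
        A_CT=A_CT, A_CD=A_CD, A_TD=A_TD,
        drug_ids=tuple(P.drug_ids[i] for i in keep_d),
        target_ids=tuple(P.target_ids[i] for i in keep_t),
        disease_ids=tuple(P.disease_ids[i] for i in keep_k),
    )
    return out, removed


def build_tensor(P: PairwiseAssociations, rule: str = "triangle") -> AssociationTensor:
    """Construct the binary triplet tensor from the pairwise matrices.

    ``triangle`` (default): X[i,j,k] = 1 iff all of A_CT[i,j], A_CD[i,k]
    and A_TD[j,k] are 1.  ``any_two``: at least two of the three edges are
    present (sensitivity-analysis variant).
    """
    ct = P.A_CT[:, :, None]
    cd = P.A_CD[:, None, :]
    td = P.A_TD[None, :, :]
    if rule == "triangle":
        X = ct * cd * td
    elif rule == "any_two":
        X = ((ct + cd + td) >= 2).astype(float)
    else:
        raise ValueError(f"unknown tensor construction rule {rule!r}")
    return AssociationTensor(
        coords=np.argwhere(X == 1), dims=X.shape,
        drug_ids=P.drug_ids, target_ids=P.target_ids, disease_ids=P.disease_ids,
    )


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint positive index subsets: P (train/test, 90%), S (parameter
    setting, 5%), I (case-study validation, 5%), plus matched negative
    sets of equal size once attached."""

    P: tuple[int, ...]
    S: tuple[int, ...]
    I: tuple[int, ...]
    negatives: dict[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sets = [set(self.P), set(self.S), set(self.I)]
        if sum(len(s) for s in sets) != len(set().union(*sets)):
            raise ValueError("P, S, I subsets must be disjoint")


def split_psi(
    positives, seed: int, fractions: tuple[float, float, float] = (0.90, 0.05, 0.05)
) -> DatasetSplit:
    """Seeded shuffle-and-partition of positive sample indices.

    Subset sizes for S and I are floored; the remainder goes to P, so the
    split is deterministic given the seed.
    """
    positives = list(positives)
    n = len(positives)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if n < 3:
        raise ValueError(f"need at least 3 positives to split, got {n}")
    n_s = int(np.floor(fractions[1] * n))
    n_i = int(np.floor(fractions[2] * n))
    order = np.random.default_rng(seed).permutation(n)
    shuffled = [positives[i] for i in order]
    s_set = shuffled[:n_s]
    i_set = shuffled[n_s:n_s + n_i]
    p_set = shuffled[n_s + n_i:]
    return DatasetSplit(P=tuple(p_set), S=tuple(s_set), I=tuple(i_set))


def write_manifest(path: str | Path, P: PairwiseAssociations,
                   X: AssociationTensor, seed: int | None = None,
                   extra: dict | None = None) -> None:
    """Record dims, association counts, tensor sparsity and the seed."""
    I, J, K = P.dims
    manifest = {
        "dims": {"drugs": I, "targets": J, "diseases": K},
        "associations": {
            "drug_target": int(P.A_CT.sum()),
            "drug_disease": int(P.A_CD.sum()),
            "target_disease": int(P.A_TD.sum()),
        },
        "tensor": {"triplets": X.nnz, "density": X.density},
        "seed": seed,
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2))
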