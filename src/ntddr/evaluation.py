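"""Evaluation protocol for drug-disease link prediction: negative
sampling, three cross-validation scenarios, AUC/AUPR, hyperparameter grid
search and top-k prediction extraction.

The evaluated matrix is the drug-disease association matrix A_CD.  Three
scenarios probe different prediction regimes:

* ``pairwise``     - individual known cells are masked (new associations
  between known drugs and known diseases);
* ``column_wise``  - whole disease columns are masked (cold-start
  diseases);
* ``row_wise``     - whole drug rows are masked (cold-start drugs).

Masked entries are zeroed in the training copy of A_CD, the association
tensor is rebuilt from the masked matrices (so the affected tensor fibers
vanish too), the model is refitted, and the drug-disease score matrix
A C' is read at the held-out cells.  Negatives are unknown cells sampled
uniformly (optionally after excluding cells that a similarity-propagation
score flags as likely-true), one negative per positive.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)

from . import ntd_model
from .data_pipeline import build_tensor
from .ntd_model import Hyperparameters, PairwiseAssociations
from .similarity import SimilaritySet

__all__ = [
    "CVPlan",
    "Fold",
    "MetricReport",
    "sample_negatives",
    "propagation_scores",
    "make_cv_plan",
    "mask_training",
    "auc_aupr",
    "cross_validate",
    "default_grids",
    "grid_search",
    "top_k",
    "case_study",
]

SCENARIOS = ("pairwise", "column_wise", "row_wise")


@dataclass(frozen=True)
class Fold:
    """Held-out cells for one CV fold.  ``units`` are the masked columns
    (column_wise) or rows (row_wise); empty for the pairwise scenario."""

    test_positives: np.ndarray  # (n, 2) cells of A_CD
    test_negatives: np.ndarray
    units: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))


@dataclass(frozen=True)
class CVPlan:
    scenario: str
    folds: tuple[Fold, ...]
    seed: int


@dataclass(frozen=True)
class MetricReport:
    """AUC and AUPR with pooled curve points and per-fold values."""

    auc: float
    aupr: float
    roc_points: pd.DataFrame
    pr_points: pd.DataFrame
    per_fold: tuple[dict, ...] = ()


def sample_negatives(
    M: np.ndarray,
    n: int,
    seed: int,
    exclusion_scores: np.ndarray | None = None,
    exclusion_quantile: float = 0.75,
) -> np.ndarray:
    """Draw ``n`` distinct unknown (zero) cells of ``M`` uniformly at
    random as negative samples.

    When ``exclusion_scores`` is given, zero cells scoring at or above the
    ``exclusion_quantile`` of zero-cell scores are excluded first: high
    propagation scores mark unknown cells likely to be undiscovered true
    associations, which would poison the negative set.
    """
    M = np.asarray(M)
    zeros = np.argwhere(M == 0)
    if exclusion_scores is not None:
        sc = np.asarray(exclusion_scores)
        if sc.shape != M.shape:
            raise ValueError("exclusion_scores shape must match the matrix")
        vals = sc[zeros[:, 0], zeros[:, 1]]
        thr = np.quantile(vals, exclusion_quantile)
        zeros = zeros[vals < thr]
    if n > len(zeros):
        raise ValueError(
            f"requested {n} negatives but only {len(zeros)} eligible zero cells"
        )
    idx = np.random.default_rng(seed).choice(len(zeros), size=n, replace=False)
    return zeros[np.sort(idx)]


def propagation_scores(
    M: np.ndarray, S_row: np.ndarray, S_col: np.ndarray
) -> np.ndarray:
    """Similarity-propagated association score S_row @ M @ S_col, scaled
    to [0, 1]; used as the exclusion score for negative filtering."""
    P = S_row @ M @ S_col
    top = P.max()
    return P / top if top > 0 else P


def _split_cells(cells: np.ndarray, k: int, rng) -> list[np.ndarray]:
    perm = rng.permutation(len(cells))
    return [cells[np.sort(part)] for part in np.array_split(perm, k)]


def make_cv_plan(
    M: np.ndarray,
    scenario: str,
    k: int = 10,
    seed: int = 0,
    negatives: np.ndarray | None = None,
    exclusion_scores: np.ndarray | None = None,
) -> CVPlan:
    """Partition the evaluation units of ``M`` into ``k`` disjoint folds.

    Positives and negatives are stratified separately so each fold keeps a
    1:1 ratio.  For ``column_wise``/``row_wise`` the partitioned units are
    whole columns/rows and a fold's test cells are the sampled cells lying
    in its units.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}, got {scenario!r}")
    M = np.asarray(M)
    rng = np.random.default_rng(seed)
    positives = np.argwhere(M == 1)
    if negatives is None:
        negatives = sample_negatives(M, len(positives), seed=seed + 1,
                                     exclusion_scores=exclusion_scores)
    if scenario == "pairwise":
        if k > len(positives) or k > len(negatives):
            raise ValueError(f"cannot make {k} folds from {len(positives)} positives")
        pos_folds = _split_cells(positives, k, rng)
        neg_folds = _split_cells(negatives, k, rng)
        folds = tuple(Fold(p, n) for p, n in zip(pos_folds, neg_folds))
    else:
        axis = 1 if scenario == "column_wise" else 0
        n_units = M.shape[axis]
        if k > n_units:
            raise ValueError(f"cannot make {k} folds from {n_units} units")
        unit_folds = [np.sort(part) for part in np.array_split(rng.permutation(n_units), k)]
        folds = []
        for units in unit_folds:
            in_fold = np.isin(positives[:, axis], units)
            in_fold_n = np.isin(negatives[:, axis], units)
            folds.append(Fold(positives[in_fold], negatives[in_fold_n], units=units))
        folds = tuple(folds)
    return CVPlan(scenario=scenario, folds=folds, seed=seed)


def mask_training(P: PairwiseAssociations, fold: Fold, scenario: str) -> PairwiseAssociations:
    """Training copy of the associations with the fold's test information
    removed from A_CD (A_CT and A_TD stay intact)."""
    A_CD = P.A_CD.copy()
    if scenario == "pairwise":
        if len(fold.test_positives):
            A_CD[fold.test_positives[:, 0], fold.test_positives[:, 1]] = 0.0
    elif scenario == "column_wise":
        A_CD[:, fold.units] = 0.0
    elif scenario == "row_wise":
        A_CD[fold.units, :] = 0.0
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return replace(P, A_CD=A_CD)


def auc_aupr(scores: Sequence[float], labels: Sequence[int]) -> MetricReport:
    """ROC and precision-recall summary of a scored sample.

    AUC is the probability a random positive outscores a random negative
    (ties count 1/2); AUPR follows the average-precision (step)
    convention.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    auc = float(roc_auc_score(labels, scores))
    aupr = float(average_precision_score(labels, scores))
    fpr, tpr, _ = roc_curve(labels, scores)
    prec, rec, _ = precision_recall_curve(labels, scores)
    return MetricReport(
        auc=auc,
        aupr=aupr,
        roc_points=pd.DataFrame({"fpr": fpr, "tpr": tpr}),
        pr_points=pd.DataFrame({"recall": rec, "precision": prec}),
    )


def cross_validate(
    P: PairwiseAssociations,
    S: SimilaritySet,
    H: Hyperparameters,
    scenario: str = "pairwise",
    k: int = 10,
    seed: int = 0,
    negatives: np.ndarray | None = None,
    exclusion_scores: np.ndarray | None = None,
    tensor_rule: str = "triangle",
) -> MetricReport:
    """Run one CV scenario end to end and pool the held-out scores.

    Each fold refits the model on masked data (the tensor is rebuilt from
    the masked matrices) and reads the drug-disease scores A C' at the
    fold's held-out positive and negative cells.
    """
    plan = make_cv_plan(P.A_CD, scenario, k=k, seed=seed, negatives=negatives,
                        exclusion_scores=exclusion_scores)
    all_scores, all_labels, per_fold = [], [], []
    for f_idx, fold in enumerate(plan.folds):
        P_train = mask_training(P, fold, scenario)
        X_train = build_tensor(P_train, rule=tensor_rule)
        H_fold = replace(H, seed=H.seed + f_idx)
        F, _ = ntd_model.fit(X_train, P_train, S, H_fold, track_kkt=False)
        P_CD = F.A @ F.C.T
        cells = np.vstack([fold.test_positives, fold.test_negatives])
        labels = np.concatenate([
            np.ones(len(fold.test_positives), dtype=int),
            np.zeros(len(fold.test_negatives), dtype=int),
        ])
        scores = P_CD[cells[:, 0], cells[:, 1]]
        all_scores.append(scores)
        all_labels.append(labels)
        entry: dict = {"fold": f_idx, "n_pos": int(labels.sum()),
                       "n_neg": int((1 - labels).sum())}
        if labels.sum() and (1 - labels).sum():
            entry["auc"] = float(roc_auc_score(labels, scores))
            entry["aupr"] = float(average_precision_score(labels, scores))
        per_fold.append(entry)
    pooled = auc_aupr(np.concatenate(all_scores), np.concatenate(all_labels))
    return replace(pooled, per_fold=tuple(per_fold))


def default_grids(dims: tuple[int, int, int]) -> dict[str, list]:
    """The hyperparameter grids used for model selection: rank from half
    and full entity counts, alpha in {0.1, 0.3, 0.4, 0.7, 0.9}, the tied
    drug-target / target-disease couplings over 1e-1..1e-4 and the target
    manifold weight over 1e-1..1e-5."""
    I, J, K = dims
    ranks = sorted({int(np.ceil(I / 2)), int(np.ceil(J / 2)), int(np.ceil(K / 2)), I, J, K})
    return {
        "rank": ranks,
        "alpha": [0.1, 0.3, 0.4, 0.7, 0.9],
        "lambda_tied": [1e-1, 1e-2, 1e-3, 1e-4],
        "gamma_t": [1e-1, 1e-2, 1e-3, 1e-4, 1e-5],
    }


def grid_search(
    P: PairwiseAssociations,
    S: SimilaritySet,
    base: Hyperparameters,
    grids: dict[str, list] | None = None,
    k: int = 10,
    seed: int = 0,
    tensor_rule: str = "triangle",
) -> tuple[Hyperparameters, pd.DataFrame]:
    """Exhaustive search over the hyperparameter grid by pairwise-CV AUC.

    ``grids`` maps hyperparameter names to candidate lists; the special
    key ``lambda_tied`` sets lambda_ct and lambda_td jointly.  Parameters
    absent from the grid stay at their ``base`` values (by convention the
    drug-disease coupling and the drug/disease manifold weights are fixed
    at 1).  Ties break toward smaller rank, then lexicographic parameter
    order; failed fits are recorded with a NaN score and skipped.
    """
    if grids is None:
        grids = default_grids(P.dims)
    if not grids or any(len(v) == 0 for v in grids.values()):
        raise ValueError("grids must be nonempty")
    names = sorted(grids, key=lambda n: {"rank": 0, "alpha": 1}.get(n, 2))
    rows = []
    best: tuple | None = None
    best_H = None
    for combo in itertools.product(*(sorted(grids[n]) for n in names)):
        params = dict(zip(names, combo))
        tied = params.pop("lambda_tied", None)
        if tied is not None:
            params["lambda_ct"] = params["lambda_td"] = tied
        params["rank"] = int(params.get("rank", base.rank))
        H = replace(base, **params)
        row = dict(params)
        try:
            report = cross_validate(P, S, H, scenario="pairwise", k=k, seed=seed,
                                    tensor_rule=tensor_rule)
            row["auc"], row["aupr"] = report.auc, report.aupr
        except (FloatingPointError, ValueError) as err:  # fit failure: skip config
            row["auc"], row["aupr"] = np.nan, np.nan
            row["error"] = str(err)
            rows.append(row)
            continue
        rows.append(row)
        key = (row["auc"], -H.rank) + tuple(
            -v for n, v in zip(names, combo) if n != "rank")
        if best is None or key > best:
            best, best_H = key, H
    table = pd.DataFrame(rows)
    if best_H is None:
        raise ValueError("every grid configuration failed to fit")
    return best_H, table


def top_k(
    P_CD: np.ndarray,
    disease: int,
    k: int = 50,
    known_mask: np.ndarray | None = None,
    drug_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Top-k drug candidates for one disease by descending score.

    Ties break by ascending drug index (stable).  ``known_mask`` flags
    drugs already associated with the disease; the rest are novel.
    """
    scores = np.asarray(P_CD)[:, disease]
    if k > len(scores):
        raise ValueError(f"k={k} exceeds the {len(scores)} available drugs")
    order = np.lexsort((np.arange(len(scores)), -scores))[:k]
    known = (np.asarray(known_mask, dtype=bool)[order]
             if known_mask is not None else np.zeros(k, dtype=bool))
    return pd.DataFrame({
        "rank": np.arange(1, k + 1),
        "drug_index": order,
        "drug_id": ([drug_ids[i] for i in order] if drug_ids is not None
                    else [f"DR{i:04d}" for i in order]),
        "score": scores[order],
        "known": known,
        "novel": ~known,
    })


def case_study(
    P: PairwiseAssociations,
    S: SimilaritySet,
    H: Hyperparameters,
    disease: int,
    k: int = 50,
    tensor_rule: str = "triangle",
) -> dict:
    """Blind rediscovery protocol for one disease.

    The disease's entire drug-association column is zeroed (and the tensor
    rebuilt), the model refitted, and the held-out true drugs looked up in
    the refitted drug-disease scores.  Returns the rank of every held-out
    drug among all drugs, plus a top-k candidate table with novelty flags.
    """
    held_out = np.flatnonzero(P.A_CD[:, disease] == 1)
    A_CD = P.A_CD.copy()
    A_CD[:, disease] = 0.0
    P_masked = replace(P, A_CD=A_CD)
    X = build_tensor(P_masked, rule=tensor_rule)
    F, trace = ntd_model.fit(X, P_masked, S, H, track_kkt=False)
    scores = (F.A @ F.C.T)[:, disease]
    order = np.lexsort((np.arange(len(scores)), -scores))
    rank_of = np.empty(len(scores), dtype=int)
    rank_of[order] = np.arange(1, len(scores) + 1)
    report = pd.DataFrame({
        "drug_index": held_out,
        "drug_id": [P.drug_ids[i] for i in held_out],
        "score": scores[held_out],
        "rank": rank_of[held_out],
        "n_candidates": len(scores),
    }).sort_values("rank", ignore_index=True)
    known_mask = P.A_CD[:, disease] == 1
    table = top_k(F.A @ F.C.T, disease, k=min(k, len(scores)),
                  known_mask=known_mask, drug_ids=P.drug_ids)
    return {"held_out": report, "top_k": table, "converged": trace.converged,
            "iterations": trace.iterations_run}
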