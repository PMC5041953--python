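"""Cross-validation and ranking evaluation.

Global leave-one-out cross-validation removes each known association in
turn, rebuilds every Y-dependent quantity (disease groups, profile kernels,
scores) without it, and asks how the left-out pair ranks among all candidate
pairs — pairs never observed as associated — pooled across all diseases.
The pooled AUC is the probability that a left-out association outscores a
random candidate pair (ties get half credit), which is exactly the
Mann-Whitney statistic of the left-out scores against the candidate scores
within each fold, averaged over folds.

Repeated k-fold cross-validation partitions the known associations at
random, holds out each fold once, and records one AUC per fold; the mean
and standard deviation over all folds and repetitions summarize performance.
A single integer seed drives all partitioning: repetition ``r`` of seed
``s`` uses the ``numpy`` seed sequence ``[s, r]`` so any repetition is
reproducible in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve

from .association_data import AdjacencyMatrix, AssociationTable
from .exceptions import IlncsimError, UnknownTermError
from .prediction_lrlslda import Pipeline, ScoreMatrix


@dataclass
class CVResult:
    """AUCs (one per fold/repetition), their summary, and representative ROC points."""

    auc_values: list[float]
    mean_auc: float
    std_auc: float
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    method: str = ""

    def to_json(self, path_or_buf=None) -> str:
        payload = {
            "method": self.method,
            "mean_auc": self.mean_auc,
            "std_auc": self.std_auc,
            "n_auc_values": len(self.auc_values),
            "auc_values": self.auc_values,
        }
        text = json.dumps(payload, indent=2)
        if path_or_buf is not None:
            if hasattr(path_or_buf, "write"):
                path_or_buf.write(text)
            else:
                with open(path_or_buf, "w", encoding="utf-8") as fh:
                    fh.write(text)
        return text


def roc_auc(scores, labels) -> tuple[float, list[tuple[float, float]]]:
    """AUC with tie half-credit (Mann-Whitney form) plus the ROC polyline.

    The AUC is computed from midranks — algebraically identical to the
    trapezoidal area under the empirical ROC — so tied scores contribute
    half credit per tied positive/negative pair.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D vectors")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise IlncsimError("ROC needs at least one positive and one negative label")
    from scipy.stats import rankdata

    ranks = rankdata(scores)  # midranks handle ties
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    auc = u / (n_pos * n_neg)
    fpr, tpr, _ = roc_curve(labels, scores)
    return float(auc), list(zip(fpr.tolist(), tpr.tolist()))


def _fold_positions(adjacency: AdjacencyMatrix) -> list[tuple[int, int]]:
    rows, cols = np.nonzero(adjacency.values)
    return list(zip(rows.tolist(), cols.tolist()))


def global_loocv(association_table: AssociationTable, pipeline: Pipeline) -> CVResult:
    """Leave each known association out in turn; pooled rank-based AUC.

    Per fold, the left-out pair's score is compared with the scores of every
    candidate (never-known) pair across all diseases simultaneously; the
    per-fold Mann-Whitney fractions average into the global AUC. Fully
    deterministic — there is no randomness to seed.
    """
    adjacency = pipeline.prepare(association_table)
    Y = adjacency.values.astype(np.int8)
    known = _fold_positions(adjacency)
    if len(known) < 2:
        raise IlncsimError("global LOOCV needs at least 2 known associations")
    candidate_mask = Y == 0
    u_fracs: list[float] = []
    for fold, (i, j) in enumerate(known):
        Y_fold = Y.copy()
        Y_fold[i, j] = 0
        try:
            F = pipeline.scores(Y_fold).values
        except Exception as exc:  # pragma: no cover - defensive
            raise IlncsimError(f"pipeline failed on LOOCV fold {fold} "
                               f"(pair {adjacency.lncrna_ids[i]}, "
                               f"{adjacency.disease_ids[j]}): {exc}") from exc
        pos = F[i, j]
        cand = F[candidate_mask]
        u = (cand < pos).sum() + 0.5 * (cand == pos).sum()
        u_fracs.append(float(u) / cand.size)
    auc = float(np.mean(u_fracs))
    # ROC over normalized ranks: threshold t on the normalized candidate rank,
    # FPR(t) = t, TPR(t) = fraction of left-out pairs ranked within t.
    xs = np.sort(1.0 - np.asarray(u_fracs))
    roc_points = [(0.0, 0.0)]
    for k, x in enumerate(xs, start=1):
        roc_points.append((float(x), k / len(xs)))
    roc_points.append((1.0, 1.0))
    return CVResult(auc_values=u_fracs, mean_auc=auc,
                    std_auc=float(np.std(u_fracs)), roc_points=roc_points,
                    method="global_loocv")


def kfold_cv(association_table: AssociationTable, pipeline: Pipeline,
             k: int = 5, repetitions: int = 1, seed: int = 0) -> CVResult:
    """Repeated k-fold CV over known associations; one AUC per held-out fold.

    Test-fold pairs are scored against pairs that were never known
    associations (other folds' held-out pairs are excluded from the
    candidate set). Identical seeds give identical partitions and results.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if repetitions < 1:
        raise ValueError("repetitions must be at least 1")
    adjacency = pipeline.prepare(association_table)
    Y = adjacency.values.astype(np.int8)
    known = _fold_positions(adjacency)
    if len(known) < k:
        raise IlncsimError(f"only {len(known)} associations; cannot split into {k} folds")
    never_known = Y == 0
    aucs: list[float] = []
    roc_points: list[tuple[float, float]] = []
    for rep in range(repetitions):
        rng = np.random.default_rng([seed, rep])
        order = rng.permutation(len(known))
        folds = np.array_split(order, k)
        for fold_idx in folds:
            Y_fold = Y.copy()
            test_pairs = [known[t] for t in fold_idx]
            for (i, j) in test_pairs:
                Y_fold[i, j] = 0
            F = pipeline.scores(Y_fold).values
            pos_scores = np.array([F[i, j] for (i, j) in test_pairs])
            neg_scores = F[never_known]
            scores = np.concatenate([pos_scores, neg_scores])
            labels = np.concatenate([np.ones(pos_scores.size, dtype=int),
                                     np.zeros(neg_scores.size, dtype=int)])
            auc, points = roc_auc(scores, labels)
            aucs.append(auc)
            if not roc_points:  # representative curve: first fold of first repetition
                roc_points = points
    return CVResult(auc_values=aucs, mean_auc=float(np.mean(aucs)),
                    std_auc=float(np.std(aucs)), roc_points=roc_points,
                    method=f"{k}-fold x {repetitions}")


def rank_candidates(score_matrix: ScoreMatrix, adjacency: AdjacencyMatrix | AssociationTable,
                    disease: str, top_k: int = 20) -> list[tuple[int, str, float]]:
    """Top-k candidate lncRNAs for a disease, excluding known partners.

    Returns (rank, lncrna_id, score) with rank starting at 1; ties are
    ordered lexicographically by id so output is deterministic.
    """
    if isinstance(adjacency, AssociationTable):
        from .association_data import to_matrix

        adjacency = to_matrix(adjacency)
    if disease not in score_matrix._col_index:
        raise UnknownTermError(f"disease {disease!r} not in score matrix")
    j = score_matrix.col_position(disease)
    dj = adjacency.disease_ids.index(disease) if disease in adjacency.disease_ids else None
    out = []
    for i, lnc in enumerate(score_matrix.row_labels):
        known = False
        if dj is not None and lnc in adjacency.lncrna_ids:
            known = bool(adjacency.values[adjacency.lncrna_ids.index(lnc), dj])
        if not known:
            out.append((lnc, float(score_matrix.values[i, j])))
    out.sort(key=lambda t: (-t[1], t[0]))
    return [(rank, lnc, score) for rank, (lnc, score) in enumerate(out[:top_k], start=1)]
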