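"""Ranking evaluation of score matrices against held-out labels.

The predictor never consumes lncRNA-disease labels, so evaluation reduces
to ranking: known associations are positives, every other lncRNA-disease
pair is an unlabeled negative.  Leave-one-out therefore aggregates to the
global ranking AUC of positives versus unlabeled pairs (Mann-Whitney with
midrank tie correction); k-fold partitions the positives only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import precision_recall_curve, roc_curve

from .data_io import BipartiteNetwork
from .exceptions import DataError
from .latent_factor import ScoreMatrix

# confusion_at_threshold is only materialized for sweeps up to this many
# distinct thresholds; beyond that it is left empty to bound memory.
_MAX_STORED_THRESHOLDS = 1000


@dataclass
class EvaluationResult:
    """ROC/PR curves, scalar AUC/AUPR, and optional per-fold breakdown."""

    auc: float
    aupr: float | None = None
    roc_points: np.ndarray | None = None  # (n, 2) columns FPR, TPR
    pr_points: np.ndarray | None = None  # (n, 2) columns recall, precision
    per_fold_auc: list[float] | None = None
    confusion_at_threshold: dict[float, tuple[int, int, int, int]] = field(
        default_factory=dict
    )

    def to_dict(self) -> dict:
        out = {"auc": self.auc, "aupr": self.aupr}
        if self.per_fold_auc is not None:
            out["per_fold_auc"] = self.per_fold_auc
        if self.roc_points is not None:
            out["roc_points"] = self.roc_points.tolist()
        if self.pr_points is not None:
            out["pr_points"] = self.pr_points.tolist()
        return out


def _align(scores: ScoreMatrix, labels: BipartiteNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Flatten scores and 0/1 labels over the pairs present in both axes."""
    rows = [n for n in scores.lncrna_names if n in set(labels.row_names)]
    cols = [n for n in scores.disease_names if n in set(labels.col_names)]
    if not rows or not cols:
        raise DataError("label axes share no entities with the score matrix")
    si = {n: i for i, n in enumerate(scores.lncrna_names)}
    sj = {n: j for j, n in enumerate(scores.disease_names)}
    li = {n: i for i, n in enumerate(labels.row_names)}
    lj = {n: j for j, n in enumerate(labels.col_names)}
    s = scores.values[np.ix_([si[n] for n in rows], [sj[n] for n in cols])]
    y = labels.adjacency[np.ix_([li[n] for n in rows], [lj[n] for n in cols])]
    return s.ravel(), y.ravel()


def confusion_counts(
    scores: ScoreMatrix, labels: BipartiteNetwork, threshold: float
) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) at one threshold; score >= threshold predicts 1."""
    s, y = _align(scores, labels)
    if y.sum() == 0:
        raise DataError("no labeled positive pair; TPR undefined")
    pred = s >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    return tp, fp, tn, fn


def ranking_auc(scores_flat: np.ndarray, labels_flat: np.ndarray) -> float:
    """Mann-Whitney AUC of positives vs negatives with midrank ties."""
    n_pos = int(labels_flat.sum())
    n_neg = labels_flat.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DataError("AUC needs at least one positive and one negative")
    ranks = rankdata(scores_flat)
    pos_rank_sum = ranks[labels_flat == 1].sum()
    return float((pos_rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _curves(s: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, dict]:
    fpr, tpr, thresholds = roc_curve(y, s, drop_intermediate=False)
    roc_points = np.column_stack([fpr, tpr])
    precision, recall, _ = precision_recall_curve(y, s)
    # precision_recall_curve returns recall descending; flip to ascending
    pr_points = np.column_stack([recall[::-1], precision[::-1]])

    confusion: dict[float, tuple[int, int, int, int]] = {}
    if thresholds.size <= _MAX_STORED_THRESHOLDS:
        n_pos, n_neg = int(y.sum()), int((y == 0).sum())
        for f, t, thr in zip(fpr, tpr, thresholds):
            if not np.isfinite(thr):
                continue
            tp = int(round(t * n_pos))
            fp = int(round(f * n_neg))
            confusion[float(thr)] = (tp, fp, n_neg - fp, n_pos - tp)
    return roc_points, pr_points, confusion


def loocv_auc(scores: ScoreMatrix, labels: BipartiteNetwork) -> EvaluationResult:
    """Leave-one-out evaluation of a fixed score matrix.

    Each known association held out in turn and ranked against all
    unlabeled pairs aggregates to the global positives-vs-unlabeled
    ranking AUC, since the scores do not depend on the labels.
    """
    s, y = _align(scores, labels)
    auc = ranking_auc(s, y)
    roc_points, pr_points, confusion = _curves(s, y)
    aupr = float(np.trapezoid(pr_points[:, 1], pr_points[:, 0]))
    return EvaluationResult(
        auc=auc, aupr=aupr, roc_points=roc_points, pr_points=pr_points,
        confusion_at_threshold=confusion,
    )


def kfold_auc(
    scores: ScoreMatrix, labels: BipartiteNetwork, k: int, seed: int = 0
) -> EvaluationResult:
    """Partition positives into k seeded folds and average per-fold AUC.

    Each fold's positives are ranked against all unlabeled pairs; the
    positives of the other folds are excluded from the ranking.  With k
    equal to the number of positives this reproduces :func:`loocv_auc`'s
    aggregate AUC.
    """
    if k < 2:
        raise DataError("k must be >= 2")
    s, y = _align(scores, labels)
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    if pos_idx.size < k:
        raise DataError(f"k={k} exceeds the number of positives ({pos_idx.size})")
    if neg_idx.size == 0:
        raise DataError("no unlabeled pair to rank against")
    rng = np.random.default_rng(seed)
    folds = np.array_split(rng.permutation(pos_idx), k)
    per_fold = []
    for fold in folds:
        idx = np.concatenate([fold, neg_idx])
        yy = np.zeros(idx.size)
        yy[: fold.size] = 1.0
        per_fold.append(ranking_auc(s[idx], yy))
    return EvaluationResult(auc=float(np.mean(per_fold)), per_fold_auc=per_fold)


def rank_candidates(
    scores: ScoreMatrix,
    disease: str,
    exclude: set[str] | None = None,
    top_n: int = 15,
) -> list[tuple[int, str, float]]:
    """Top candidate lncRNAs for one disease, by descending score.

    ``exclude`` removes already-known positives before ranking; ties are
    broken by lncRNA name order so output is reproducible.
    """
    if disease not in scores.disease_names:
        raise DataError(f"unknown disease {disease!r}")
    j = scores.disease_names.index(disease)
    exclude = exclude or set()
    candidates = [
        (name, float(scores.values[i, j]))
        for i, name in enumerate(scores.lncrna_names)
        if name not in exclude
    ]
    candidates.sort(key=lambda t: (-t[1], t[0]))
    return [(rank, name, score)
            for rank, (name, score) in enumerate(candidates[:top_n], start=1)]
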