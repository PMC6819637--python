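"""Per-residue evaluation: confusion counts, ROC curves, AUC, and
metrics-at-fixed-TPR tables.

A residue is called MoRF when its score strictly exceeds the threshold.
ACC = (TP + TN) / (N_MoRF + N_non), TPR = TP / N_MoRF, and FPR = FP / N_non
(the standard false-positive rate). The AUC equals the probability that a
random MoRF residue outscores a random non-MoRF residue, with half credit
for ties; it is computed as the trapezoidal area under the tie-grouped ROC
step curve, which realizes exactly that convention.

Labels may carry a third state, -1, marking residues excluded from
evaluation (used by the short/long MoRF-region masking protocol); use
``drop_ignored`` before calling the metric functions.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import ValidationError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n_morf(self) -> int:
        return self.tp + self.fn

    @property
    def n_non(self) -> int:
        return self.tn + self.fp

    @property
    def acc(self) -> float:
        return (self.tp + self.tn) / (self.n_morf + self.n_non)

    @property
    def tpr(self) -> float:
        return self.tp / self.n_morf if self.n_morf else float("nan")

    @property
    def fpr(self) -> float:
        return self.fp / self.n_non if self.n_non else float("nan")


def _validate(scores, labels, require_both: bool = False) -> tuple:
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels must have equal length")
    if not np.all(np.isin(labels, (0, 1))):
        raise ValidationError("labels must be binary (use drop_ignored first)")
    if require_both and (labels.min() == labels.max() or labels.size == 0):
        raise ValidationError("need both classes present")
    return scores, labels.astype(np.int8)


def drop_ignored(scores, labels) -> tuple:
    """Remove residues flagged -1 (excluded regions) before metric calls."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    keep = labels >= 0
    return scores[keep], labels[keep]


def confusion(scores, labels, threshold: float = 0.0) -> ConfusionCounts:
    """Confusion counts at a threshold, with the strict > call rule."""
    scores, labels = _validate(scores, labels)
    calls = scores > threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(calls & pos)),
        tn=int(np.sum(~calls & ~pos)),
        fp=int(np.sum(calls & ~pos)),
        fn=int(np.sum(~calls & pos)),
    )


def roc_curve(scores, labels) -> tuple:
    """ROC step curve over all distinct thresholds.

    Returns ``(fpr, tpr, thresholds)`` starting at (0, 0) and ending at
    (1, 1); tied scores collapse into a single vertex, so the trapezoidal
    area gives ties half credit.
    """
    scores, labels = _validate(scores, labels, require_both=True)
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    y = labels[order]
    distinct = np.r_[np.flatnonzero(np.diff(s)), s.size - 1]
    tp = np.cumsum(y)[distinct]
    fp = np.cumsum(1 - y)[distinct]
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    fpr = np.r_[0.0, fp / n_neg]
    tpr = np.r_[0.0, tp / n_pos]
    thresholds = np.r_[np.inf, s[distinct]]
    return fpr, tpr, thresholds


def roc_auc(scores, labels) -> tuple:
    """The ROC curve and its area. The area equals the pairwise
    probability P(score_pos > score_neg) + 0.5 * P(tie)."""
    fpr, tpr, thresholds = roc_curve(scores, labels)
    auc = float(np.trapezoid(tpr, fpr))
    return (fpr, tpr, thresholds), auc


def metrics_at_tpr(scores, labels, tpr_targets) -> list:
    """For each TPR target, the largest threshold achieving TPR >= target,
    with the achieved (TPR, FPR, ACC) triple.

    Returns a list of dicts with keys target, threshold, tpr, fpr, acc.
    """
    scores, labels = _validate(scores, labels, require_both=True)
    pos_sorted = np.sort(scores[labels == 1])
    neg_sorted = np.sort(scores[labels == 0])
    n_pos, n_neg = pos_sorted.size, neg_sorted.size
    # descending candidates; TPR is non-decreasing as the threshold drops
    candidates = np.unique(scores)[::-1]
    candidates = np.concatenate((candidates, [scores.min() - 1.0]))
    out = []
    for target in tpr_targets:
        if not (0 <= target <= 1):
            raise ValidationError(f"TPR target {target} outside [0, 1]")
        chosen = None
        for t in candidates:
            tpr = (n_pos - np.searchsorted(pos_sorted, t, side="right")) / n_pos
            if tpr >= target:
                chosen = float(t)
                break
        fpr = float((n_neg - np.searchsorted(neg_sorted, chosen, side="right")) / n_neg)
        tpr = float((n_pos - np.searchsorted(pos_sorted, chosen, side="right")) / n_pos)
        c = confusion(scores, labels, threshold=chosen)
        out.append(
            {"target": float(target), "threshold": chosen,
             "tpr": tpr, "fpr": fpr, "acc": c.acc}
        )
    return out
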