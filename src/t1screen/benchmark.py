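"""Benchmarking the interaction matrix against known interactions.

Detection is a strict threshold on the relaxation factor (ΔRF > cutoff).
Pairs present in the reference set are positives, all other evaluable pairs
negatives; TPR = TP/(TP+FN) and FPR = FP/(FP+TN) traced over candidate
cutoffs give the ROC curve, and the operating cutoff is chosen as the
smallest cutoff whose FPR stays at or below a target (5% in the screen),
which maximises TPR subject to that bound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .interactions import InteractionMatrix
from .tables import ReferenceSet

MISSING_POLICIES = ("exclude", "negative")


@dataclass(frozen=True)
class ConfusionCounts:
    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.fp + self.tn

    @property
    def tpr(self) -> float:
        return self.tp / self.positives if self.positives else float("nan")

    @property
    def fpr(self) -> float:
        return self.fp / self.negatives if self.negatives else float("nan")

    @property
    def n_detected(self) -> int:
        return self.tp + self.fp


@dataclass(frozen=True)
class RocPoint:
    cutoff: float
    tpr: float
    fpr: float


def _scores_and_labels(
    matrix: InteractionMatrix, reference: ReferenceSet, missing: str = "exclude"
):
    """Flatten the matrix into (score, is_known) arrays.

    ``missing='exclude'`` drops unevaluable cells from both classes (their
    count is reported separately); ``missing='negative'`` scores them as
    never-detected with ΔRF of -inf.
    """
    if missing not in MISSING_POLICIES:
        raise ValueError(f"missing policy must be one of {MISSING_POLICIES}")
    prots = set(matrix.proteins)
    mets = set(matrix.metabolites)
    for (p, m) in reference.pairs():
        if p not in prots or m not in mets:
            raise ValueError(f"reference entry {(p, m)} outside the matrix rosters")
    scores, labels = [], []
    n_missing = 0
    for p in matrix.proteins:
        for m in matrix.metabolites:
            v = matrix.delta_rf.at[p, m]
            if pd.isna(v):
                n_missing += 1
                if missing == "exclude":
                    continue
                v = -np.inf
            scores.append(float(v))
            labels.append((p, m) in reference)
    return np.asarray(scores), np.asarray(labels, dtype=bool), n_missing


def confusion_at_cutoff(
    matrix: InteractionMatrix,
    reference: ReferenceSet,
    cutoff: float,
    missing: str = "exclude",
) -> ConfusionCounts:
    """Exact confusion counts at one ΔRF cutoff (detection is strict >)."""
    scores, labels, _ = _scores_and_labels(matrix, reference, missing)
    detected = scores > cutoff
    return ConfusionCounts(
        cutoff=cutoff,
        tp=int(np.sum(detected & labels)),
        fp=int(np.sum(detected & ~labels)),
        tn=int(np.sum(~detected & ~labels)),
        fn=int(np.sum(~detected & labels)),
    )


def roc_curve(
    matrix: InteractionMatrix,
    reference: ReferenceSet,
    cutoffs=None,
    missing: str = "exclude",
) -> list:
    """ROC points over candidate cutoffs, sorted by ascending cutoff.

    The default candidate set is every observed ΔRF value plus {0, 0.5}
    (an exact ROC); pass an explicit grid, e.g. ``numpy.arange(0, 0.5,
    0.0005)``, for a fixed-grid sweep.  Requires at least one positive and
    one negative among the evaluable pairs.
    """
    scores, labels, _ = _scores_and_labels(matrix, reference, missing)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"degenerate reference: {n_pos} positives / {n_neg} negatives "
            "among evaluable pairs"
        )
    if cutoffs is None:
        cutoffs = np.unique(np.concatenate([scores[np.isfinite(scores)], [0.0, 0.5]]))
    cutoffs = np.sort(np.asarray(cutoffs, dtype=float))
    points = []
    for c in cutoffs:
        detected = scores > c
        tp = int(np.sum(detected & labels))
        fp = int(np.sum(detected & ~labels))
        points.append(RocPoint(float(c), tp / n_pos, fp / n_neg))
    return points


def select_cutoff(roc: list, target_fpr: float) -> tuple[float, float, float]:
    """Operating cutoff at a target false-positive rate.

    Returns the smallest candidate cutoff whose FPR is at or below the
    target (TPR and FPR are non-increasing in the cutoff, so this maximises
    TPR subject to the bound), together with the achieved (tpr, fpr).  If no
    candidate satisfies the bound the minimum-FPR corner is returned.
    """
    if not roc:
        raise ValueError("empty ROC curve")
    ordered = sorted(roc, key=lambda pt: pt.cutoff)
    for pt in ordered:
        if pt.fpr <= target_fpr:
            return pt.cutoff, pt.tpr, pt.fpr
    corner = min(ordered, key=lambda pt: (pt.fpr, pt.cutoff))
    return corner.cutoff, corner.tpr, corner.fpr


def auc(roc: list) -> float:
    """Trapezoidal area under the ROC curve over fpr in [0, 1]."""
    if not roc:
        raise ValueError("empty ROC curve")
    pts = sorted(roc, key=lambda pt: (pt.fpr, pt.tpr))
    fpr = np.concatenate([[0.0], [pt.fpr for pt in pts], [1.0]])
    tpr = np.concatenate([[0.0], [pt.tpr for pt in pts], [1.0]])
    return float(np.trapezoid(tpr, fpr))


# ----------------------------------------------------------------------
# Closed-form confusion arithmetic from summary counts


def confusion_from_counts(
    n_proteins: int,
    n_metabolites: int,
    n_known: int,
    n_detected: int,
    n_known_detected: int,
    cutoff: float = float("nan"),
) -> ConfusionCounts:
    """Confusion counts implied by screen-level summary numbers.

    Given the roster sizes, the number of known interactions, the number of
    detections and how many of those were known, the remaining cells of the
    confusion matrix follow by arithmetic: FP = detected - known detected,
    FN = known - known detected, TN = everything else.
    """
    total = n_proteins * n_metabolites
    if n_known_detected > min(n_known, n_detected):
        raise ValueError("known detections cannot exceed known or detected totals")
    tp = n_known_detected
    fp = n_detected - n_known_detected
    fn = n_known - n_known_detected
    tn = total - tp - fp - fn
    if tn < 0:
        raise ValueError("counts exceed the roster grid")
    return ConfusionCounts(cutoff=cutoff, tp=tp, fp=fp, tn=tn, fn=fn)


def mean_partners(n_detections: int, n_interacting: int) -> float:
    """Average number of partners per interacting entity (e.g. detections
    per metabolite that has at least one)."""
    if n_interacting <= 0:
        raise ValueError("need at least one interacting entity")
    return n_detections / n_interacting
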