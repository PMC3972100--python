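"""Ranked-classification and ranking metrics, self-implemented.

ROC curves are built by a descending-score threshold sweep with tied
scores processed as a single step (a diagonal segment), AUC by the
trapezoid rule.  The AUC is simultaneously computed as the normalized
count of concordant pairs (the Mann–Whitney statistic, tied
positive–negative pairs credited 0.5) and the two routes must agree to
1e-12 — a structural self-check that the curve construction and the
pair-counting view describe the same ranking.

Early enrichment is reported as the true-positive rate while the false
positive rate is still exactly zero, i.e. the fraction of actives ranked
strictly above every decoy; a positive tied with a negative does not
count (the negative is taken to enter the ranking first).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

_AGREEMENT_TOL = 1e-12


@dataclass
class ROCResult:
    """ROC curve points, AUC, and enrichment summary for one ranking."""

    points: list[tuple[float, float]]  # (FPR, TPR), from (0,0) to (1,1)
    auc: float
    n_pos: int
    n_neg: int
    tpr_at_zero_fpr: float


def roc(scores: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """ROC analysis of decision values against binary labels.

    Parameters
    ----------
    scores
        Decision values; higher means more confidently positive.
    labels
        1 (or truthy) for positives, 0 for negatives.

    Raises
    ------
    ValueError
        On length mismatch or single-class input (an AUC needs at least
        one positive and one negative).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray([1 if lab else 0 for lab in labels], dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and of equal length")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative")

    # Threshold sweep, one step per distinct score value.
    order = np.argsort(-s, kind="mergesort")
    s_sorted, y_sorted = s[order], y[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < s_sorted.size:
        j = i
        while j < s_sorted.size and s_sorted[j] == s_sorted[i]:
            j += 1
        tp += int(y_sorted[i:j].sum())
        fp += (j - i) - int(y_sorted[i:j].sum())
        points.append((fp / n_neg, tp / n_pos))
        i = j
    auc_trap = 0.0
    for (x0, y0), (x1, y1) in zip(points, points[1:]):
        auc_trap += (x1 - x0) * (y0 + y1) / 2.0

    # Independent route: Mann–Whitney pair counting via mid-ranks.
    ranks = rankdata(s, method="average")
    u = float(ranks[y == 1].sum()) - n_pos * (n_pos + 1) / 2.0
    auc_pairs = u / (n_pos * n_neg)
    if abs(auc_trap - auc_pairs) > _AGREEMENT_TOL:
        raise AssertionError(
            f"trapezoid AUC {auc_trap!r} and pair-count AUC {auc_pairs!r} disagree"
        )

    # TPR while FPR == 0, pessimistic on ties with negatives.
    tpr0 = 0.0
    for fpr, tpr in points:
        if fpr > 0:
            break
        tpr0 = tpr
    return ROCResult(
        points=points, auc=auc_trap, n_pos=n_pos, n_neg=n_neg, tpr_at_zero_fpr=tpr0
    )


def tpr_at_zero_fpr(roc_result: ROCResult) -> float:
    """Fraction of positives ranked above every negative (early enrichment)."""
    return roc_result.tpr_at_zero_fpr


def rank_correlation(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties.

    Used to judge rank-ordering of congeneric series, where the question
    is whether small structural changes move predictions in the right
    direction, not whether absolute values agree.
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.ndim != 1:
        raise ValueError("predicted and observed must be 1-D and of equal length")
    if p.size < 3:
        raise ValueError("need at least 3 pairs")
    rp = rankdata(p, method="average")
    ro = rankdata(o, method="average")
    if np.ptp(rp) == 0 or np.ptp(ro) == 0:
        raise ValueError("constant vector has no rank correlation")
    rp = rp - rp.mean()
    ro = ro - ro.mean()
    return float(rp @ ro / np.sqrt((rp @ rp) * (ro @ ro)))


def evaluation_report(
    rows: Sequence[dict], path: Path | str | None = None
) -> "pd.DataFrame":
    """Tabulate named ROC evaluations; optionally write delimited text.

    Each row dict needs ``model``, ``set`` and an :class:`ROCResult`
    under ``roc``.
    """
    import pandas as pd

    frame = pd.DataFrame(
        [
            {
                "model": row["model"],
                "set": row["set"],
                "auc": row["roc"].auc,
                "tpr_at_zero_fpr": row["roc"].tpr_at_zero_fpr,
                "n_pos": row["roc"].n_pos,
                "n_neg": row["roc"].n_neg,
            }
            for row in rows
        ]
    )
    if path is not None:
        frame.to_csv(path, sep="\t", index=False)
    return frame


def curve_to_frame(roc_result: ROCResult) -> "pd.DataFrame":
    """Curve points as a two-column table for plotting/export."""
    import pandas as pd

    return pd.DataFrame(roc_result.points, columns=["fpr", "tpr"])
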