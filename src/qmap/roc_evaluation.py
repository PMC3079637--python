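"""ROC curves and the three summary metrics used throughout the package.

A ROC curve summarises the trade-off between the true positive rate (TPR,
sensitivity) and the false positive rate (FPR, 1 - specificity) along a
ranked list of mutant pairs. Three scalars summarise it:

* AUC - area under the full curve (0.5 for a random ranking, 1 for ideal);
* pAUC(r) - area over FPR in [0, r], divided by r (no TPR rescaling);
  the diagonal chance curve has raw area r^2/2, so a random ranking
  scores r/2 = 0.05 at the default r = 0.1;
* early sensitivity - the TPR of the step curve at the largest achieved
  FPR at or below a small cut (default 0.01), reflecting the very top of
  the candidate list.

Tied scores are collapsed into single thresholds, producing diagonal
segments whose trapezoidal area equals the Mann-Whitney statistic with
ties counted 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

DEFAULT_PAUC_R = 0.1
DEFAULT_EARLY_FPR = 0.01


@dataclass
class ROCResult:
    """A ROC step curve with its summary metrics.

    ``fpr_points``/``tpr_points`` run from (0, 0) to (1, 1) and are
    non-decreasing; ``auc``, ``pauc_r`` (at ``r``) and ``early_tpr`` (at
    ``early_fpr``) are the three summaries.
    """

    fpr_points: np.ndarray
    tpr_points: np.ndarray
    n_pos: int
    n_neg: int
    auc: float
    r: float = DEFAULT_PAUC_R
    pauc_r: float = field(default=np.nan)
    early_fpr: float = DEFAULT_EARLY_FPR
    early_tpr: float = field(default=np.nan)


def roc_curve(scores, labels) -> ROCResult:
    """Build the ROC step curve for binary ``labels`` ranked by ``scores``
    (higher score = stronger call).

    Requires at least one positive and one negative label and finite
    scores. Tied scores collapse into a single step.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValidationError("scores and labels must be 1-D and aligned")
    if np.any(np.isnan(scores)):
        raise ValidationError("scores contain NaN; drop undefined entries first")
    labels = labels.astype(bool)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValidationError(
            f"need both classes present (n_pos={n_pos}, n_neg={n_neg})"
        )
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    lab = labels[order]
    # collapse tied thresholds
    distinct = np.r_[np.nonzero(np.diff(s))[0], s.size - 1]
    tp = np.cumsum(lab)[distinct]
    fp = np.cumsum(~lab)[distinct]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    roc = ROCResult(fpr_points=fpr, tpr_points=tpr, n_pos=n_pos, n_neg=n_neg,
                    auc=auc)
    roc.pauc_r = partial_auc(roc, roc.r)
    roc.early_tpr = early_sensitivity(roc, roc.early_fpr)
    return roc


def partial_auc(roc: ROCResult, r: float = DEFAULT_PAUC_R) -> float:
    """Normalised partial AUC: trapezoidal area over FPR in [0, r]
    (linear interpolation at r), divided by r.

    ``partial_auc(roc, 1.0)`` equals the full AUC; a random ranking gives
    r/2 on the raw area, i.e. 0.05 after normalisation at r = 0.1.
    """
    if not (0.0 < r <= 1.0):
        raise ValidationError(f"r must lie in (0, 1]; got {r}")
    fpr, tpr = roc.fpr_points, roc.tpr_points
    if r < fpr[-1]:
        tpr_at_r = float(np.interp(r, fpr, tpr))
        keep = fpr <= r
        f = np.r_[fpr[keep], r]
        t = np.r_[tpr[keep], tpr_at_r]
    else:
        f, t = fpr, tpr
    return float(np.trapezoid(t, f)) / r


def early_sensitivity(roc: ROCResult, fpr0: float = DEFAULT_EARLY_FPR) -> float:
    """TPR of the step curve at the largest achieved FPR <= ``fpr0``
    (no interpolation).

    With few negatives, FPR = fpr0 may be unreachable; the value is then
    the TPR at FPR = 0, which is conservative.
    """
    if not (0.0 < fpr0 < 1.0):
        raise ValidationError(f"fpr0 must lie in (0, 1); got {fpr0}")
    keep = roc.fpr_points <= fpr0
    return float(roc.tpr_points[keep].max())
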