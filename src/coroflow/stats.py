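"""Threshold-determination statistics for paired pressure indices.

Covers the workflow used to map one diagnostic index onto another:
confusion-matrix metrics, Bland-Altman agreement, Pearson correlation,
polynomial relations between paired indices with threshold extraction at a
reference cut-off, and ROC analysis with Youden-optimal thresholding.

Conventions (documented, since they matter at the boundary):
* the positive (diseased) class is index value strictly BELOW the cut-off;
* a value exactly at a threshold classifies negative;
* ROC thresholds are swept over the observed values plus sentinels, the AUC
  is the trapezoid over the resulting step curve (equal to the Mann-Whitney
  statistic), and threshold ties on Youden's J break toward the higher
  threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "diagnostic_metrics",
    "classify",
    "confusion_from_indices",
    "fit_polynomial",
    "threshold_from_fit",
    "bland_altman",
    "pearson",
    "roc",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def diagnostic_metrics(cm: ConfusionMatrix) -> dict[str, float | None]:
    """Sensitivity, specificity, PPV, NPV and accuracy, in percent.

    A metric whose denominator is zero is reported as None (undefined),
    never as a silent NaN.
    """

    def pct(num: int, den: int) -> float | None:
        return 100.0 * num / den if den > 0 else None

    return {
        "sensitivity": pct(cm.tp, cm.tp + cm.fn),
        "specificity": pct(cm.tn, cm.tn + cm.fp),
        "ppv": pct(cm.tp, cm.tp + cm.fp),
        "npv": pct(cm.tn, cm.tn + cm.fn),
        "accuracy": pct(cm.tp + cm.tn, cm.total),
    }


def classify(values, threshold: float, positive_below: bool = True) -> np.ndarray:
    """Boolean disease classification of index values against a cut-off.

    Strict inequality: a value equal to the threshold is negative.
    """
    v = np.asarray(values, dtype=float)
    return v < threshold if positive_below else v > threshold


def confusion_from_indices(values, reference_positive, threshold: float) -> ConfusionMatrix:
    """Confusion matrix of ``values < threshold`` against reference labels."""
    pred = classify(values, threshold)
    ref = np.asarray(reference_positive, dtype=bool)
    if pred.shape != ref.shape:
        raise ValueError("values and reference labels differ in length")
    return ConfusionMatrix(
        tp=int(np.sum(pred & ref)),
        fp=int(np.sum(pred & ~ref)),
        tn=int(np.sum(~pred & ~ref)),
        fn=int(np.sum(~pred & ref)),
    )


def fit_polynomial(x, y, degree: int) -> dict:
    """Ordinary least-squares polynomial fit of y on x.

    Returns coefficients highest-degree first plus R^2 and residual SD
    (ddof = number of coefficients).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if degree not in (1, 2, 3):
        raise ValueError("degree must be 1, 2 or 3")
    if x.size <= degree + 1:
        raise ValueError("need more points than coefficients")
    V = np.vander(x, degree + 1)
    coeffs, residuals, rank, _ = np.linalg.lstsq(V, y, rcond=None)
    if rank < degree + 1:
        raise np.linalg.LinAlgError("rank-deficient design matrix")
    fitted = V @ coeffs
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    dof = x.size - (degree + 1)
    return {
        "coefficients": coeffs,
        "r_squared": 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0,
        "residual_sd": float(np.sqrt(ss_res / dof)) if dof > 0 else 0.0,
        "degree": degree,
    }


def threshold_from_fit(coefficients, ffr_cut: float = 0.8) -> float:
    """Evaluate a fitted index-index polynomial at the reference cut-off."""
    return float(np.polyval(np.asarray(coefficients, dtype=float), ffr_cut))


def bland_altman(a, b) -> dict[str, float]:
    """Agreement between paired measurements: mean and SD of a - b.

    Sample SD (n-1); limits of agreement are mean +/- 1.96 SD.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired arrays must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return {
        "mean_difference": mean,
        "sd_difference": sd,
        "limits_of_agreement": (mean - 1.96 * sd, mean + 1.96 * sd),
        "mean_values": (a + b) / 2.0,
        "differences": d,
    }


def pearson(a, b) -> float:
    """Product-moment correlation coefficient."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need equal-length arrays with n >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance")
    return float(np.corrcoef(a, b)[0, 1])


def roc(values, reference_positive) -> dict:
    """ROC analysis of an index where LOW values indicate disease.

    Sweeps thresholds over the unique observed values plus below-min and
    above-max sentinels; sensitivity = fraction of positives below the
    threshold, 1-specificity = fraction of negatives below it.  AUC by
    trapezoid over the step curve; the optimal threshold maximizes
    Youden's J (ties toward the higher threshold).
    """
    v = np.asarray(values, dtype=float)
    ref = np.asarray(reference_positive, dtype=bool)
    if v.shape != ref.shape:
        raise ValueError("values and labels differ in length")
    n_pos = int(ref.sum())
    n_neg = int((~ref).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    uniq = np.unique(v)
    eps = max(1e-9, 1e-9 * float(np.max(np.abs(uniq))))
    thresholds = np.concatenate(([uniq[0] - eps], uniq, [uniq[-1] + eps]))
    tpr = np.array([(v[ref] < th).mean() for th in thresholds])
    fpr = np.array([(v[~ref] < th).mean() for th in thresholds])
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    best = np.flatnonzero(j == j.max())[-1]  # ties -> higher threshold
    return {
        "thresholds": thresholds,
        "tpr": tpr,
        "fpr": fpr,
        "auc": auc,
        "youden_j": float(j[best]),
        "optimal_threshold": float(thresholds[best]),
    }
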