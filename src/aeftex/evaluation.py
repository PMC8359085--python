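"""Model evaluation: ROC with Youden-optimal cutoff, calibration, and
decision-curve analysis.

The ROC AUC is the trapezoidal area over all distinct score thresholds,
identical to the normalized Mann-Whitney rank statistic U/(n0*n1) with
mid-rank ties. The operating point maximizes Youden's J = sensitivity +
specificity - 1 (ties resolved toward the lower cutoff), and accuracy /
sensitivity / specificity are reported at that cutoff with "predicted
positive" meaning score >= cutoff.

Decision-curve analysis reports, for each threshold probability pt, the net
benefit NB = TP/n - (FP/n) * pt/(1-pt) of treating subjects whose predicted
probability is >= pt, against the treat-all and treat-none policies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from sklearn.metrics import roc_curve

__all__ = [
    "ROCResult",
    "CalibrationResult",
    "NetBenefitCurve",
    "roc_analysis",
    "calibration_curve",
    "decision_curve",
]


@dataclass(frozen=True)
class ROCResult:
    auc: float
    cutoff: float
    accuracy: float
    sensitivity: float
    specificity: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    cutoff_rule: str = "youden"


@dataclass(frozen=True)
class CalibrationResult:
    """Equal-frequency reliability points plus a logistic recalibration."""

    bin_pred_mean: np.ndarray
    bin_obs_rate: np.ndarray
    bin_count: np.ndarray
    slope: float
    intercept: float


@dataclass(frozen=True)
class NetBenefitCurve:
    thresholds: np.ndarray
    model: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray


def _check_labels(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels, dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    return y


def roc_analysis(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """ROC curve, AUC, and classification metrics at the Youden cutoff."""
    y = _check_labels(labels)
    s = np.asarray(scores, dtype=float)
    fpr, tpr, thr = roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    # thresholds descend; among ties on J pick the lowest finite cutoff
    best = max(i for i in range(len(j)) if j[i] == j.max())
    cutoff = float(thr[best])
    if np.isinf(cutoff):
        cutoff = float(s.max())
    pred = s >= cutoff
    tp = int(np.sum(pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    return ROCResult(
        auc=auc,
        cutoff=cutoff,
        accuracy=(tp + tn) / y.size,
        sensitivity=tp / int(np.sum(y == 1)),
        specificity=tn / int(np.sum(y == 0)),
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
    )


def calibration_curve(
    probabilities: np.ndarray, labels: np.ndarray, n_bins: int = 10
) -> CalibrationResult:
    """Reliability diagram with equal-frequency bins and recalibration fit.

    The slope and intercept come from a logistic regression of the outcome
    on the linear predictor logit(probability); slope 1 / intercept 0 means
    perfect calibration. Probabilities are clipped away from 0/1 before the
    logit. Degenerate (constant-probability) inputs collapse to a single
    bin with slope 1 by convention.
    """
    y = _check_labels(labels)
    prob = np.asarray(probabilities, dtype=float)
    if (prob < 0).any() or (prob > 1).any():
        raise ValueError("probabilities must lie in [0, 1]")
    if n_bins > y.size // 2:
        raise ValueError("n_bins must be at most n/2")
    edges = np.unique(np.quantile(prob, np.linspace(0, 1, n_bins + 1)))
    if edges.size == 1:  # constant probability: one degenerate bin
        edges = np.array([edges[0], edges[0] + 1e-12])
    idx = np.clip(np.searchsorted(edges, prob, side="right") - 1, 0, len(edges) - 2)
    pred_mean, obs_rate, count = [], [], []
    for b in range(len(edges) - 1):
        sel = idx == b
        if not sel.any():
            continue
        pred_mean.append(float(prob[sel].mean()))
        obs_rate.append(float(y[sel].mean()))
        count.append(int(sel.sum()))
    eps = 1e-10
    lp = np.log(np.clip(prob, eps, 1 - eps) / np.clip(1 - prob, eps, 1 - eps))
    if np.ptp(lp) < 1e-12:
        slope, intercept = 1.0, 0.0
    else:
        X = sm.add_constant(lp)
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            intercept, slope = float(res.params[0]), float(res.params[1])
        except Exception:
            res = sm.Logit(y, X).fit(method="lbfgs", maxiter=500, disp=0)
            intercept, slope = float(res.params[0]), float(res.params[1])
    return CalibrationResult(
        bin_pred_mean=np.array(pred_mean),
        bin_obs_rate=np.array(obs_rate),
        bin_count=np.array(count),
        slope=slope,
        intercept=intercept,
    )


def decision_curve(
    probabilities: np.ndarray,
    labels: np.ndarray,
    thresholds: np.ndarray | None = None,
) -> NetBenefitCurve:
    """Net benefit of the model vs treat-all and treat-none policies."""
    y = _check_labels(labels)
    prob = np.asarray(probabilities, dtype=float)
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    pt = np.asarray(thresholds, dtype=float)
    if (pt <= 0).any() or (pt >= 1).any():
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = y.size
    prevalence = y.mean()
    odds = pt / (1.0 - pt)
    model_nb = np.empty_like(pt)
    for k, t in enumerate(pt):
        pred = prob >= t
        tp = np.sum(pred & (y == 1)) / n
        fp = np.sum(pred & (y == 0)) / n
        model_nb[k] = tp - fp * odds[k]
    treat_all = prevalence - (1.0 - prevalence) * odds
    return NetBenefitCurve(
        thresholds=pt,
        model=model_nb,
        treat_all=treat_all,
        treat_none=np.zeros_like(pt),
    )
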