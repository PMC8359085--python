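"""Feature standardization, redundancy filtering, LASSO selection and
logistic modeling.

The modeling chain mirrors common radiomics-signature practice: z-score
standardization of every feature (texture features span many orders of
magnitude), removal of redundant features by Spearman rank correlation
(|rho| >= 0.9, keeping of each redundant pair the feature with the stronger
univariate outcome association), L1-penalized logistic regression with the
penalty tuned by stratified 5-fold cross-validated deviance, and a final
unpenalized multivariate logistic fit on the surviving features.

Two fixed-coefficient logistic models ship as versioned JSON resources:
model "A" predicts an Improved (CR+PR) outcome from 9 standardized texture
features, model "B" predicts an Un-worsened (CR+PR+SD) outcome from 4.
They are applied to new subjects with :func:`published_model_score`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .cohort_stats import compare_groups_continuous

__all__ = [
    "ModelSpec",
    "FeatureTable",
    "standardize",
    "apply_standardization",
    "spearman_filter",
    "lasso_select",
    "fit_logistic",
    "load_published_model",
    "published_model_score",
]


@dataclass(frozen=True)
class ModelSpec:
    """A named logistic model: intercept plus one coefficient per feature."""

    name: str
    outcome: str
    intercept: float
    coefficients: dict[str, float]
    z: dict[str, float] | None = None
    p: dict[str, float] | None = None
    warning: str | None = None

    def to_json(self) -> str:
        payload = {
            "name": self.name,
            "outcome": self.outcome,
            "intercept": self.intercept,
            "coefficients": self.coefficients,
        }
        if self.z is not None:
            payload["z"] = self.z
        if self.p is not None:
            payload["p"] = self.p
        if self.warning is not None:
            payload["warning"] = self.warning
        return json.dumps(payload, indent=1)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        return cls(
            name=d["name"],
            outcome=d["outcome"],
            intercept=float(d["intercept"]),
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            z={k: float(v) for k, v in d.get("z", {}).items()} or None,
            p={k: float(v) for k, v in d.get("p", {}).items()} or None,
            warning=d.get("warning"),
        )


@dataclass
class FeatureTable:
    """Per-subject feature matrix with a binary outcome.

    ``standardization`` stores the per-column (mean, sd) applied to
    ``data`` so that new subjects can be scored on the same scale.
    """

    data: pd.DataFrame
    outcome: pd.Series
    standardization: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValueError("feature table contains missing values")
        if not set(np.unique(self.outcome)) <= {0, 1}:
            raise ValueError("outcome must be binary 0/1")


def standardize(df: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Z-score each column with the sample (n-1) standard deviation.

    Returns the standardized frame and a {column: (mean, sd)} record for
    scoring new data. A zero-variance column is an error naming the column.
    """
    record: dict[str, tuple[float, float]] = {}
    out = {}
    for col in df.columns:
        x = df[col].astype(float)
        mean, sd = float(x.mean()), float(x.std(ddof=1))
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"column {col!r} has zero variance; cannot standardize")
        record[col] = (mean, sd)
        out[col] = (x - mean) / sd
    return pd.DataFrame(out, index=df.index), record


def apply_standardization(
    df: pd.DataFrame, record: Mapping[str, tuple[float, float]]
) -> pd.DataFrame:
    out = {}
    for col, (mean, sd) in record.items():
        if col not in df.columns:
            raise ValueError(f"feature {col!r} missing from input")
        out[col] = (df[col].astype(float) - mean) / sd
    return pd.DataFrame(out, index=df.index)


def _univariate_p(x: np.ndarray, y: np.ndarray) -> float:
    return compare_groups_continuous(x[y == 0], x[y == 1], force_test="mannwhitney").p


def spearman_filter(
    df: pd.DataFrame, y: np.ndarray, threshold: float = 0.9
) -> list[str]:
    """Drop redundant features by Spearman correlation.

    Greedy elimination: repeatedly take the remaining pair with the largest
    |rho| >= threshold and drop its member with the weaker univariate
    outcome association (larger Mann-Whitney p); exact ties keep the
    alphabetically-first name. The retained set has no pair at or above the
    threshold, and the result does not depend on column order when
    association strengths are distinct.
    """
    cols = sorted(df.columns)
    if len(cols) < 2:
        return list(cols)
    y = np.asarray(y)
    rho = pd.DataFrame(
        stats.spearmanr(df[cols].to_numpy()).statistic
        if len(cols) > 2
        else np.array(
            [[1.0, stats.spearmanr(df[cols[0]], df[cols[1]]).statistic], [0.0, 1.0]]
        ),
        index=cols,
        columns=cols,
    )
    assoc = {c: _univariate_p(df[c].to_numpy(), y) for c in cols}
    keep = set(cols)
    while True:
        best_pair, best_rho = None, threshold
        for i, a in enumerate(cols):
            if a not in keep:
                continue
            for b in cols[i + 1 :]:
                if b not in keep:
                    continue
                r = abs(float(rho.loc[a, b]))
                if r >= best_rho:
                    best_pair, best_rho = (a, b), r
        if best_pair is None:
            break
        a, b = best_pair
        if assoc[a] < assoc[b]:
            keep.discard(b)
        elif assoc[b] < assoc[a]:
            keep.discard(a)
        else:
            keep.discard(max(a, b))  # tie: alphabetically-first survives
    return [c for c in cols if c in keep]


def _l1_logistic(C: float) -> LogisticRegression:
    # sklearn >= 1.8 spells the L1 penalty as l1_ratio=1; older releases
    # need penalty="l1"
    import sklearn

    major, minor = (int(v) for v in sklearn.__version__.split(".")[:2])
    if (major, minor) >= (1, 8):
        return LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear", max_iter=2000)
    return LogisticRegression(penalty="l1", C=C, solver="liblinear", max_iter=2000)


def lasso_select(
    df: pd.DataFrame,
    y: np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
    n_lambdas: int = 40,
) -> tuple[list[str], dict]:
    """L1-penalized logistic feature selection with cross-validated penalty.

    The penalty grid descends log-linearly from the smallest lambda that
    zeroes every coefficient; the chosen lambda minimizes the mean held-out
    binomial deviance over stratified ``n_folds`` folds (ties prefer the
    sparser, larger lambda). Returns the names with nonzero coefficients at
    the chosen lambda (refit on the full data) plus path metadata.
    """
    y = np.asarray(y, dtype=int)
    X = df.to_numpy(dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least two candidate features")
    lam_max = float(np.max(np.abs(X.T @ (y - y.mean()))) / n)
    if lam_max <= 0:
        lam_max = 1e-3
    lambdas = np.logspace(np.log10(lam_max), np.log10(lam_max * 1e-3), n_lambdas)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    eps = 1e-12
    mean_dev = np.zeros(n_lambdas)
    for k, lam in enumerate(lambdas):
        devs = []
        for tr, te in folds:
            clf = _l1_logistic(C=1.0 / (len(tr) * lam)).fit(X[tr], y[tr])
            prob = np.clip(clf.predict_proba(X[te])[:, 1], eps, 1 - eps)
            devs.append(-2.0 * np.mean(y[te] * np.log(prob) + (1 - y[te]) * np.log(1 - prob)))
        mean_dev[k] = np.mean(devs)
    best = int(np.argmin(mean_dev))  # argmin takes the first (largest-lambda) tie
    lam = float(lambdas[best])
    final = _l1_logistic(C=1.0 / (n * lam)).fit(X, y)
    coefs = final.coef_.ravel()
    selected = [c for c, w in zip(df.columns, coefs) if w != 0.0]
    if not selected:
        warnings.warn("LASSO drove every coefficient to zero", stacklevel=2)
    meta = {
        "lambdas": lambdas.tolist(),
        "mean_cv_deviance": mean_dev.tolist(),
        "chosen_lambda": lam,
        "n_folds": n_folds,
        "seed": seed,
        "coefficients": dict(zip(df.columns, coefs.tolist())),
    }
    return selected, meta


def fit_logistic(
    df: pd.DataFrame,
    y: np.ndarray,
    features: list[str],
    name: str = "fitted",
    outcome: str = "outcome",
) -> ModelSpec:
    """Unpenalized maximum-likelihood logistic fit with Wald z and p.

    Perfect separation cannot be fit by ML (coefficients diverge); the fit
    is then capped at the iteration limit and the returned spec carries a
    warning. A singular design raises.
    """
    if not features:
        raise ValueError("feature subset is empty")
    y = np.asarray(y, dtype=float)
    if len(y) <= len(features):
        raise ValueError("need more subjects than model terms")
    X = sm.add_constant(df[features].astype(float), has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("singular design matrix")
    warn_msg = None
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
        except Exception:  # perfect separation raises in the Newton path
            res = sm.Logit(y, X).fit(method="lbfgs", maxiter=200, disp=0)
            warn_msg = "possible perfect separation: coefficients at iteration cap"
    for w in caught:
        if "separation" in str(w.message).lower() or "converge" in str(w.message).lower():
            warn_msg = warn_msg or str(w.message)
    params = res.params
    zvals = res.params / res.bse
    pvals = res.pvalues
    if warn_msg:
        warnings.warn(warn_msg, stacklevel=2)
    return ModelSpec(
        name=name,
        outcome=outcome,
        intercept=float(params["const"]),
        coefficients={f: float(params[f]) for f in features},
        z={"Intercept": float(zvals["const"]), **{f: float(zvals[f]) for f in features}},
        p={"Intercept": float(pvals["const"]), **{f: float(pvals[f]) for f in features}},
        warning=warn_msg,
    )


def load_published_model(name: str) -> ModelSpec:
    """Load fixed-coefficient model "A" (Improved) or "B" (Un-worsened)."""
    key = name.strip().upper()
    if key not in ("A", "B"):
        raise ValueError(f"published models are 'A' and 'B', got {name!r}")
    path = importlib_resources.files("aeftex.resources") / f"model_{key.lower()}.json"
    return ModelSpec.from_dict(json.loads(path.read_text()))


def published_model_score(
    features: Mapping[str, float] | pd.DataFrame, model: ModelSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Score standardized features with a fixed-coefficient model.

    Returns (linear predictor, probability); inputs must already be on the
    model's standardized scale. Accepts a single mapping or a DataFrame of
    subjects (rows); output arrays are scalar-shaped for a mapping.
    """
    if isinstance(features, pd.DataFrame):
        frame = features
    else:
        frame = pd.DataFrame([dict(features)])
    missing = [f for f in model.coefficients if f not in frame.columns]
    if missing:
        raise ValueError(f"missing features for model {model.name}: {missing}")
    lp = np.full(len(frame), model.intercept, dtype=float)
    for feat, coef in model.coefficients.items():
        lp += coef * frame[feat].to_numpy(dtype=float)
    prob = 1.0 / (1.0 + np.exp(-lp))
    if not isinstance(features, pd.DataFrame):
        return lp[0], prob[0]
    return lp, prob
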