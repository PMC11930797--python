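"""Guideline prognostic model, graph-measure augmentation, and comparison.

The guideline model is a logistic regression of poor outcome on the
established predictors: a combined bilateral-fixed-pupils-and/or-absent-
SSEPs indicator, and the guideline EEG class (good: continuous pattern
established early; poor: suppressed pattern persisting; indifferent:
reference level, entered as two indicator contrasts).  Augmented models
append one whole-brain graph measure, preserving the nested structure for
a likelihood-ratio test.  Each model is evaluated in-sample by ROC AUC and
by the clinically constrained operating points: sensitivity for good
outcome at specificity >= 90 % and sensitivity for poor outcome at
specificity = 100 %.

Poor outcome is the modelled event (score = predicted probability of poor
outcome); the good-outcome analysis re-poles the score so that good is the
positive class.  Perfect separation — common in small cohorts with a
100 %-specificity target — triggers a documented ridge-penalized fallback.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve, auc as sk_auc

__all__ = [
    "FittedLogistic",
    "PredictionResult",
    "build_guideline_design",
    "fit_guideline_model",
    "augment_model",
    "roc_analysis",
    "sensitivity_at_specificity",
    "likelihood_ratio_test",
    "penalized_objective",
    "compare_prediction_models",
]

#: L2 penalty weight used by the separation fallback (sklearn C = 1/penalty).
RIDGE_PENALTY = 1.0


@dataclass
class FittedLogistic:
    label: str
    params: pd.Series
    loglik: float  # unpenalized log-likelihood at the fitted coefficients
    probabilities: np.ndarray  # per-subject P(poor outcome)
    n_params: int
    penalized: bool = False


@dataclass
class PredictionResult:
    model_label: str
    auc: float
    sens_good: float  # good-outcome sensitivity at specificity >= 0.90
    sens_poor: float  # poor-outcome sensitivity at specificity = 1.00
    loglik: float
    lrt_p: float | None = None


def _bernoulli_loglik(y: np.ndarray, p: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def build_guideline_design(metadata: pd.DataFrame) -> pd.DataFrame:
    """Guideline predictors as coded indicators (EEG class vs indifferent)."""
    X = pd.DataFrame(index=metadata.index)
    X["pupils_ssep_absent"] = metadata["pupils_ssep_absent"].astype(float)
    X["eeg_class_good"] = (metadata["eeg_class"] == "good").astype(float)
    X["eeg_class_poor"] = (metadata["eeg_class"] == "poor").astype(float)
    return sm.add_constant(X, has_constant="add")


def _outcome_vector(metadata: pd.DataFrame) -> np.ndarray:
    y = (metadata["outcome"] == "poor").astype(float).to_numpy()
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    return y


def _fit_logistic(
    y: np.ndarray, X: pd.DataFrame, label: str, ridge: bool = False
) -> FittedLogistic:
    # constant predictors carry no information and make the design singular
    drop = [c for c in X.columns if c != "const" and X[c].nunique() == 1]
    if drop:
        X = X.drop(columns=drop)
    if ridge:
        return _ridge_fit(y, X, label)
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    # Quasi-separation (an empty predictor-outcome cell) still has a finite
    # likelihood supremum that Newton reaches, so it is accepted for
    # likelihood-based comparison; only genuine fitting failure (complete
    # separation, singular Hessian, non-convergence) triggers the fallback.
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            warnings.simplefilter("error", ConvergenceWarning)
            fit = sm.Logit(y, X.astype(float)).fit(disp=0, maxiter=200)
        if not fit.mle_retvals.get("converged", True):
            raise RuntimeError("Newton iterations did not converge")
        return FittedLogistic(
            label=label,
            params=fit.params,
            loglik=float(fit.llf),
            probabilities=np.asarray(fit.predict(X.astype(float))),
            n_params=X.shape[1],
        )
    except Exception:
        warnings.warn(
            f"{label}: separation or non-convergence; "
            f"falling back to ridge-penalized fit (penalty {RIDGE_PENALTY})",
            stacklevel=2,
        )
    return _ridge_fit(y, X, label)


def _ridge_fit(y: np.ndarray, X: pd.DataFrame, label: str) -> FittedLogistic:
    Xm = X.drop(columns="const").to_numpy(dtype=float)
    clf = LogisticRegression(C=1.0 / RIDGE_PENALTY, max_iter=5000)
    clf.fit(Xm, y)
    probs = clf.predict_proba(Xm)[:, 1]
    params = pd.Series(
        np.concatenate([clf.intercept_, clf.coef_.ravel()]), index=X.columns
    )
    return FittedLogistic(
        label=label,
        params=params,
        loglik=_bernoulli_loglik(y, probs),
        probabilities=probs,
        n_params=X.shape[1],
        penalized=True,
    )


def penalized_objective(fit: FittedLogistic) -> float:
    """Ridge objective (loglik minus L2 penalty on non-intercept terms).

    For two ridge fits with the same penalty, a nested model can never score
    above its superset, so this is the right monotone comparison when the
    maximum-likelihood route is unavailable.
    """
    coefs = fit.params.drop(labels=["const"], errors="ignore").to_numpy()
    pen = 0.5 * RIDGE_PENALTY * float(coefs @ coefs) if fit.penalized else 0.0
    return fit.loglik - pen


def fit_guideline_model(
    metadata: pd.DataFrame, label: str = "guideline", ridge: bool = False
) -> FittedLogistic:
    """Maximum-likelihood logistic fit of poor outcome on guideline predictors.

    ``ridge=True`` forces the penalized route (useful to put both members of
    a nested pair on the same footing when one of them separates).
    """
    return _fit_logistic(
        _outcome_vector(metadata), build_guideline_design(metadata), label, ridge=ridge
    )


def augment_model(
    metadata: pd.DataFrame, graph_metric, metric_name: str = "metric",
    ridge: bool = False,
) -> FittedLogistic:
    """Guideline model with one graph measure appended (nested superset)."""
    X = build_guideline_design(metadata)
    X[metric_name] = np.asarray(graph_metric, dtype=float)
    return _fit_logistic(
        _outcome_vector(metadata), X, f"guideline+{metric_name}", ridge=ridge
    )


def roc_analysis(probabilities, outcomes) -> dict:
    """Full ROC (all thresholds, tied scores grouped) and trapezoidal AUC.

    ``outcomes`` may be 0/1 (1 = positive) or 'good'/'poor' strings, in
    which case poor is the positive class.
    """
    scores = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes)
    if y.dtype.kind in "OUS":
        y = (y == "poor").astype(int)
    y = y.astype(int)
    if len(set(y)) < 2:
        raise ValueError("both outcome classes must be present")
    fpr, tpr, thresholds = roc_curve(y, scores, drop_intermediate=False)
    return {"fpr": fpr, "tpr": tpr, "thresholds": thresholds, "auc": float(sk_auc(fpr, tpr))}


def sensitivity_at_specificity(
    scores, y_positive, min_specificity: float
) -> float:
    """Maximum sensitivity over operating points with specificity >= bound.

    ``y_positive`` marks the class of interest as 1 and ``scores`` must be
    oriented so higher means more likely positive (re-pole the model score
    for the good-outcome analysis).  Tied scores are thresholded as a
    group.  The degenerate predict-nobody point (specificity 1, sensitivity
    0) always qualifies, so an uninformative model scores 0.
    """
    if not (0.0 < min_specificity <= 1.0):
        raise ValueError("min_specificity must be in (0, 1]")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(y_positive, dtype=int)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    best = 0.0  # predict-nobody operating point
    for t in np.unique(s):
        pred = s >= t
        spec = float(np.sum(~pred & (y == 0))) / n_neg
        if spec >= min_specificity - 1e-12:
            sens = float(np.sum(pred & (y == 1))) / n_pos
            best = max(best, sens)
    return best


def likelihood_ratio_test(nested: FittedLogistic, full: FittedLogistic) -> tuple[float, float]:
    """LRT of the nested against the augmented model.

    Statistic 2*(ll_full - ll_nested) against chi-square with df equal to
    the parameter-count difference.
    """
    df = full.n_params - nested.n_params
    if df <= 0:
        raise ValueError("full model must add parameters over the nested model")
    stat = 2.0 * (full.loglik - nested.loglik)
    if stat < -1e-6:
        raise ValueError(
            f"full-model log-likelihood below nested ({full.loglik:.6g} < "
            f"{nested.loglik:.6g}): fitting failure"
        )
    stat = max(stat, 0.0)
    return float(stat), float(chi2.sf(stat, df))


def _evaluate(fit: FittedLogistic, y_poor: np.ndarray, lrt_p: float | None = None) -> PredictionResult:
    roc = roc_analysis(fit.probabilities, y_poor)
    sens_poor = sensitivity_at_specificity(fit.probabilities, y_poor, 1.00)
    sens_good = sensitivity_at_specificity(1.0 - fit.probabilities, 1 - y_poor, 0.90)
    return PredictionResult(
        model_label=fit.label,
        auc=roc["auc"],
        sens_good=sens_good,
        sens_poor=sens_poor,
        loglik=fit.loglik,
        lrt_p=lrt_p,
    )


def compare_prediction_models(
    metadata: pd.DataFrame,
    metrics: pd.DataFrame,
    metric_cols=("whole_brain_fc", "clustering_auc", "global_efficiency_auc", "modularity_auc"),
) -> pd.DataFrame:
    """Guideline model versus guideline + each graph measure.

    Returns one row per model with AUC, the two constrained sensitivities,
    log-likelihood, and (for augmented models) the LRT p against the
    guideline model.  The LRT is reported only when both fits are
    unpenalized maximum-likelihood fits.
    """
    df = metrics.merge(metadata, on="subject_id")
    y_poor = _outcome_vector(df).astype(int)
    base = fit_guideline_model(df)
    rows = [_evaluate(base, y_poor)]
    for col in metric_cols:
        full = augment_model(df, df[col], col)
        lrt_p = None
        if not (base.penalized or full.penalized):
            _, lrt_p = likelihood_ratio_test(base, full)
        rows.append(_evaluate(full, y_poor, lrt_p))
    return pd.DataFrame([r.__dict__ for r in rows])
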