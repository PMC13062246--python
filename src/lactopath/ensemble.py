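"""Feature selection, the four-classifier ensemble and the integrated score.

LASSO (L1-penalized, cross-validated) prunes the reduced slide features;
four probabilistic classifiers — XGBoost, gradient boosting, LightGBM and an
SVM with probability calibration — are trained on the selected features.
Their class-1 probabilities are summed, unweighted, into the integrated
lactate score in [0, 4], and evaluation covers AUROC, decision-curve net
benefit, Youden-optimal and fixed-0.5 threshold metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LassoCV, LogisticRegression, LogisticRegressionCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

__all__ = [
    "lasso_select",
    "default_model_registry",
    "train_ensemble",
    "predict_ensemble",
    "auroc",
    "decision_curve",
    "threshold_metrics",
    "integrated_score",
    "stratify_extremes",
    "split_units",
    "EvalReport",
]


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------

def lasso_select(
    features: np.ndarray,
    labels: np.ndarray,
    cv_folds: int = 5,
    seed: int = 0,
    mode: str = "logistic",
    alpha: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """L1-penalized feature selection with cross-validated regularization.

    ``mode="logistic"`` (default) fits an L1 logistic regression over a
    regularization path, choosing the strength by stratified CV;
    ``mode="linear"`` uses the lasso on the 0/1 labels (``alpha`` may pin
    the penalty, ``alpha=0`` reduces to ordinary least squares). If the
    selected penalty zeroes every coefficient, the weakest penalty with at
    least one nonzero coefficient is used instead (with a warning).

    Returns ``(selected_indices, coefficients_at_selected_indices)``.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if x.shape[0] <= cv_folds or cv_folds < 3:
        raise ValueError("need more samples than folds and cv_folds >= 3")
    scaler = StandardScaler().fit(x)
    xs = scaler.transform(x)

    if mode == "logistic":
        cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        model = LogisticRegressionCV(
            Cs=np.logspace(-3, 3, 25),
            cv=cv,
            penalty="l1",
            solver="liblinear",
            scoring="neg_log_loss",
            random_state=seed,
            max_iter=5000,
        ).fit(xs, y)
        coef = model.coef_.ravel()
        if not np.any(coef != 0):
            warnings.warn(
                "all coefficients zero at the CV-selected penalty; falling "
                "back to the weakest penalty with a nonzero coefficient",
                stacklevel=2,
            )
            for c_val in sorted(np.logspace(-3, 3, 25), reverse=True):
                fallback = LogisticRegression(
                    C=c_val, penalty="l1", solver="liblinear",
                    random_state=seed, max_iter=5000,
                ).fit(xs, y)
                coef = fallback.coef_.ravel()
                if np.any(coef != 0):
                    break
    elif mode == "linear":
        if alpha is not None:
            if alpha == 0:
                coef, *_ = np.linalg.lstsq(
                    np.column_stack([np.ones(len(xs)), xs]), y.astype(float),
                    rcond=None,
                )
                coef = coef[1:]
            else:
                from sklearn.linear_model import Lasso

                coef = Lasso(alpha=alpha, max_iter=50000).fit(xs, y).coef_
        else:
            model = LassoCV(cv=cv_folds, random_state=seed, max_iter=50000).fit(
                xs, y.astype(float)
            )
            coef = model.coef_
            if not np.any(coef != 0):
                warnings.warn(
                    "all coefficients zero at the CV-selected alpha; using "
                    "the smallest alpha on the path with a nonzero coefficient",
                    stacklevel=2,
                )
                for a in sorted(model.alphas_):
                    from sklearn.linear_model import Lasso

                    coef = Lasso(alpha=a, max_iter=50000).fit(xs, y).coef_
                    if np.any(coef != 0):
                        break
    else:
        raise ValueError(f"unknown lasso mode: {mode!r}")

    selected = np.flatnonzero(coef)
    return selected, coef[selected]


# ---------------------------------------------------------------------------
# the four-model ensemble
# ---------------------------------------------------------------------------

MODEL_ORDER = ("xgboost", "gradient_boosting", "lightgbm", "svm")


def default_model_registry(seed: int = 0) -> dict[str, object]:
    """Fresh instances of the four classifier families, all seeded.

    Any mapping of name -> estimator with ``fit`` and ``predict_proba`` can
    replace this registry; the SVM slot uses built-in Platt probability
    calibration.
    """
    return {
        "xgboost": XGBClassifier(
            n_estimators=200,
            max_depth=3,
            learning_rate=0.1,
            random_state=seed,
            verbosity=0,
            eval_metric="logloss",
            n_jobs=1,
        ),
        "gradient_boosting": GradientBoostingClassifier(
            n_estimators=200, max_depth=3, random_state=seed
        ),
        "lightgbm": LGBMClassifier(
            n_estimators=200,
            max_depth=3,
            min_child_samples=5,  # cohorts here are tens of slides, not thousands
            random_state=seed,
            verbose=-1,
            deterministic=True,
            force_row_wise=True,
            n_jobs=1,
        ),
        "svm": SVC(probability=True, kernel="rbf", random_state=seed),
    }


def train_ensemble(
    features: np.ndarray,
    labels: np.ndarray,
    registry: dict[str, object] | None = None,
    seed: int = 0,
) -> dict[str, object]:
    """Fit every classifier in the registry on the selected features."""
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    registry = registry if registry is not None else default_model_registry(seed)
    fitted = {}
    for name, model in registry.items():
        fitted[name] = model.fit(x, y)
    return fitted


def predict_ensemble(
    models: dict[str, object], features: np.ndarray
) -> pd.DataFrame:
    """Class-1 probability per model; columns in registry order."""
    x = np.asarray(features, dtype=float)
    probs = {name: m.predict_proba(x)[:, 1] for name, m in models.items()}
    return pd.DataFrame(probs)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def auroc(probs: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (Mann–Whitney statistic, 0.5 credit for ties)."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("AUROC needs both classes present")
    return float(roc_auc_score(y, np.asarray(probs, dtype=float)))


def decision_curve(
    probs: np.ndarray,
    labels: np.ndarray,
    thresholds: np.ndarray | None = None,
) -> pd.DataFrame:
    """Decision-curve analysis: net benefit across decision thresholds.

    Net benefit at threshold probability ``pt`` is
    ``TP/n - (FP/n) * pt / (1 - pt)`` for the model (predict positive when
    prob >= pt), alongside the treat-all and treat-none reference policies.
    """
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(labels).astype(int)
    if thresholds is None:
        thresholds = np.arange(0.01, 1.00, 0.01)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(thresholds <= 0) or np.any(thresholds >= 1):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = len(y)
    prevalence = y.mean()
    rows = []
    for pt in thresholds:
        pred = probs >= pt
        tp = np.count_nonzero(pred & (y == 1))
        fp = np.count_nonzero(pred & (y == 0))
        odds = pt / (1 - pt)
        rows.append(
            {
                "threshold": pt,
                "net_benefit": tp / n - (fp / n) * odds,
                "treat_all": prevalence - (1 - prevalence) * odds,
                "treat_none": 0.0,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class EvalReport:
    """Threshold-dependent classification metrics at one cutoff."""

    threshold: float
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    confusion: dict[str, int] = field(default_factory=dict)  # tn/fp/fn/tp


def _metrics_at(probs: np.ndarray, y: np.ndarray, thr: float) -> EvalReport:
    pred = probs >= thr
    tp = int(np.count_nonzero(pred & (y == 1)))
    tn = int(np.count_nonzero(~pred & (y == 0)))
    fp = int(np.count_nonzero(pred & (y == 0)))
    fn = int(np.count_nonzero(~pred & (y == 1)))
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    return EvalReport(
        threshold=float(thr),
        accuracy=(tp + tn) / len(y),
        sensitivity=sens,
        specificity=spec,
        ppv=tp / (tp + fp) if tp + fp else np.nan,
        npv=tn / (tn + fn) if tn + fn else np.nan,
        confusion={"tn": tn, "fp": fp, "fn": fn, "tp": tp},
    )


def threshold_metrics(
    probs: np.ndarray, labels: np.ndarray, mode: str = "youden"
) -> EvalReport:
    """Classification metrics at the Youden-optimal or fixed-0.5 cutoff.

    ``mode="youden"`` scans the observed probabilities (plus a sentinel
    above the maximum, i.e. the all-negative rule) and keeps the cutoff
    maximizing sensitivity + specificity - 1, ties resolved toward the
    lower cutoff. ``mode="fixed_0.5"`` predicts positive at prob >= 0.5.
    """
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("threshold metrics need both classes present")
    if mode == "fixed_0.5":
        return _metrics_at(probs, y, 0.5)
    if mode != "youden":
        raise ValueError(f"unknown mode: {mode!r}")
    candidates = np.append(np.unique(probs), probs.max() + 1.0)
    best: EvalReport | None = None
    best_j = -np.inf
    for thr in candidates:  # ascending; strict > keeps the lower tie
        rep = _metrics_at(probs, y, thr)
        j = rep.sensitivity + rep.specificity - 1.0
        if j > best_j + 1e-12:
            best_j = j
            best = rep
    return best


def integrated_score(probs_per_model: np.ndarray | pd.DataFrame) -> np.ndarray | float:
    """Unweighted sum of the four models' class-1 probabilities, in [0, 4].

    Accepts a length-4 vector (one unit) or an ``(n, 4)`` array / DataFrame.
    """
    p = np.asarray(probs_per_model, dtype=float)
    one = p.ndim == 1
    p = np.atleast_2d(p)
    if p.shape[1] != 4:
        raise ValueError(f"expected probabilities from 4 models, got {p.shape[1]}")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    s = p.sum(axis=1)
    return float(s[0]) if one else s


def stratify_extremes(
    scores: pd.Series, fraction: float = 0.10
) -> pd.Series:
    """Label the top/bottom ``fraction`` of units 'high' / 'low', rest 'mid'.

    ``k = round(fraction * n)`` per extreme (half rounds up); ties broken by
    stable unit-id order.
    """
    n = len(scores)
    if not 0 < fraction < 0.5:
        raise ValueError("fraction must lie in (0, 0.5)")
    k = int(np.floor(fraction * n + 0.5))
    if k == 0:
        raise ValueError(f"fraction {fraction} selects no units from n={n}")
    frame = pd.DataFrame(
        {"score": scores.to_numpy(dtype=float), "_sid": scores.index.astype(str)},
        index=scores.index,
    )
    order = frame.sort_values(["score", "_sid"], kind="stable").index
    out = pd.Series("mid", index=scores.index, name="group")
    out.loc[order[:k]] = "low"
    out.loc[order[-k:]] = "high"
    return out


def split_units(
    unit_ids: np.ndarray | list,
    labels: np.ndarray,
    train_fraction: float = 0.75,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test split with train size = floor(fraction * n).

    With the default 3:1 ratio, 273 units yield 204 training units.
    Returns boolean masks ``(is_train, is_test)``.
    """
    ids = np.asarray(unit_ids)
    y = np.asarray(labels)
    n = len(ids)
    n_train = int(np.floor(train_fraction * n))
    idx_train, idx_test = train_test_split(
        np.arange(n), train_size=n_train, stratify=y, random_state=seed
    )
    is_train = np.zeros(n, dtype=bool)
    is_train[idx_train] = True
    return is_train, ~is_train
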