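"""Outcome classification: logistic regression, repeated stratified CV,
band-combination search, backward elimination and external validation.

Labels are binary with 'favorable' as the positive class.  With many
more attributes than subjects the default fit is ridge-penalized on
standardized features; standardization statistics are always estimated
inside the training portion only.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ClassifierModel", "CVReport", "ValidationReport",
    "fit_logistic", "crossval_accuracy", "band_combination_search",
    "backward_eliminate", "evaluate", "dichotomous_cutoff",
]

FAVORABLE, POOR = "F", "P"


def _encode_labels(y) -> np.ndarray:
    arr = np.asarray(y)
    if arr.dtype.kind in "ifb":
        return arr.astype(int)
    return (arr == FAVORABLE).astype(int)


@dataclass
class ClassifierModel:
    weights: np.ndarray
    intercept: float
    selected_features: list[str]
    feature_means: np.ndarray
    feature_sds: np.ndarray
    separation_flagged: bool = False

    def decision_values(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.selected_features].to_numpy(dtype=float)
        Z = (np.asarray(X, dtype=float) - self.feature_means) / self.feature_sds
        return Z @ self.weights + self.intercept

    def predict_proba(self, X) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.decision_values(X)))

    def predict(self, X) -> np.ndarray:
        return np.where(self.predict_proba(X) >= 0.5, FAVORABLE, POOR)


@dataclass
class CVReport:
    mean_accuracy: float        # percent
    sd_accuracy: float          # percent, over repetitions
    repetition_accuracies: np.ndarray
    fold_accuracies: np.ndarray  # repetitions x folds
    seed: int


@dataclass
class ValidationReport:
    """Confusion counts and derived metrics, favorable = positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @staticmethod
    def _ratio(num, den):
        return 100.0 * num / den if den > 0 else None

    @property
    def sensitivity(self):
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self):
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def positive_predictive_value(self):
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def accuracy(self):
        return self._ratio(self.tp + self.tn, self.n)

    def summary(self) -> dict:
        # half-up to one decimal (13/16 -> 81.3), as clinical tables print
        fmt = lambda v: None if v is None else np.floor(v * 10 + 0.5) / 10
        return {
            "TP": self.tp, "FP": self.fp, "FN": self.fn, "TN": self.tn,
            "sensitivity_%": fmt(self.sensitivity),
            "specificity_%": fmt(self.specificity),
            "ppv_%": fmt(self.positive_predictive_value),
            "accuracy_%": fmt(self.accuracy),
        }


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return (X - mu) / sd, mu, sd


def fit_logistic(
    X: pd.DataFrame | np.ndarray,
    y,
    regularization: float = 1.0,
    feature_names: list[str] | None = None,
) -> ClassifierModel:
    """Maximum-likelihood logistic fit with optional ridge penalty.

    ``regularization`` is the ridge strength on standardized features
    (0 = unpenalized).  Perfect separation of an unpenalized fit is
    flagged and refitted with a unit ridge.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    yb = _encode_labels(y)
    if len(np.unique(yb)) < 2 or min(np.bincount(yb)) < 2:
        raise ValueError("need at least 2 samples per class")
    if np.any(~np.isfinite(X)):
        raise ValueError("missing values in features")
    names = feature_names or [f"x{i}" for i in range(X.shape[1])]
    Z, mu, sd = _standardize(X)
    flagged = False
    if regularization <= 0:
        clf = LogisticRegression(C=np.inf, max_iter=10_000, tol=1e-10)
        clf.fit(Z, yb)
        margin = Z @ clf.coef_.ravel() + clf.intercept_[0]
        prob = 1.0 / (1.0 + np.exp(-margin))
        # MLE does not exist under perfect separation: every training point
        # on the right side with near-saturated probabilities
        saturated = np.all(np.where(yb == 1, prob > 0.99, prob < 0.01))
        if saturated and np.all((margin > 0) == (yb == 1)):
            flagged = True
            clf = LogisticRegression(C=1.0, max_iter=10_000, tol=1e-10)
            clf.fit(Z, yb)
    else:
        clf = LogisticRegression(C=1.0 / regularization,
                                 max_iter=10_000, tol=1e-10)
        clf.fit(Z, yb)
    return ClassifierModel(
        weights=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        selected_features=names,
        feature_means=mu,
        feature_sds=sd,
        separation_flagged=flagged,
    )


def crossval_accuracy(
    X: pd.DataFrame | np.ndarray,
    y,
    k: int = 5,
    repeats: int = 100,
    seed: int = 0,
    regularization: float = 1.0,
) -> CVReport:
    """Repeated stratified k-fold cross-validated accuracy (percent).

    Standardization is fitted on each training fold only, so test folds
    never leak into the training statistics.  The SD is taken over
    repetition means.
    """
    if k < 2:
        raise ValueError("need k >= 2 folds")
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    yb = _encode_labels(y)
    rep_acc = np.empty(repeats)
    fold_acc = np.empty((repeats, k))
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + r)
        for f, (tr, te) in enumerate(skf.split(X, yb)):
            model = fit_logistic(X[tr], yb[tr], regularization=regularization)
            pred = model.predict_proba(X[te]) >= 0.5
            fold_acc[r, f] = np.mean(pred.astype(int) == yb[te])
        rep_acc[r] = fold_acc[r].mean()
    return CVReport(
        mean_accuracy=100.0 * rep_acc.mean(),
        sd_accuracy=100.0 * rep_acc.std(ddof=1) if repeats > 1 else 0.0,
        repetition_accuracies=100.0 * rep_acc,
        fold_accuracies=100.0 * fold_acc,
        seed=seed,
    )


def band_combination_search(
    features: pd.DataFrame,
    y,
    bands=("theta", "alpha", "beta", "gamma"),
    k: int = 5,
    repeats: int = 100,
    seed: int = 0,
    regularization: float = 1.0,
) -> pd.DataFrame:
    """CV accuracy of every non-empty band subset of the features.

    Feature columns must follow the ``unit.band.sign`` naming scheme.
    Returns a table ranked by mean accuracy with one row per subset
    (15 rows for 4 bands).
    """
    band_of = {c: c.split(".")[1] for c in features.columns}
    rows = []
    for size in range(1, len(bands) + 1):
        for combo in itertools.combinations(bands, size):
            cols = [c for c in features.columns if band_of[c] in combo]
            if not cols:
                rows.append({"combination": "+".join(combo), "n_features": 0,
                             "mean_accuracy": np.nan, "sd_accuracy": np.nan})
                continue
            rep = crossval_accuracy(features[cols], y, k=k, repeats=repeats,
                                    seed=seed, regularization=regularization)
            rows.append({
                "combination": "+".join(combo),
                "n_features": len(cols),
                "mean_accuracy": rep.mean_accuracy,
                "sd_accuracy": rep.sd_accuracy,
            })
    table = pd.DataFrame(rows)
    return table.sort_values("mean_accuracy", ascending=False, kind="stable").reset_index(drop=True)


def backward_eliminate(
    X: pd.DataFrame,
    y,
    alpha: float = 0.05,
    ridge_fallback: float = 1e-4,
) -> tuple[ClassifierModel, list[dict]]:
    """Backward elimination on Wald p-values of an unpenalized logistic fit.

    Repeatedly removes the feature with the largest coefficient p-value
    while it exceeds ``alpha`` (ties broken by column order); stops when
    all remaining features are significant or one feature is left.
    Non-convergent or separable refits fall back to a tiny ridge and are
    flagged in the trace.  Returns the final model (fit on the retained
    features) and the removal trace.
    """
    if X.shape[1] == 0:
        raise ValueError("starting feature set is empty")
    yb = _encode_labels(y)
    cols = list(X.columns)
    trace: list[dict] = []
    while len(cols) > 1:
        Z, _, _ = _standardize(X[cols].to_numpy(dtype=float))
        design = sm.add_constant(Z, has_constant="add")
        flagged = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(yb, design).fit(disp=0, maxiter=200)
                pvals = np.asarray(res.pvalues)[1:]
                if not np.all(np.isfinite(pvals)):
                    raise ValueError("non-finite p-values")
            except Exception:
                # separation / singular fit: ridge-IRLS Wald statistics
                flagged = True
                clf = LogisticRegression(C=1.0 / ridge_fallback,
                                         max_iter=5000, tol=1e-10)
                clf.fit(Z, yb)
                beta = np.concatenate([clf.intercept_, clf.coef_.ravel()])
                eta = design @ beta
                p = 1.0 / (1.0 + np.exp(-eta))
                w = np.clip(p * (1 - p), 1e-10, None)
                H = design.T @ (design * w[:, None])
                H += ridge_fallback * np.eye(design.shape[1])
                cov = np.linalg.pinv(H)
                se = np.sqrt(np.clip(np.diag(cov), 1e-300, None))
                from scipy.stats import norm
                pvals = 2 * norm.sf(np.abs(beta / se))[1:]
        worst = int(np.argmax(pvals))
        if pvals[worst] <= alpha:
            break
        trace.append({"removed": cols[worst], "p_value": float(pvals[worst]),
                      "n_remaining": len(cols) - 1, "flagged": flagged})
        cols.pop(worst)
    model = fit_logistic(X[cols], yb, regularization=0.0)
    return model, trace


def evaluate(predicted, truth) -> ValidationReport:
    """Confusion-matrix metrics with favorable as the positive class."""
    pred = np.asarray(predicted)
    true = np.asarray(truth)
    if pred.size == 0:
        raise ValueError("empty input")
    if pred.shape != true.shape:
        raise ValueError("predicted and truth must have equal length")
    p = _encode_labels(pred)
    t = _encode_labels(true)
    return ValidationReport(
        tp=int(np.sum((p == 1) & (t == 1))),
        fp=int(np.sum((p == 1) & (t == 0))),
        fn=int(np.sum((p == 0) & (t == 1))),
        tn=int(np.sum((p == 0) & (t == 0))),
    )


def dichotomous_cutoff(variable, y) -> tuple[float, float, str]:
    """Best single-variable threshold classifier.

    Scans all midpoints between sorted unique values in both
    orientations ('>=' predicts favorable, or '<=' predicts favorable)
    and returns (cutoff, accuracy_percent, orientation); ties resolve to
    the smallest cutoff, '>= ' orientation first.
    """
    v = np.asarray(variable, dtype=float)
    yb = _encode_labels(y)
    uniq = np.unique(v)
    if uniq.size < 2:
        warnings.warn("constant variable; cutoff is meaningless")
        acc = 100.0 * max(np.mean(yb), 1 - np.mean(yb))
        return float(uniq[0]), acc, ">="
    cuts = (uniq[:-1] + uniq[1:]) / 2.0
    best = (-1.0, np.inf, ">=")
    for orientation in (">=", "<="):
        for c in cuts:
            pred = (v >= c) if orientation == ">=" else (v <= c)
            acc = 100.0 * np.mean(pred.astype(int) == yb)
            if acc > best[0] or (acc == best[0] and c < best[1]):
                best = (acc, c, orientation)
    return float(best[1]), float(best[0]), best[2]
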