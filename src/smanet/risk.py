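"""Logistic propensity classifier on band-averaged coherence features.

Each seizure contributes two features - the per-seizure mean wavelet phase
coherence over 1-12 Hz and over 13-30 Hz - and a binary label (SUDEP = 1).
A logistic model on the standardized features yields a propensity score in
[0, 1]; discrimination is summarised by the ROC curve / AUC and assessed by
leave-one-out cross-validation.  Group differences are reported as effect
sizes with bootstrap confidence intervals rather than p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

__all__ = [
    "SeizureFeatures",
    "ROCResult",
    "LogisticModel",
    "LOOCVResult",
    "MeanDifference",
    "fit_logistic",
    "roc_auc",
    "loo_cv",
    "mean_difference_bootstrap",
]

#: Ridge strength used as the perfect-separation fallback (C = 1 / ridge).
_RIDGE_FALLBACK = 1e-6
#: Effectively-unpenalised fit used first (maximum likelihood in practice).
_C_ML = 1e10


@dataclass
class SeizureFeatures:
    """Per-seizure coherence features with label and (optional) propensity."""

    seizure_id: str
    patient_id: str
    wpc_low: float   # mean WPC over 1-12 Hz
    wpc_high: float  # mean WPC over 13-30 Hz
    label: int | None = None  # 1 = SUDEP, 0 = non-SUDEP
    propensity: float | None = None

    def __post_init__(self):
        for name in ("wpc_low", "wpc_high"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0/1/None, got {self.label}")


def _design(features: list[SeizureFeatures]) -> tuple[np.ndarray, np.ndarray]:
    X = np.array([[f.wpc_low, f.wpc_high] for f in features], dtype=float)
    y = np.array([f.label for f in features], dtype=float)
    if np.any(np.isnan(y)):
        raise ValueError("all features must carry a 0/1 label for fitting")
    return X, y.astype(int)


@dataclass
class LogisticModel:
    """Fitted propensity model: logit(p) = intercept + coef . z(features)."""

    coef: np.ndarray        # on standardized features
    intercept: float
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    regularized: bool = False

    def predict_propensity(self, features: list[SeizureFeatures]) -> np.ndarray:
        X = np.array([[f.wpc_low, f.wpc_high] for f in features], dtype=float)
        z = (X - self.feature_mean) / self.feature_scale
        logits = self.intercept + z @ self.coef
        return 1.0 / (1.0 + np.exp(-logits))

    def score(self, features: list[SeizureFeatures]) -> list[SeizureFeatures]:
        """Return copies of ``features`` with the propensity filled in."""
        p = self.predict_propensity(features)
        return [replace(f, propensity=float(pi)) for f, pi in zip(features, p)]


def fit_logistic(features: list[SeizureFeatures]) -> LogisticModel:
    """Maximum-likelihood logistic fit on standardized (wpc_low, wpc_high).

    Requires both classes with at least 3 examples each.  On perfectly
    separable data the unpenalised likelihood diverges; the fit then falls
    back to a small ridge penalty (1e-6) with a warning.
    """
    X, y = _design(features)
    counts = np.bincount(y, minlength=2)
    if counts.min() == 0:
        raise ValueError("both classes must be present to fit the classifier")
    if counts.min() < 3:
        raise ValueError(f"need >= 3 examples per class, got {counts.tolist()}")

    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0.0] = 1.0
    Z = (X - mean) / scale

    model = LogisticRegression(C=_C_ML, solver="lbfgs", max_iter=10_000, tol=1e-10)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(Z, y)
    # data are perfectly separated iff the fitted direction splits the
    # classes with a margin - the unpenalised likelihood then diverges
    margin = Z @ model.coef_.ravel()
    separated = margin[y == 0].max() < margin[y == 1].min()
    if separated:
        warnings.warn(
            "features perfectly separate the classes; refitting with a small "
            f"ridge penalty ({_RIDGE_FALLBACK:g})"
        )
        model = LogisticRegression(
            C=1.0 / _RIDGE_FALLBACK, solver="lbfgs", max_iter=10_000, tol=1e-10
        )
        model.fit(Z, y)
        regularized = True
    else:
        regularized = False
    return LogisticModel(
        model.coef_.ravel().copy(), float(model.intercept_[0]), mean, scale, regularized
    )


@dataclass
class ROCResult:
    """ROC curve with trapezoidal AUC and the accuracy-optimal threshold."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    decision_threshold: float

    def accuracy_at(self, scores: np.ndarray, labels: np.ndarray) -> float:
        pred = np.asarray(scores) >= self.decision_threshold
        return float(np.mean(pred == np.asarray(labels).astype(bool)))


def roc_auc(scores, labels) -> ROCResult:
    """ROC curve and AUC of ``scores`` against binary ``labels``.

    The trapezoidal AUC equals the tie-aware (mid-rank) concordance
    probability of the Mann-Whitney U statistic.  The decision threshold is
    the score cut maximising classification accuracy (ties resolved toward
    the smaller false-positive rate).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute a ROC curve")
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    area = float(_trapezoid_auc(fpr, tpr))
    correct = tpr * n_pos + (1.0 - fpr) * n_neg
    best = int(np.argmax(correct))
    return ROCResult(fpr, tpr, thr, area, float(thr[best]))


@dataclass
class LOOCVResult:
    """Leave-one-out cross-validation pooled over all seizures."""

    rocs: list[ROCResult]
    mean_auc: float
    scored: list[SeizureFeatures] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)


def loo_cv(
    features: list[SeizureFeatures],
    rounds: int = 10,
    seed: int | None = 0,
    group_by_patient: bool = False,
) -> LOOCVResult:
    """Leave-one-out propensities pooled into one ROC, repeated over rounds.

    Each seizure is scored by a model trained on all other seizures (or on
    all other *patients* when ``group_by_patient`` - the seizure-level CV of
    the original design leaks patient identity across folds, so the grouped
    variant is offered as an option).  The procedure is deterministic;
    rounds differ only in the order the training rows are presented, which
    matters only under stochastic fitting, so per-round AUCs coincide for
    this solver.  The mean AUC across rounds is reported.
    """
    if len(features) < 4:
        raise ValueError("need at least 4 seizures for leave-one-out CV")
    _design(features)  # validates labels present
    rng = np.random.default_rng(seed)

    rocs: list[ROCResult] = []
    scored: list[SeizureFeatures] = []
    excluded: list[str] = []
    for r in range(rounds):
        order = rng.permutation(len(features))
        scores, labels, kept = [], [], []
        for i in range(len(features)):
            if group_by_patient:
                train = [
                    f for f in features if f.patient_id != features[i].patient_id
                ]
            else:
                train = [features[j] for j in order if j != i]
            train_labels = {f.label for f in train}
            if len(train_labels) < 2:
                if r == 0:
                    warnings.warn(
                        f"fold for seizure {features[i].seizure_id!r} has a "
                        "single-class training set; fold excluded"
                    )
                    excluded.append(features[i].seizure_id)
                continue
            model = fit_logistic(train)
            scores.append(float(model.predict_propensity([features[i]])[0]))
            labels.append(features[i].label)
            kept.append(i)
        rocs.append(roc_auc(scores, labels))
        if r == 0:
            scored = [
                replace(features[i], propensity=s) for i, s in zip(kept, scores)
            ]
    return LOOCVResult(rocs, float(np.mean([r.auc for r in rocs])), scored, excluded)


@dataclass
class MeanDifference:
    """Estimation-statistics summary: effect size with a bootstrap 95% CI."""

    difference: float  # mean(B) - mean(A)
    ci_low: float
    ci_high: float
    n_boot: int

    def __str__(self):
        return (
            f"mean difference {self.difference:+.4f} "
            f"[95% CI {self.ci_low:+.4f}, {self.ci_high:+.4f}]"
        )


def mean_difference_bootstrap(
    group_a, group_b, n_boot: int = 5000, seed: int | None = None
) -> MeanDifference:
    """Mean difference (B - A) with a percentile bootstrap 95% CI."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("groups must be finite-valued")
    rng = np.random.default_rng(seed)
    boot_b = b[rng.integers(0, b.size, (n_boot, b.size))].mean(axis=1)
    boot_a = a[rng.integers(0, a.size, (n_boot, a.size))].mean(axis=1)
    lo, hi = np.percentile(boot_b - boot_a, [2.5, 97.5])
    return MeanDifference(float(b.mean() - a.mean()), float(lo), float(hi), n_boot)
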