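"""Model validation: classification metrics, r_m² external predictivity,
and applicability-domain analysis by the standardization approach.

Undefined metrics (zero denominators, constant predictions) are surfaced
as ``None`` / NaN with an explicit flag — never silently reported as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "confusion_metrics",
    "rm_squared",
    "applicability_domain",
    "ApplicabilityDomain",
    "ADReport",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.tp + self.tn + self.fp + self.fn < 1:
            raise ValueError("empty confusion matrix")


def confusion_metrics(c: ConfusionCounts):
    """Matthews correlation, sensitivity (TPR) and specificity (TNR).

        MCC = (TP·TN - FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
        TPR = TP / (TP + FN)        TNR = TN / (FP + TN)

    A metric whose denominator vanishes is returned as ``None``.
    """
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else None
    tpr = tp / (tp + fn) if (tp + fn) > 0 else None
    tnr = tn / (fp + tn) if (fp + tn) > 0 else None
    return mcc, tpr, tnr


def rm_squared(observed, predicted):
    """Roy's modified external-predictivity metric.

    r² is the squared Pearson correlation of observed vs predicted; r₀² is
    the coefficient of determination of the through-origin regression of
    observed on predicted (slope k = Σ o·p / Σ p², r₀² = 1 - Σ(o - k·p)² /
    Σ(o - ō)²); and

        r_m² = r² (1 - sqrt(max(r² - r₀², 0)))

    Values above 0.5 are conventionally read as good external
    predictability. Returns ``(r2, r0_2, rm2)``; constant predictions make
    all three ``None`` (undefined).
    """
    o = np.asarray(observed, float).ravel()
    p = np.asarray(predicted, float).ravel()
    if o.size != p.size or o.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.var(o) == 0:
        raise ValueError("observed values have zero variance")
    if np.var(p) == 0 or np.sum(p * p) == 0:
        return None, None, None
    r = np.corrcoef(o, p)[0, 1]
    r2 = float(r * r)
    k = float(np.sum(o * p) / np.sum(p * p))
    r0_2 = float(1.0 - np.sum((o - k * p) ** 2) / np.sum((o - o.mean()) ** 2))
    rm2 = float(r2 * (1.0 - math.sqrt(max(r2 - r0_2, 0.0))))
    return r2, r0_2, rm2


@dataclass
class ADReport:
    in_domain: np.ndarray  # bool per query compound
    s_max: np.ndarray
    s_min: np.ndarray
    s_mean: np.ndarray
    s_new: np.ndarray  # S_k = mean + 1.28 sd, NaN where the rule was not needed
    dropped_columns: np.ndarray  # indices of constant training columns


def applicability_domain(X_train, X_query, threshold: float = 3.0) -> ADReport:
    """Standardization-approach applicability domain.

    Each descriptor of each query compound is standardized against the
    training set, s_ki = |x_ki - mean_i| / sd_i. Compound k is inside the
    domain if its largest s_ki is at most ``threshold`` (3 = the 99.7%
    band of a normal descriptor distribution); it is an outlier outright if
    even its smallest s_ki exceeds the threshold; otherwise the 90th-
    percentile proxy S_k = mean(s_k) + 1.28 sd(s_k) decides (inside iff
    S_k <= threshold). Constant training columns are dropped with a
    warning.
    """
    Xt = np.asarray(X_train, float)
    Xq = np.asarray(X_query, float)
    if Xt.ndim != 2 or Xq.ndim != 2 or Xt.shape[1] != Xq.shape[1]:
        raise ValueError("train and query descriptor dimensions differ")
    mu = Xt.mean(axis=0)
    sd = Xt.std(axis=0, ddof=1)
    const = sd == 0
    dropped = np.where(const)[0]
    if const.any():
        import warnings

        warnings.warn(f"dropping {const.sum()} constant training column(s) from AD",
                      UserWarning)
    keep = ~const
    if not keep.any():
        raise ValueError("no non-constant training columns")
    S = np.abs(Xq[:, keep] - mu[keep]) / sd[keep]
    s_max = S.max(axis=1)
    s_min = S.min(axis=1)
    s_mean = S.mean(axis=1)
    s_sd = S.std(axis=1, ddof=1) if S.shape[1] > 1 else np.zeros(len(S))
    s_new = s_mean + 1.28 * s_sd
    in_domain = np.where(
        s_max <= threshold, True,
        np.where(s_min > threshold, False, s_new <= threshold),
    )
    s_new_report = np.where((s_max > threshold) & (s_min <= threshold), s_new, np.nan)
    return ADReport(in_domain=in_domain.astype(bool), s_max=s_max, s_min=s_min,
                    s_mean=s_mean, s_new=s_new_report, dropped_columns=dropped)


class ApplicabilityDomain:
    """Estimator-style wrapper: ``fit(X_train)`` then ``predict(X)`` returns
    the in-domain flags and ``score_samples(X)`` the mean standardized
    scores."""

    def __init__(self, threshold: float = 3.0):
        self.threshold = threshold

    def fit(self, X, y=None):
        X = np.asarray(X, float)
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=1)
        self._X_train = X
        return self

    def report(self, X) -> ADReport:
        if not hasattr(self, "_X_train"):
            raise RuntimeError("ApplicabilityDomain is not fitted")
        return applicability_domain(self._X_train, X, threshold=self.threshold)

    def predict(self, X):
        return self.report(X).in_domain

    def score_samples(self, X):
        return self.report(X).s_mean

    def get_params(self, deep=True):
        return {"threshold": self.threshold}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self
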