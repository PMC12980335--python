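"""Comparator metrics benchmarked against the KDE regulation score.

Two families:

* **Cohort-level** summaries (:func:`cohort_metric`) — mutual information,
  canonical correlation, Pearson/Spearman correlation, PC1 explained
  variance, coefficient of variation, Jensen–Shannon divergence — each
  reduced to a single healthy-vs-cancer summary oriented so that *more
  dysregulation pushes the summary above its null value* (1.0 for ratios,
  0.0 for the divergence).
* **Sample-level** distances (:func:`sample_distance`,
  :class:`ReferenceDistanceScorer`) — Manhattan, Euclidean, Chebyshev and
  Cosine distance to the healthy-reference centroid, and Mahalanobis
  distance under the reference mean and covariance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist, jensenshannon
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.metrics import mutual_info_score
from sklearn.utils.validation import check_is_fitted

from .io import GenePairMatrix
from .kde import _check_points

logger = logging.getLogger(__name__)

COHORT_METRICS = (
    "mutual_information",
    "canonical_correlation",
    "pearson",
    "spearman",
    "pca_variance",
    "coefficient_of_variation",
    "js_divergence",
)

DISTANCE_METRICS = ("manhattan", "euclidean", "chebyshev", "cosine", "mahalanobis")

#: Expected summary under no dysregulation, per metric.  Ratio-based metrics
#: have null 1.0; the Jensen–Shannon divergence of two draws from the same
#: law tends to 0, so its null is 0.0.
NULL_VALUES = {m: 1.0 for m in COHORT_METRICS} | {"js_divergence": 0.0}


@dataclass
class CohortMetricResult:
    """One cohort-level comparison: per-cohort values plus the oriented summary."""

    metric_id: str
    healthy_value: float | None
    cancer_value: float | None
    summary: float
    null_value: float

    @property
    def finite(self) -> bool:
        return bool(np.isfinite(self.summary))


def _values(x) -> np.ndarray:
    return x.values if isinstance(x, GenePairMatrix) else _check_points(x)


def _binned_mi(X: np.ndarray, n_bins: int) -> float:
    """Equal-frequency binned mutual information in bits.

    Quantile bins make the estimate invariant under strictly monotone
    per-gene transforms; ties can merge bins (pandas-style qcut semantics).
    """
    import pandas as pd

    bx = pd.qcut(X[:, 0], n_bins, labels=False, duplicates="drop")
    by = pd.qcut(X[:, 1], n_bins, labels=False, duplicates="drop")
    return float(mutual_info_score(bx, by) / np.log(2.0))


def _hist2d(X: np.ndarray, edges: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    h, _, _ = np.histogram2d(X[:, 0], X[:, 1], bins=edges)
    return (h / h.sum()).ravel()


def _js_divergence(h: np.ndarray, c: np.ndarray, n_bins: int) -> float:
    """Base-2 JSD between 2-D histograms on a shared pooled-range grid."""
    pooled = np.vstack([h, c])
    edges = tuple(
        np.linspace(pooled[:, j].min(), pooled[:, j].max(), n_bins + 1)
        for j in range(2)
    )
    # jensenshannon returns the distance (sqrt of the divergence)
    return float(jensenshannon(_hist2d(h, edges), _hist2d(c, edges), base=2.0) ** 2)


def _pc1_fraction(X: np.ndarray) -> float:
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    return float(PCA(n_components=2).fit(Z).explained_variance_ratio_[0])


def _cov_mean(X: np.ndarray) -> float:
    means = X.mean(axis=0)
    if np.any(means == 0):
        raise ValueError("coefficient of variation undefined for zero-mean gene")
    return float(np.mean(X.std(axis=0, ddof=1) / np.abs(means)))


def cohort_metric(
    metric_id: str,
    healthy,
    cancer,
    n_mi_bins: int = 8,
    n_jsd_bins: int = 16,
    min_samples: int = 20,
) -> CohortMetricResult:
    """Summarise healthy-vs-cancer dysregulation with one comparator metric.

    A zero denominator yields a non-finite summary, flagged with a warning
    so the caller can exclude it from robustness testing.
    """
    if metric_id not in COHORT_METRICS:
        raise ValueError(f"unknown cohort metric {metric_id!r}")
    h, c = _values(healthy), _values(cancer)
    for name, arr in (("healthy", h), ("cancer", c)):
        if arr.shape[0] < min_samples:
            raise ValueError(f"{name} cohort has fewer than {min_samples} samples")

    null = NULL_VALUES[metric_id]
    if metric_id == "js_divergence":
        val = _js_divergence(h, c, n_jsd_bins)
        return CohortMetricResult(metric_id, None, None, val, null)

    if metric_id in ("pearson", "canonical_correlation"):
        hv = abs(stats.pearsonr(h[:, 0], h[:, 1]).statistic)
        cv = abs(stats.pearsonr(c[:, 0], c[:, 1]).statistic)
        summary = _ratio(hv, cv)
    elif metric_id == "spearman":
        hv = abs(stats.spearmanr(h[:, 0], h[:, 1]).statistic)
        cv = abs(stats.spearmanr(c[:, 0], c[:, 1]).statistic)
        summary = _ratio(hv, cv)
    elif metric_id == "pca_variance":
        hv, cv = _pc1_fraction(h), _pc1_fraction(c)
        summary = _ratio(hv, cv)
    elif metric_id == "coefficient_of_variation":
        hv, cv = _cov_mean(h), _cov_mean(c)
        summary = _ratio(cv, hv)  # noisier cancer -> larger CoV -> summary > 1
    elif metric_id == "mutual_information":
        hv, cv = _binned_mi(h, n_mi_bins), _binned_mi(c, n_mi_bins)
        summary = _ratio(hv, cv)
    if not np.isfinite(summary):
        warnings.warn(
            f"{metric_id}: zero denominator, summary is non-finite and should "
            "be excluded from robustness testing",
            RuntimeWarning,
            stacklevel=2,
        )
    return CohortMetricResult(metric_id, float(hv), float(cv), float(summary), null)


def _ratio(num: float, den: float) -> float:
    return num / den if den != 0 else np.inf if num > 0 else np.nan


class ReferenceDistanceScorer(BaseEstimator, TransformerMixin):
    """Distance of each query to a healthy reference distribution.

    ``manhattan``/``euclidean``/``chebyshev``/``cosine`` measure distance to
    the reference centroid; ``mahalanobis`` uses the reference mean and
    covariance (with an optional diagonal ridge for near-singular cohorts).
    """

    def __init__(self, metric: str = "euclidean", ridge: float = 0.0):
        self.metric = metric
        self.ridge = ridge

    def fit(self, X, y=None):
        if self.metric not in DISTANCE_METRICS:
            raise ValueError(f"unknown distance metric {self.metric!r}")
        if isinstance(X, GenePairMatrix):
            X = X.healthy.values if (X.cohort == "healthy").any() else X.values
        X = _check_points(X)
        if X.shape[0] < 3:
            raise ValueError("reference needs at least 3 samples")
        self.centroid_ = X.mean(axis=0)
        if self.metric == "mahalanobis":
            cov = np.cov(X.T, ddof=1) + self.ridge * np.eye(2)
            if np.linalg.matrix_rank(cov) < 2 or np.linalg.det(cov) <= 0:
                raise ValueError(
                    "singular reference covariance; pass ridge > 0 to regularise"
                )
            self.covariance_ = cov
            self.precision_ = np.linalg.inv(cov)
        return self

    def distances(self, X) -> np.ndarray:
        check_is_fitted(self, "centroid_")
        X = _values(X)
        mu = self.centroid_[None, :]
        if self.metric == "mahalanobis":
            d = X - mu
            return np.sqrt(np.einsum("ij,jk,ik->i", d, self.precision_, d))
        if self.metric == "cosine":
            if np.allclose(self.centroid_, 0) or np.any(
                np.linalg.norm(X, axis=1) == 0
            ):
                raise ValueError("cosine distance undefined at the zero vector")
            return cdist(X, mu, metric="cosine").ravel()
        scipy_name = {"manhattan": "cityblock", "euclidean": "euclidean",
                      "chebyshev": "chebyshev"}[self.metric]
        return cdist(X, mu, metric=scipy_name).ravel()

    def transform(self, X) -> np.ndarray:
        return self.distances(X)[:, None]


def sample_distance(metric_id: str, reference, queries, ridge: float = 0.0) -> np.ndarray:
    """Functional form of :class:`ReferenceDistanceScorer` (fit + distances)."""
    return ReferenceDistanceScorer(metric=metric_id, ridge=ridge).fit(
        reference
    ).distances(queries)
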