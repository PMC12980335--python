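"""Covariance-based joint-distribution alignment across cohorts.

Matches the first two moments of a source cohort's two-gene expression to a
reference cohort's via an affine whitening/recoloring map,

    x  ->  A (x - mu_src) + mu_ref,      A = L_ref L_src^{-1},

with L the lower-triangular Cholesky factors of the cohort covariances.
By construction the transformed source has exactly the reference mean and
covariance, while linear relationships between the two genes are preserved
— which is what lets a regulation model fitted on one cohort (e.g. TCGA)
score an external cohort (e.g. a GEO series) without refitting.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import GenePairMatrix
from .kde import _check_points


def _moments(X: np.ndarray, ridge: float) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    cov = np.cov(X.T, ddof=1) + ridge * np.eye(2)
    return mu, cov


def _chol(cov: np.ndarray, which: str) -> np.ndarray:
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals[0] <= 1e-12 * max(eigvals[-1], 1e-300):
        raise ValueError(f"singular {which} covariance; pass ridge > 0")
    return cholesky(cov, lower=True)


class CovarianceAligner(BaseEstimator, TransformerMixin):
    """Affine transform aligning source moments onto reference moments.

    Parameters
    ----------
    ridge : float, default 0.0
        Diagonal term added to both covariances before factorisation, for
        near-singular cohorts.

    Attributes
    ----------
    source_mean_, reference_mean_ : ndarray (2,)
    source_cov_, reference_cov_ : ndarray (2, 2)
    mixing_matrix_ : ndarray (2, 2)
        A = L_ref L_src^{-1}; satisfies A src_cov A.T = ref_cov.
    """

    def __init__(self, ridge: float = 0.0):
        self.ridge = ridge

    def fit(self, X, X_reference):
        """Estimate the transform from source samples X to the reference."""
        X = _check_points(X)
        R = _check_points(X_reference)
        if X.shape[0] < 3 or R.shape[0] < 3:
            raise ValueError("both cohorts need at least 3 samples")
        self.source_mean_, self.source_cov_ = _moments(X, self.ridge)
        self.reference_mean_, self.reference_cov_ = _moments(R, self.ridge)
        L_src = _chol(self.source_cov_, "source")
        L_ref = _chol(self.reference_cov_, "reference")
        # A = L_ref L_src^{-1} via a triangular solve on the right
        self.mixing_matrix_ = solve_triangular(
            L_src.T, L_ref.T, lower=False
        ).T
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "mixing_matrix_")
        X = _check_points(X)
        return (X - self.source_mean_) @ self.mixing_matrix_.T + self.reference_mean_

    def inverse_transform(self, X) -> np.ndarray:
        check_is_fitted(self, "mixing_matrix_")
        X = _check_points(X)
        A_inv = np.linalg.inv(self.mixing_matrix_)
        return (X - self.reference_mean_) @ A_inv.T + self.source_mean_

    def to_dict(self) -> dict:
        check_is_fitted(self, "mixing_matrix_")
        return {
            "format": "kdereg-alignment",
            "source_mean": self.source_mean_.tolist(),
            "reference_mean": self.reference_mean_.tolist(),
            "source_cov": self.source_cov_.tolist(),
            "reference_cov": self.reference_cov_.tolist(),
            "mixing_matrix": self.mixing_matrix_.tolist(),
            "ridge": self.ridge,
        }


def fit_alignment(
    source: GenePairMatrix,
    reference: GenePairMatrix,
    healthy_only: bool = False,
    ridge: float = 0.0,
) -> CovarianceAligner:
    """Fit the alignment between two labelled cohorts.

    By default moments come from ALL samples of each cohort.  With
    ``healthy_only=True`` they come from the healthy-labelled subsets only
    (useful when the cancer fraction differs between cohorts and would bias
    the moments); the fitted transform is still applied to every sample.
    """
    if healthy_only:
        src, ref = source.healthy.values, reference.healthy.values
    else:
        src, ref = source.values, reference.values
    return CovarianceAligner(ridge=ridge).fit(src, ref)


def apply_alignment(
    transform: CovarianceAligner, points: np.ndarray | GenePairMatrix
):
    """Apply a fitted alignment row-wise; GenePairMatrix in, matrix out."""
    if isinstance(points, GenePairMatrix):
        return GenePairMatrix(
            sample_ids=points.sample_ids,
            gene_names=points.gene_names,
            values=transform.transform(points.values),
            cohort=points.cohort,
        )
    return transform.transform(points)
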