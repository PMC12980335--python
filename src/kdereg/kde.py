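"""Healthy-reference KDE and the per-sample regulation score.

The model estimates the joint density of a two-gene pair (writer/eraser
enzymes such as OGT and OGA) over a healthy reference cohort with a
bivariate Gaussian product kernel,

    f(x, y) = 1/(m h1 h2) * sum_i phi((x - x_i)/h1) * phi((y - y_i)/h2),

with per-gene bandwidths h_g = 2 * IQR_g * m^(-1/3).  A density threshold
KDEt is calibrated as the median density of the reference samples, so that
half of the healthy cohort falls inside the high-density region.  A query's
density d maps to a regulation score in [0, 1] by the piecewise-linear rule

    score = 0.5 * (d - d_min) / (KDEt - d_min)              if d <= KDEt
    score = 0.5 + 0.5 * (d - KDEt) / (d_max - KDEt)         if d >  KDEt

with d_min = 0 (the infimum of a Gaussian KDE) and d_max the maximum density
observed at the reference points at fit time; out-of-range densities clamp.
High density means high score: 0.5 is the calibrated healthy median, values
toward 0 indicate dysregulation.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import __version__
from .io import GenePairMatrix

_SQRT_2PI = np.sqrt(2.0 * np.pi)


def compute_bandwidth(values: np.ndarray) -> float:
    """Interquartile-range bandwidth ``h = 2 * IQR * m**(-1/3)``.

    Quantiles use linear interpolation (the type-7 convention).  Raises for
    fewer than two points or a zero IQR, in which case the caller should
    supply a manual bandwidth instead.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("bandwidth needs at least two values")
    if not np.all(np.isfinite(v)):
        raise ValueError("bandwidth input must be finite")
    q1, q3 = np.percentile(v, [25.0, 75.0])
    iqr = q3 - q1
    if iqr <= 0:
        raise ValueError(
            "IQR is zero (constant or near-constant data); "
            "supply a manual bandwidth"
        )
    return 2.0 * iqr * v.size ** (-1.0 / 3.0)


def piecewise_score(
    density: np.ndarray, density_min: float, threshold: float, density_max: float
) -> np.ndarray:
    """Map densities to [0, 1] scores, linear on each side of the threshold.

    Continuous at the threshold (both branches give 0.5 there); clamped so
    densities outside the calibration range hit the endpoints exactly.
    """
    d = np.asarray(density, dtype=float)
    if density_max <= threshold:
        raise ValueError(
            "degenerate calibration: density_max must exceed the threshold"
        )
    if threshold <= density_min:
        raise ValueError(
            "degenerate calibration: threshold must exceed density_min"
        )
    below = 0.5 * (d - density_min) / (threshold - density_min)
    above = 0.5 + 0.5 * (d - threshold) / (density_max - threshold)
    return np.clip(np.where(d <= threshold, below, above), 0.0, 1.0)


def _check_points(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("expected an (n, 2) matrix of gene-pair expression")
    if not np.all(np.isfinite(X)):
        raise ValueError("query points must be finite")
    return X


class KdeRegulationScorer(BaseEstimator, TransformerMixin):
    """Map joint two-gene expression to a regulation score in [0, 1].

    Fit on the healthy reference cohort only; score anything.

    Parameters
    ----------
    bandwidths : (float, float), optional
        Manual per-gene kernel bandwidths; by default each gene's bandwidth
        is derived from its own IQR via :func:`compute_bandwidth`.
    min_samples : int, default 10
        Minimum reference cohort size accepted by :meth:`fit`.

    Attributes
    ----------
    reference_points_ : ndarray (m, 2)
        The healthy training expression.
    bandwidths_ : ndarray (2,)
        Fitted (h1, h2), expression units.
    kde_threshold_ : float
        KDEt, the median reference density (midpoint of the two central
        order statistics for even m).
    density_min_, density_max_ : float
        Score-calibration bounds: 0 and the maximum reference density.
    gene_names_ : tuple of str or None

    Examples
    --------
    >>> import numpy as np
    >>> rng = np.random.default_rng(0)
    >>> healthy = rng.normal(10, 2, size=(100, 2))
    >>> scorer = KdeRegulationScorer().fit(healthy)
    >>> float(np.median(scorer.score_samples(healthy)))
    0.5
    """

    def __init__(self, bandwidths=None, min_samples: int = 10):
        self.bandwidths = bandwidths
        self.min_samples = min_samples

    def fit(self, X, y=None, gene_names: tuple[str, str] | None = None):
        """Fit on an (m, 2) matrix of healthy reference expression.

        Accepts a :class:`GenePairMatrix`, in which case only the
        healthy-labelled rows are used.
        """
        if isinstance(X, GenePairMatrix):
            gene_names = gene_names or X.gene_names
            X = X.healthy.values
        X = _check_points(X)
        m = X.shape[0]
        if m < self.min_samples:
            raise ValueError(
                f"need at least {self.min_samples} healthy reference samples, got {m}"
            )
        if self.bandwidths is not None:
            h1, h2 = (float(h) for h in self.bandwidths)
            if h1 <= 0 or h2 <= 0:
                raise ValueError("manual bandwidths must be positive")
        else:
            h1 = compute_bandwidth(X[:, 0])
            h2 = compute_bandwidth(X[:, 1])
        self.reference_points_ = X.copy()
        self.bandwidths_ = np.array([h1, h2])
        self.gene_names_ = tuple(gene_names) if gene_names is not None else None
        ref_density = self.density(X)
        self.kde_threshold_ = float(np.median(ref_density))
        self.density_min_ = 0.0
        self.density_max_ = float(ref_density.max())
        return self

    def density(self, X) -> np.ndarray:
        """Evaluate the fitted joint KDE at (n, 2) query points."""
        check_is_fitted(self, "bandwidths_")
        X = _check_points(X)
        h1, h2 = self.bandwidths_
        ref = self.reference_points_
        # (n, m) standardised offsets; m and n stay small (10^2..10^4)
        zx = (X[:, 0, None] - ref[None, :, 0]) / h1
        zy = (X[:, 1, None] - ref[None, :, 1]) / h2
        kern = np.exp(-0.5 * (zx * zx + zy * zy)) / (2.0 * np.pi)
        return kern.mean(axis=1) / (h1 * h2)

    def score_samples(self, X) -> np.ndarray:
        """Regulation scores in [0, 1] for (n, 2) query points."""
        check_is_fitted(self, "kde_threshold_")
        return piecewise_score(
            self.density(X), self.density_min_, self.kde_threshold_,
            self.density_max_,
        )

    def transform(self, X) -> np.ndarray:
        """Scores as an (n, 1) column, for pipeline composition."""
        if isinstance(X, GenePairMatrix):
            X = X.values
        return self.score_samples(X)[:, None]

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        check_is_fitted(self, "kde_threshold_")
        return {
            "format": "kdereg-model",
            "version": __version__,
            "kernel": "gaussian-product",
            "gene_names": list(self.gene_names_) if self.gene_names_ else None,
            "bandwidths": self.bandwidths_.tolist(),
            "kde_threshold": self.kde_threshold_,
            "density_min": self.density_min_,
            "density_max": self.density_max_,
            "reference_points": self.reference_points_.tolist(),
            "params": {"min_samples": self.min_samples},
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_dict(cls, d: dict) -> "KdeRegulationScorer":
        model = cls(min_samples=d.get("params", {}).get("min_samples", 10))
        model.reference_points_ = np.asarray(d["reference_points"], dtype=float)
        model.bandwidths_ = np.asarray(d["bandwidths"], dtype=float)
        model.kde_threshold_ = float(d["kde_threshold"])
        model.density_min_ = float(d["density_min"])
        model.density_max_ = float(d["density_max"])
        gn = d.get("gene_names")
        model.gene_names_ = tuple(gn) if gn else None
        if model.bandwidths_.shape != (2,) or (model.bandwidths_ <= 0).any():
            raise ValueError("model file has invalid bandwidths")
        if not (model.density_min_ <= model.kde_threshold_ <= model.density_max_):
            raise ValueError("model file violates density_min <= KDEt <= density_max")
        return model

    @classmethod
    def load(cls, path: str | Path) -> "KdeRegulationScorer":
        return cls.from_dict(json.loads(Path(path).read_text()))


# -- functional wrappers -----------------------------------------------


def fit_regulation_model(
    healthy: GenePairMatrix | np.ndarray,
    bandwidths=None,
    min_samples: int = 10,
) -> KdeRegulationScorer:
    """Fit the healthy-reference model; see :class:`KdeRegulationScorer`."""
    return KdeRegulationScorer(bandwidths=bandwidths, min_samples=min_samples).fit(
        healthy
    )


def evaluate_density(model: KdeRegulationScorer, points) -> np.ndarray:
    return model.density(points)


def score(model: KdeRegulationScorer, points) -> np.ndarray:
    if isinstance(points, GenePairMatrix):
        points = points.values
    return model.score_samples(points)
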