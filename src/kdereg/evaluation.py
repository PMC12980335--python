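"""Robustness criteria, AUROC, cross-validated classification and the
synthetic benchmark driver.

A metric is *robust* if (i) at 1.0x noise — healthy and cancer drawn from
the same law — its replicate summaries centre on the no-dysregulation null,
and (ii) its summaries increase strictly with the noise multiplier,
confirmed by one-sided Mann–Whitney U tests between successive levels.

Classification value is measured by AUROC of single-feature logistic
regressions under stratified k-fold cross-validation; any feature that
needs a healthy reference (the regulation score, the reference distances)
is refitted inside each fold on the fold's healthy *training* samples only,
so test data never leak into the reference density.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .io import GenePairMatrix
from .kde import KdeRegulationScorer
from .metrics import (
    COHORT_METRICS,
    DISTANCE_METRICS,
    NULL_VALUES,
    ReferenceDistanceScorer,
    cohort_metric,
)
from .simulate import BenchmarkConfig, generate_condition

logger = logging.getLogger(__name__)

#: Features understood by cross_validate / the benchmark AUROC loop.
#: "expression" is the raw two-gene baseline; "product" and "ratio" are the
#: gene1*gene2 and gene1/gene2 derived features.
SAMPLE_FEATURES = (
    "regulation_score",
    "expression",
    "gene1",
    "gene2",
    "product",
    "ratio",
) + DISTANCE_METRICS


def auroc(scores, labels) -> float:
    """Area under the ROC curve; equals U/(n1*n2) with ties credited 0.5."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length vectors")
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("AUROC needs exactly two classes present")
    return float(roc_auc_score(labels, scores))


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test.

    D is the supremum absolute difference of the two empirical CDFs; the
    p-value comes from the standard asymptotic two-sample distribution.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("KS test needs non-empty samples")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def mwu_one_sided(greater, lesser) -> float:
    """One-sided Mann–Whitney U p-value (alternative: `greater` larger).

    Exact enumeration when both samples have at most 20 tie-free values,
    otherwise the tie-corrected normal approximation.
    """
    g = np.asarray(greater, dtype=float)
    l = np.asarray(lesser, dtype=float)
    if g.size == 0 or l.size == 0:
        raise ValueError("Mann–Whitney test needs non-empty samples")
    pooled = np.concatenate([g, l])
    exact = g.size <= 20 and l.size <= 20 and np.unique(pooled).size == pooled.size
    res = stats.mannwhitneyu(
        g, l, alternative="greater", method="exact" if exact else "asymptotic"
    )
    return float(res.pvalue)


def robustness_check(
    summaries: dict[float, np.ndarray],
    null_value: float,
    alpha: float = 0.01,
    null_tol: float = 0.1,
) -> tuple[bool, bool]:
    """Apply the two robustness criteria to per-level replicate summaries.

    ``null_ok``: the 1.0x replicate mean lies within ``null_tol`` of the
    null value *and* a two-sided one-sample t-test does not reject at
    ``alpha``.  ``monotone_ok``: every successive-level one-sided MWU has
    p < ``alpha``.  Non-finite summaries are dropped with a warning.
    """
    levels = sorted(float(k) for k in summaries)
    if 1.0 not in levels:
        raise ValueError("robustness check requires the 1.0x noise level")
    clean: dict[float, np.ndarray] = {}
    for lv in levels:
        v = np.asarray(summaries[lv], dtype=float)
        finite = np.isfinite(v)
        if not finite.all():
            logger.warning(
                "dropping %d non-finite summaries at level %gx", (~finite).sum(), lv
            )
        v = v[finite]
        if v.size < 2:
            raise ValueError(f"fewer than 2 finite replicates at level {lv}x")
        clean[lv] = v

    base = clean[1.0]
    within = abs(float(base.mean()) - null_value) <= null_tol
    if base.std(ddof=1) == 0:
        not_rejected = float(base.mean()) == null_value
    else:
        not_rejected = stats.ttest_1samp(base, null_value).pvalue >= alpha
    null_ok = bool(within and not_rejected)

    monotone_ok = all(
        mwu_one_sided(clean[hi], clean[lo]) < alpha
        for lo, hi in zip(levels, levels[1:])
    )
    return null_ok, bool(monotone_ok)


# -- single-feature classification -------------------------------------


def _feature_columns(
    feature_id: str,
    X: np.ndarray,
    reference: np.ndarray | None,
    ridge: float = 0.0,
) -> np.ndarray:
    """Build the design matrix for one feature, given the fold's healthy
    training reference where the feature needs one."""
    if feature_id == "expression":
        return X
    if feature_id == "gene1":
        return X[:, [0]]
    if feature_id == "gene2":
        return X[:, [1]]
    if feature_id == "product":
        return (X[:, 0] * X[:, 1])[:, None]
    if feature_id == "ratio":
        denom = np.where(X[:, 1] == 0, np.finfo(float).tiny, X[:, 1])
        return (X[:, 0] / denom)[:, None]
    if reference is None:
        raise ValueError(f"feature {feature_id!r} needs a healthy reference")
    if feature_id == "regulation_score":
        return KdeRegulationScorer().fit(reference).transform(X)
    if feature_id in DISTANCE_METRICS:
        return ReferenceDistanceScorer(metric=feature_id, ridge=ridge).fit(
            reference
        ).transform(X)
    raise ValueError(f"unknown feature {feature_id!r}")


def _logistic_auroc(F_train, y_train, F_test, y_test) -> float:
    # C=inf: unregularised single-feature fit (tiny finite C only if a
    # caller ever hits perfect separation and needs the fallback)
    clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=5000)
    clf.fit(F_train, y_train)
    return auroc(clf.predict_proba(F_test)[:, 1], y_test)


@dataclass
class CvResult:
    """Cross-validated AUROC of one single-feature classifier."""

    feature_id: str
    fold_aurocs: np.ndarray
    mean_auroc: float = field(init=False)

    def __post_init__(self) -> None:
        self.fold_aurocs = np.asarray(self.fold_aurocs, dtype=float)
        self.mean_auroc = float(self.fold_aurocs.mean())


def cross_validate(
    matrix: GenePairMatrix,
    feature_id: str,
    k: int = 5,
    seed: int = 0,
    ridge: float = 0.0,
) -> CvResult:
    """Stratified k-fold CV of a single-feature logistic regression.

    Reference-based features (regulation score, distances) are refitted per
    fold on the healthy training samples only.  ``unknown``-labelled samples
    are excluded.  Deterministic given the seed.
    """
    if feature_id not in SAMPLE_FEATURES:
        raise ValueError(f"unknown feature {feature_id!r}")
    labelled = matrix.subset(np.isin(matrix.cohort, ["healthy", "cancer"]))
    X = labelled.values
    y = (labelled.cohort == "cancer").astype(int)
    if min((y == 0).sum(), (y == 1).sum()) < k:
        raise ValueError(f"each class needs at least k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    aucs = []
    for train_idx, test_idx in skf.split(X, y):
        ref = X[train_idx][y[train_idx] == 0]
        F_train = _feature_columns(feature_id, X[train_idx], ref, ridge)
        F_test = _feature_columns(feature_id, X[test_idx], ref, ridge)
        aucs.append(_logistic_auroc(F_train, y[train_idx], F_test, y[test_idx]))
    return CvResult(feature_id=feature_id, fold_aurocs=np.asarray(aucs))


# -- benchmark driver ---------------------------------------------------

KDE_SUMMARY_ID = "kde_regulation"


def _kde_cohort_summary(score_healthy: np.ndarray, score_cancer: np.ndarray) -> float:
    """Cohort-level dysregulation summary for the KDE score itself.

    Dysregulation mass is 1 − mean score; the summary is its cancer/healthy
    ratio, oriented like the comparator ratios (null 1.0, grows with noise).
    """
    return float((1.0 - score_cancer.mean()) / (1.0 - score_healthy.mean()))


@dataclass
class EvalReport:
    """Benchmark output: tidy per-replicate tables plus robustness flags."""

    config: BenchmarkConfig
    summaries: pd.DataFrame  # shape, multiplier, replicate, metric, summary
    aurocs: pd.DataFrame     # shape, multiplier, replicate, feature, auroc
    robustness: pd.DataFrame  # shape, metric, null_ok, monotone_ok

    def summary_values(self, shape: str, metric: str) -> dict[float, np.ndarray]:
        sub = self.summaries[
            (self.summaries["shape"] == shape) & (self.summaries["metric"] == metric)
        ]
        return {
            float(lv): g["summary"].to_numpy()
            for lv, g in sub.groupby("multiplier")
        }


def run_benchmark(
    config: BenchmarkConfig,
    cohort_metrics: tuple[str, ...] = (KDE_SUMMARY_ID,) + COHORT_METRICS,
    features: tuple[str, ...] = ("regulation_score",),
    alpha: float = 0.01,
    null_tol: float = 0.1,
) -> EvalReport:
    """Run the synthetic benchmark grid end to end.

    Per (shape, multiplier, replicate): independent train and test cohort
    pairs are generated; the KDE model and any reference distances are fit
    on the *training healthy* samples; cohort metrics are summarised on the
    test pair; single-feature logistic classifiers are trained on the
    training pair and scored by AUROC on the test pair.  Robustness flags
    are then computed per (shape, metric) across noise levels.
    """
    unknown = set(features) - set(SAMPLE_FEATURES)
    if unknown:
        raise ValueError(f"unknown features: {sorted(unknown)}")
    sum_rows, auc_rows = [], []
    for shape in config.shapes:
        for mult in config.noise_levels:
            for rep in range(config.replicates):
                train_h, train_c = generate_condition(config, shape, mult, rep, "train")
                test_h, test_c = generate_condition(config, shape, mult, rep, "test")

                model = KdeRegulationScorer().fit(train_h.values)
                s_test_h = model.score_samples(test_h.values)
                s_test_c = model.score_samples(test_c.values)

                for metric in cohort_metrics:
                    if metric == KDE_SUMMARY_ID:
                        val = _kde_cohort_summary(s_test_h, s_test_c)
                    else:
                        val = cohort_metric(metric, test_h, test_c).summary
                    sum_rows.append((shape, mult, rep, metric, val))

                if features:
                    X_train = np.vstack([train_h.values, train_c.values])
                    y_train = np.r_[
                        np.zeros(train_h.n_samples, int),
                        np.ones(train_c.n_samples, int),
                    ]
                    X_test = np.vstack([test_h.values, test_c.values])
                    y_test = np.r_[
                        np.zeros(test_h.n_samples, int),
                        np.ones(test_c.n_samples, int),
                    ]
                    ref = train_h.values
                    for feat in features:
                        F_tr = _feature_columns(feat, X_train, ref)
                        F_te = _feature_columns(feat, X_test, ref)
                        auc_rows.append(
                            (shape, mult, rep, feat,
                             _logistic_auroc(F_tr, y_train, F_te, y_test))
                        )
        logger.info("benchmark: finished shape %s", shape)

    summaries = pd.DataFrame(
        sum_rows, columns=["shape", "multiplier", "replicate", "metric", "summary"]
    )
    aurocs = pd.DataFrame(
        auc_rows, columns=["shape", "multiplier", "replicate", "feature", "auroc"]
    )

    rob_rows = []
    report = EvalReport(config, summaries, aurocs, pd.DataFrame())
    for shape in config.shapes:
        for metric in cohort_metrics:
            values = report.summary_values(shape, metric)
            null = 1.0 if metric == KDE_SUMMARY_ID else NULL_VALUES[metric]
            try:
                null_ok, monotone_ok = robustness_check(
                    values, null, alpha=alpha, null_tol=null_tol
                )
            except ValueError:  # all-replicate non-finite summaries
                null_ok = monotone_ok = False
            rob_rows.append((shape, metric, null_ok, monotone_ok))
    report.robustness = pd.DataFrame(
        rob_rows, columns=["shape", "metric", "null_ok", "monotone_ok"]
    )
    return report
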