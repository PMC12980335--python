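# Methods

## Model

`kdereg` scores each sample of a two-gene regulatory pair by its position in
the joint expression density of a healthy reference cohort. The density is a
bivariate Gaussian product-kernel KDE over the m reference pairs (x_i, y_i):

    f(x, y) = 1/(m h1 h2) Σ_i φ((x − x_i)/h1) φ((y − y_i)/h2)

Each gene gets its own bandwidth from the interquartile-range rule
h_g = 2 · IQR_g · m^(−1/3), with the IQR computed by linear-interpolation
(type-7) quantiles. A product kernel with per-gene bandwidths is used rather
than a single shared h: a single bandwidth with 1/(m·h) normalisation is
dimensionally inconsistent for a bivariate density, and per-gene bandwidths
additionally make the score exactly invariant under per-gene affine maps
(h scales with the IQR, so the density and all calibration constants rescale
by the same factor and the score's ratios cancel). The two forms coincide
when the genes' IQRs are equal.

The score calibration uses three constants fixed at fit time:

* **KDEt** — the median of the densities evaluated at the m reference points
  (midpoint of the two central order statistics for even m). Exactly half of
  an even-sized reference cohort lies at or above KDEt; for odd m the middle
  sample, whose density equals the threshold, counts as inside.
* **d_min = 0** — the infimum of a Gaussian KDE. Using 0 rather than the
  minimum observed density keeps scoring of new samples independent of which
  reference sample happened to be most peripheral.
* **d_max** — the maximum density at the reference points. Computed from the
  training references only, so test-set scoring never depends on test data;
  queries denser than any reference clamp to score 1.

Density d maps to the score piecewise-linearly: 0.5·(d − d_min)/(KDEt − d_min)
below the threshold, 0.5 + 0.5·(d − KDEt)/(d_max − KDEt) above it, clamped to
[0, 1]. The map is continuous at KDEt and non-decreasing in density. High
density means high score: the healthy median is 0.5 by construction and
dysregulated samples drift toward 0. Fitting requires at least 10 healthy
samples (configurable) and a non-zero IQR in both genes; constant genes are
rejected with instructions to pass a manual bandwidth.

The tool is unit-agnostic: expression is consumed as-is (an optional
log2(x+1) read-time transform is available), and the affine invariance means
linear unit changes do not move scores.

## Synthetic benchmark

The generator emulates a two-gene regulatory system under four laws. The
driver gene1 is Normal(10, 2); gene2 is the regulatory response plus
Gaussian noise with sd = base_noise_sd × multiplier, base_noise_sd = 1.0:

* linear: y = x
* exponential: y = exp(0.15·x)
* parabolic: y = 0.25·(x − 10)²
* multicluster: equal-weight Gaussian mixture at (6,6), (10,12), (14,8),
  within-cluster sd 1.0 in gene1; the multiplier inflates the gene2
  within-cluster spread only.

Dysregulation is purely a noise inflation (multipliers 1.0/1.5/2.0 in the
benchmark grid): the conditional mean of gene2 given gene1 is independent of
the multiplier, and — because the multiplier scales a standard-normal draw
made after the driver draws, and the multiplier is excluded from the seed
derivation — the gene1 marginal is *identical* across multipliers for a
given replicate. Defaults are sized so the 1.5× and 2.0× conditions are
separable but not trivially so (null AUROC ≈ 0.50; 1.5×/2.0× AUROC ≈
0.58–0.67 at n = 200 per cohort, depending on shape). The exponential rate
of 0.15 keeps the curve's response spread (IQR ≈ 2) commensurate with the
base noise sd of 1.0; a much steeper exponential makes the responder's
dynamic range so large that unit-scale noise becomes invisible relative to
the IQR-driven bandwidth and no noise level is detectable.

Seeding: one master seed; per-(shape, replicate, cohort, train/test-role)
integer seeds are derived through `numpy.random.SeedSequence` spawn keys
(all below 2³¹), so any replicate regenerates byte-identically in isolation.

What the generator does **not** emulate: count noise or zero inflation,
library-size or batch structure, marginal distributions of any real dataset,
or >2-gene regulation. Passing benchmarks therefore demonstrate the score's
behaviour under controlled joint-density distortions, not performance on any
particular clinical cohort.

## Comparator metrics and robustness testing

Cohort-level comparators (mutual information, canonical correlation,
Pearson, Spearman, PC1 explained variance, coefficient of variation,
Jensen–Shannon divergence) are each reduced to one summary oriented so more
dysregulation pushes it above its null (1.0 for ratios, 0.0 for the
divergence). Choices worth noting:

* MI uses equal-frequency binning (8×8 default, base 2): deterministic and
  invariant under strictly monotone per-gene transforms, unlike fixed-width
  bins or k-NN estimators.
* JSD uses 16×16 histograms on a shared grid spanning the pooled range, with
  the 0·log 0 = 0 convention. At benchmark sample sizes the plug-in JSD of
  two finite samples from the same law is biased well above 0, which is
  exactly the kind of spurious baseline signal the robustness criterion is
  designed to flag.
* Canonical correlation of two univariate variables equals |Pearson r|; it is
  reported separately only to keep the comparator roster explicit.
* A zero denominator (e.g. an exactly uncorrelated cohort) yields a
  non-finite summary flagged with a warning and excluded from robustness
  testing rather than an exception.

The KDE score's own cohort summary is the dysregulation-mass ratio
(1 − mean cancer score)/(1 − mean healthy score), computed on held-out test
cohorts, null 1.0.

A metric is **robust** for a shape if (i) at 1.0× noise its replicate
summaries centre on the null — mean within ±0.1 of the null value and a
two-sided one-sample t-test not rejecting at α = 0.01 — and (ii) summaries
increase strictly with noise, every successive-level one-sided Mann–Whitney
U test rejecting at p < .01. The MWU uses exact enumeration when both
samples have ≤ 20 tie-free values, otherwise the tie-corrected normal
approximation.

Sample-level comparators are distances to the healthy training reference
(Manhattan/Euclidean/Chebyshev/Cosine to the centroid; Mahalanobis under the
reference mean and covariance, with an optional diagonal ridge for
near-singular references). Classification value is AUROC — computed as the
normalised Mann–Whitney U with ties credited 0.5 — of a single-feature
logistic regression fitted without regularisation (C = ∞; a small finite C
is the documented fallback for perfectly separable features). Under
cross-validation the folds are stratified with a fixed seed, and every
reference-dependent feature (the regulation score and all distances alike)
is refitted inside each fold on that fold's healthy *training* samples only,
so the reference density never sees test data.

## Cross-cohort alignment

To score an external cohort with a model fitted elsewhere, the external
cohort's two-gene mean and covariance are matched to the reference's by the
affine map x ↦ A(x − μ_src) + μ_ref with A = L_ref L_src⁻¹, the L's being
lower-triangular Cholesky factors. Cholesky recoloring is used over the
symmetric square root because it is cheaper and bit-for-bit deterministic;
both satisfy A Σ_src Aᵀ = Σ_ref exactly. By default moments are fitted on
all samples of each cohort (whole datasets are being aligned); a
healthy-only mode exists because differing cancer fractions bias the
moments, and the choice is recorded in the run sidecar. Covariances whose
smallest eigenvalue is below 10⁻¹² of the largest are rejected with a
pointer to the ridge option. Alignment is exact only up to second moments:
nonlinear batch distortions are out of scope.

## Numerical and interface choices

* Density evaluation is vectorised over an (n_queries × m) kernel matrix;
  at the package's intended scales (m, n ≤ ~10⁴) this is faster and simpler
  than FFT-gridded approximations and exact to machine precision.
* Degenerate calibrations (d_max = KDEt, i.e. a reference cohort with no
  density interior) raise rather than return clamped constants.
* Scores are serialised nowhere; the *model* is — a single JSON document
  with reference points, bandwidths, threshold, bounds, gene names and tool
  version — so external cohorts can be scored reproducibly.
* Tables are delimited text with the delimiter inferred from the extension
  (.csv comma, otherwise tab) and overridable; rows with missing expression
  are dropped and counted; cohort labels normalise case-insensitively to
  healthy/cancer/unknown, and unknown samples are scoreable but excluded
  from fits and tests that need labels.
* Every CLI run emits a `.run.json` sidecar carrying the tool version and
  the fully resolved configuration.

## Benchmark problem sizes

The packaged evaluation grid is 4 shapes × 3 noise levels × 100 replicates
with 200 samples per cohort and independent train/test cohort pairs per
replicate — small enough to run in about a minute on one CPU while leaving
the Monte-Carlo error of replicate means near 0.005 AUROC.

## Known limitations

* Two genes only; no adaptive bandwidths; no multivariate extension.
* The score is relative to the supplied healthy reference — reference
  imbalance or batch effects move the calibration (mitigated, not removed,
  by covariance alignment).
* The plug-in comparator estimators (binned MI, histogram JSD) are biased at
  small n; they are benchmarked as-is because that is how they are commonly
  applied, not because the bias is desirable.
* Transcript-level only: a regulation score says nothing about enzyme
  activity or actual post-translational modification levels.
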