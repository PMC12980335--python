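# kdereg

Kernel-density regulation scoring for tightly coupled gene pairs.

Some cellular systems are controlled by exactly two genes working in
opposition — the motivating case is protein O-GlcNAcylation, written by the
single transferase OGT and erased by the single hydrolase OGA. Direct
measurement of such modifications is fragile and low-throughput, but the
*joint* expression of the writer/eraser pair is routinely available from
bulk or single-cell transcriptomics. `kdereg` quantifies how far any
sample's joint expression deviates from a healthy reference, producing an
interpretable per-sample **regulation score** in [0, 1], and ships the
simulation benchmark, comparator metrics, evaluation harness and
cross-cohort alignment needed to validate the score. It is aimed at
computational biologists studying dysregulation of two-enzyme systems in
disease cohorts (tumor vs. normal being the canonical design).

## The model

Given m healthy reference samples with expression pairs (x_i, y_i), the
joint density is a bivariate Gaussian product-kernel KDE,

    f(x, y) = 1/(m h1 h2) Σ_i φ((x − x_i)/h1) φ((y − y_i)/h2),

with per-gene bandwidths from the interquartile-range rule

    h_g = 2 · IQR_g · m^(−1/3).

A density threshold KDEt is calibrated as the **median density of the
reference samples**, so that half the healthy cohort falls inside the
high-density region. Each sample's density d then maps piecewise-linearly
to a score,

    score = 0.5 · (d − d_min)/(KDEt − d_min)          if d ≤ KDEt
    score = 0.5 + 0.5 · (d − KDEt)/(d_max − KDEt)     if d > KDEt

with d_min = 0 and d_max the maximum reference density (out-of-range
densities clamp). A healthy-typical sample scores ≈ 0.5; scores toward 0
indicate expression falling in regions healthy tissue rarely occupies —
dysregulation. Because the bandwidths track each gene's IQR, scores are
invariant under per-gene affine rescaling of the data.

For transferring a fitted model to an external cohort (different platform
or preprocessing), `CovarianceAligner` matches the external cohort's
two-gene mean and covariance to the reference's with a Cholesky
whitening/recoloring map, so the model scores external samples without
refitting.

## Worked example

```python
import numpy as np
from kdereg import (ShapeSpec, generate_pair, fit_regulation_model,
                    ks_two_sample, cross_validate)
from kdereg.simulate import combine

healthy = generate_pair(ShapeSpec("linear", seed=1, n_samples=200))
cancer = generate_pair(ShapeSpec("linear", seed=2, n_samples=200,
                                 noise_multiplier=2.0, cohort_label="cancer"))

model = fit_regulation_model(healthy)          # healthy reference only
s_h = model.score_samples(healthy.values)
s_c = model.score_samples(cancer.values)
print("healthy median/mean: %.3f / %.3f" % (np.median(s_h), s_h.mean()))
print("cancer  median/mean: %.3f / %.3f" % (np.median(s_c), s_c.mean()))
print("KS D = %.3f, p = %.3g" % ks_two_sample(s_h, s_c))
cv = cross_validate(combine(healthy, cancer), "regulation_score", seed=0)
print("5-fold CV AUROC: %.3f" % cv.mean_auroc)
```

prints

```
healthy median/mean: 0.500 / 0.531
cancer  median/mean: 0.270 / 0.309
KS D = 0.365, p = 1.9e-12
5-fold CV AUROC: 0.716
```

The healthy median is 0.5 by calibration. The cancer cohort — the same
regulatory law with its residual noise doubled — drifts into low-density
regions and scores far lower; the KS test rejects distributional equality
and a single-feature logistic classifier on the score separates the cohorts
with AUROC ≈ 0.72.

The same workflow is available from the shell:

```bash
kdereg simulate --shape linear --n 200 --seed 1 --out healthy.tsv
kdereg fit --input healthy.tsv --model-out model.json
kdereg score --model model.json --input mixed.tsv --out scores.tsv
kdereg benchmark --replicates 100 --seed 0 --out-prefix bench
```

Every command writes a `.run.json` sidecar with the tool version and the
fully resolved configuration. See `kdereg --help` for the remaining
subcommands (`metrics`, `classify`, `kstest`, `align`).

## Scope

The package consumes delimited text tables (TSV/CSV) of per-sample
expression for two genes plus a cohort label; it does not download or parse
TCGA/GEO archives, map probes to genes, or model >2-gene systems. Scores
describe transcript-level joint density only — they make no claim about
protein-level modification state.
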