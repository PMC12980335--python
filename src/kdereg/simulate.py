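"""Synthetic two-gene cohorts under four regulatory shapes.

A "healthy" cohort follows one of four regulatory laws — linear,
exponential, parabolic, or multicluster — relating a driver gene (gene1)
to a responder (gene2).  Graded dysregulation in the "cancer" cohort is
induced by inflating the responder noise by a multiplier (1.0x, 1.5x,
2.0x): the conditional mean of gene2 given gene1 never changes, only the
spread around it, and the gene1 marginal is untouched.

Shape functions and their default parameters (the tool's documented
study conditions; all overridable through :class:`ShapeSpec`):

==============  =======================================  ==================
shape           law for gene2 | gene1 = x                 shape_params keys
==============  =======================================  ==================
linear          slope*x + intercept                       slope, intercept
exponential     scale*exp(rate*x)                         rate, scale
parabolic       curvature*(x - vertex)**2                 curvature, vertex
multicluster    Gaussian mixture; gene2 spread inflated   centers, weights,
                by the noise multiplier                    cluster_sd
==============  =======================================  ==================

The driver is Normal(10, 2) and the base responder noise sd is 1.0 by
default, sized so the 1.5x and 2.0x conditions are separable but not
trivially so at n = 200 per cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .io import GenePairMatrix

SHAPES = ("linear", "exponential", "parabolic", "multicluster")

DEFAULT_SHAPE_PARAMS: dict[str, dict] = {
    "linear": {"slope": 1.0, "intercept": 0.0},
    "exponential": {"rate": 0.15, "scale": 1.0},
    "parabolic": {"curvature": 0.25, "vertex": 10.0},
    "multicluster": {
        "centers": [[6.0, 6.0], [10.0, 12.0], [14.0, 8.0]],
        "weights": [1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0],
        "cluster_sd": 1.0,
    },
}


@dataclass
class ShapeSpec:
    """Full generative description of one synthetic cohort."""

    shape: str
    driver_mean: float = 10.0
    driver_sd: float = 2.0
    shape_params: dict = field(default_factory=dict)
    base_noise_sd: float = 1.0
    noise_multiplier: float = 1.0
    n_samples: int = 200
    seed: int = 0
    cohort_label: str = "healthy"

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}; expected one of {SHAPES}")
        if self.base_noise_sd <= 0:
            raise ValueError("base_noise_sd must be positive")
        if self.noise_multiplier <= 0:
            raise ValueError("noise_multiplier must be positive")
        if self.n_samples < 2:
            raise ValueError("n_samples must be at least 2")
        params = dict(DEFAULT_SHAPE_PARAMS[self.shape])
        params.update(self.shape_params)
        self.shape_params = params
        if self.shape == "multicluster":
            w = np.asarray(self.shape_params["weights"], dtype=float)
            if not np.isclose(w.sum(), 1.0):
                raise ValueError("multicluster weights must sum to 1")

    def to_dict(self) -> dict:
        return asdict(self)


def _conditional_mean(shape: str, params: dict, x: np.ndarray) -> np.ndarray:
    if shape == "linear":
        return params["slope"] * x + params["intercept"]
    if shape == "exponential":
        return params["scale"] * np.exp(params["rate"] * x)
    if shape == "parabolic":
        return params["curvature"] * (x - params["vertex"]) ** 2
    raise ValueError(f"no conditional-mean form for shape {shape!r}")


def generate_pair(spec: ShapeSpec) -> GenePairMatrix:
    """Draw one cohort from the spec's generative law, deterministic in seed.

    The noise multiplier scales a standard-normal draw made *after* the
    driver draws, so cohorts that differ only in multiplier share identical
    gene1 values under the same seed (paired-noise design).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    noise_sd = spec.base_noise_sd * spec.noise_multiplier
    if spec.shape == "multicluster":
        centers = np.asarray(spec.shape_params["centers"], dtype=float)
        weights = np.asarray(spec.shape_params["weights"], dtype=float)
        csd = float(spec.shape_params["cluster_sd"])
        comp = rng.choice(len(centers), size=n, p=weights)
        x = centers[comp, 0] + csd * rng.standard_normal(n)
        y = centers[comp, 1] + noise_sd * rng.standard_normal(n)
    else:
        x = rng.normal(spec.driver_mean, spec.driver_sd, size=n)
        y = _conditional_mean(spec.shape, spec.shape_params, x)
        y = y + noise_sd * rng.standard_normal(n)
    ids = [f"{spec.cohort_label}-{spec.shape}-{i:05d}" for i in range(n)]
    return GenePairMatrix(
        sample_ids=ids,
        gene_names=("gene1", "gene2"),
        values=np.column_stack([x, y]),
        cohort=np.asarray([spec.cohort_label] * n, dtype=object),
    )


@dataclass
class BenchmarkConfig:
    """Grid of benchmark conditions: shapes x noise levels x replicates."""

    shapes: tuple[str, ...] = SHAPES
    noise_levels: tuple[float, ...] = (1.0, 1.5, 2.0)
    replicates: int = 100
    n_healthy: int = 200
    n_cancer: int = 200
    master_seed: int = 0
    base_spec: dict = field(default_factory=dict)  # ShapeSpec overrides

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be at least 1")
        levels = tuple(float(m) for m in self.noise_levels)
        if sorted(levels) != list(levels) or 1.0 not in levels:
            raise ValueError("noise levels must be ascending and include 1.0")
        self.noise_levels = levels
        for s in self.shapes:
            if s not in SHAPES:
                raise ValueError(f"unknown shape {s!r}")

    def to_dict(self) -> dict:
        return asdict(self)


_COHORT_KEY = {"healthy": 0, "cancer": 1}
_ROLE_KEY = {"train": 0, "test": 1}


def derive_seed(
    master_seed: int, shape: str, replicate: int, cohort: str, role: str = "train"
) -> int:
    """Deterministic per-cohort seed from a spawn-keyed seed sequence.

    The noise multiplier is deliberately absent from the key: cancer cohorts
    at different multipliers share driver and base-noise draws, so the gene1
    marginal is identical across multipliers by construction.
    """
    ss = np.random.SeedSequence(
        entropy=int(master_seed),
        spawn_key=(SHAPES.index(shape), int(replicate), _COHORT_KEY[cohort],
                   _ROLE_KEY[role]),
    )
    return int(ss.generate_state(1)[0] % (2**31))


def generate_condition(
    config: BenchmarkConfig,
    shape: str,
    multiplier: float,
    replicate: int,
    role: str = "train",
) -> tuple[GenePairMatrix, GenePairMatrix]:
    """(healthy, cancer) cohorts for one benchmark condition and replicate.

    The healthy cohort is always generated at multiplier 1.0; only the
    cancer cohort carries the requested noise inflation.  Any replicate can
    be regenerated in isolation, byte-identically, from the master seed.
    """
    if float(multiplier) not in config.noise_levels:
        raise ValueError(
            f"multiplier {multiplier} not in configured levels {config.noise_levels}"
        )
    if not 0 <= replicate < config.replicates:
        raise ValueError(f"replicate {replicate} outside 0..{config.replicates - 1}")
    common = dict(config.base_spec)
    healthy = generate_pair(
        ShapeSpec(
            shape=shape,
            noise_multiplier=1.0,
            n_samples=config.n_healthy,
            seed=derive_seed(config.master_seed, shape, replicate, "healthy", role),
            cohort_label="healthy",
            **common,
        )
    )
    cancer = generate_pair(
        ShapeSpec(
            shape=shape,
            noise_multiplier=float(multiplier),
            n_samples=config.n_cancer,
            seed=derive_seed(config.master_seed, shape, replicate, "cancer", role),
            cohort_label="cancer",
            **common,
        )
    )
    return healthy, cancer


def combine(*matrices: GenePairMatrix) -> GenePairMatrix:
    """Stack cohorts into one labelled matrix (ids must stay unique)."""
    if not matrices:
        raise ValueError("need at least one matrix")
    gene_names = matrices[0].gene_names
    for m in matrices:
        if m.gene_names != gene_names:
            raise ValueError("gene names differ between matrices")
    return GenePairMatrix(
        sample_ids=[s for m in matrices for s in m.sample_ids],
        gene_names=gene_names,
        values=np.vstack([m.values for m in matrices]),
        cohort=np.concatenate([m.cohort for m in matrices]),
    )
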