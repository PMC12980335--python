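import numpy as np
import pytest
from hypothesis import settings

from kdereg import GenePairMatrix, ShapeSpec, generate_pair

# reproducible hypothesis runs in any environment
settings.register_profile("det", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("det")


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def healthy_cohort():
    """One deterministic healthy linear-shape cohort, n=200 (even)."""
    return generate_pair(ShapeSpec("linear", seed=101, n_samples=200))


@pytest.fixture
def cancer_cohort():
    """Matching 2.0x-noise cancer cohort."""
    return generate_pair(
        ShapeSpec("linear", seed=202, n_samples=200, noise_multiplier=2.0,
                  cohort_label="cancer")
    )


def make_matrix(values, cohort="healthy", gene_names=("gene1", "gene2"),
                prefix="s"):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    cohort = [cohort] * n if isinstance(cohort, str) else list(cohort)
    return GenePairMatrix(
        sample_ids=[f"{prefix}{i}" for i in range(n)],
        gene_names=gene_names,
        values=values,
        cohort=np.asarray(cohort, dtype=object),
    )


@pytest.fixture
def mixed_cohort(healthy_cohort, cancer_cohort):
    from kdereg.simulate import combine

    return combine(healthy_cohort, cancer_cohort)
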