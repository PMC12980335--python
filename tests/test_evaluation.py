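import itertools

import numpy as np
import pytest

from kdereg import (
    BenchmarkConfig,
    auroc,
    cross_validate,
    ks_two_sample,
    mwu_one_sided,
    robustness_check,
    run_benchmark,
)
from kdereg.evaluation import KDE_SUMMARY_ID
from kdereg.simulate import combine, generate_condition

from conftest import make_matrix


def auroc_by_pair_enumeration(scores, labels):
    """Oracle: count concordant positive-negative pairs, ties half credit."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0
        for p, n in itertools.product(pos, neg)
    )
    return wins / (len(pos) * len(neg))


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert auroc([0.3, 0.3, 0.3, 0.3], [1, 1, 0, 0]) == 0.5

    def test_hand_enumerated_value(self):
        # pairs: (0.9 vs 0.6), (0.9 vs 0.1), (0.4 vs 0.6), (0.4 vs 0.1)
        assert auroc([0.9, 0.4, 0.6, 0.1], [1, 1, 0, 0]) == 0.75

    def test_matches_exhaustive_pair_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 51))
            scores = rng.choice(np.linspace(0, 1, 13), size=n)  # forces ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert auroc(scores, labels) == pytest.approx(
                auroc_by_pair_enumeration(scores, labels), abs=1e-12
            )

    def test_complement_symmetry_for_tie_free_scores(self, rng):
        scores = rng.permutation(np.linspace(0, 1, 40))
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        assert auroc(scores, labels) + auroc(-scores, labels) == \
            pytest.approx(1.0, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            auroc([0.1, 0.2], [1, 1])


class TestKsTwoSample:
    def test_identical_samples(self):
        d, _ = ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0

    def test_disjoint_supports(self):
        d, _ = ks_two_sample([0.0, 0.0], [1.0, 1.0])
        assert d == 1.0

    def test_stepwise_ecdf_enumeration(self):
        d, _ = ks_two_sample([1.0, 2.0], [1.5, 2.5])
        assert d == 0.5

    def test_invariant_under_strictly_monotone_transform(self, rng):
        a = rng.normal(size=60)
        b = rng.normal(0.5, 1.3, size=45)
        d0, _ = ks_two_sample(a, b)
        f = lambda x: np.exp(x) + x**3  # strictly increasing
        d1, _ = ks_two_sample(f(a), f(b))
        assert d0 == pytest.approx(d1, abs=1e-15)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


class TestMwuOneSided:
    def test_exact_enumeration_small_case(self):
        # fully separated 3v3: one of C(6,3)=20 assignments, p = 0.05
        assert mwu_one_sided([10, 11, 12], [1, 2, 3]) == pytest.approx(0.05)

    def test_identical_vectors_not_significant(self):
        p = mwu_one_sided([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p >= 0.5

    def test_direction_check(self):
        p = mwu_one_sided([1, 2, 3], [10, 11, 12])
        assert p > 0.9

    def test_large_samples_use_tie_corrected_normal(self, rng):
        g = rng.normal(1.0, 1.0, 100).round(1)  # rounded -> ties
        l = rng.normal(0.0, 1.0, 100).round(1)
        p = mwu_one_sided(g, l)
        assert 0 < p < 1e-6


class TestRobustnessCheck:
    def test_flat_summaries_are_not_monotone(self, rng):
        flat = {m: np.full(50, 1.0) + rng.normal(0, 1e-9, 50)
                for m in (1.0, 1.5, 2.0)}
        null_ok, monotone_ok = robustness_check(flat, null_value=1.0)
        assert null_ok and not monotone_ok

    def test_well_separated_levels_pass_both_criteria(self, rng):
        levels = {
            1.0: rng.normal(1.0, 0.01, 100),
            1.5: rng.normal(1.3, 0.01, 100),
            2.0: rng.normal(1.6, 0.01, 100),
        }
        assert robustness_check(levels, null_value=1.0) == (True, True)

    def test_spurious_baseline_signal_fails_null(self, rng):
        levels = {
            1.0: rng.normal(1.4, 0.01, 100),
            1.5: rng.normal(1.6, 0.01, 100),
        }
        null_ok, monotone_ok = robustness_check(levels, null_value=1.0)
        assert not null_ok and monotone_ok

    def test_missing_baseline_level_rejected(self, rng):
        with pytest.raises(ValueError, match="1.0x"):
            robustness_check({1.5: rng.normal(size=10),
                              2.0: rng.normal(size=10)}, 1.0)


class TestCrossValidate:
    def test_separable_feature_is_learnt(self, rng):
        n = 200
        y = np.repeat([0, 1], n // 2)
        vals = np.column_stack([y + rng.normal(0, 0.01, n),
                                rng.normal(10, 1, n)])
        m = make_matrix(vals, cohort=np.where(y == 1, "cancer", "healthy"))
        res = cross_validate(m, "gene1", seed=0)
        assert res.mean_auroc > 0.99
        assert len(res.fold_aurocs) == 5
        assert res.mean_auroc == pytest.approx(res.fold_aurocs.mean())

    def test_label_independent_feature_centres_on_half(self, rng):
        aucs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            vals = r.normal(10, 2, size=(2000, 2))
            cohort = np.where(r.integers(0, 2, 2000) == 1, "cancer", "healthy")
            m = make_matrix(vals, cohort=cohort)
            aucs.append(cross_validate(m, "gene1", seed=seed).mean_auroc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_seeded_determinism(self, mixed_cohort):
        a = cross_validate(mixed_cohort, "regulation_score", seed=7)
        b = cross_validate(mixed_cohort, "regulation_score", seed=7)
        np.testing.assert_array_equal(a.fold_aurocs, b.fold_aurocs)

    def test_regulation_score_separates_noisy_cancer(self, mixed_cohort):
        res = cross_validate(mixed_cohort, "regulation_score", seed=0)
        assert res.mean_auroc > 0.6

    def test_class_too_small_for_folds(self, rng):
        vals = rng.normal(size=(10, 2))
        m = make_matrix(vals, cohort=["cancer"] * 3 + ["healthy"] * 7)
        with pytest.raises(ValueError, match="at least k"):
            cross_validate(m, "gene1", k=5)

    def test_unknown_feature_rejected(self, mixed_cohort):
        with pytest.raises(ValueError, match="unknown feature"):
            cross_validate(mixed_cohort, "tsne")


@pytest.fixture(scope="module")
def reduced_report():
    cfg = BenchmarkConfig(replicates=30, master_seed=314)
    return run_benchmark(cfg)


class TestBenchmark:
    def test_report_covers_the_full_grid(self, reduced_report):
        rep = reduced_report
        assert set(rep.summaries["shape"]) == set(rep.config.shapes)
        assert set(rep.summaries["multiplier"]) == {1.0, 1.5, 2.0}
        assert len(rep.robustness) == 4 * (1 + 7)

    def test_kde_score_is_robust_on_all_shapes(self, reduced_report):
        kde_rows = reduced_report.robustness.query(
            f"metric == '{KDE_SUMMARY_ID}'"
        )
        assert kde_rows.null_ok.all()
        assert kde_rows.monotone_ok.all()

    def test_some_comparator_fails_on_a_nonlinear_shape(self, reduced_report):
        rows = reduced_report.robustness.query(
            f"metric != '{KDE_SUMMARY_ID}' and shape != 'linear'"
        )
        assert (~(rows.null_ok & rows.monotone_ok)).any()

    def test_auroc_grows_with_noise(self, reduced_report):
        means = reduced_report.aurocs.groupby("multiplier")["auroc"].mean()
        assert means[1.0] < means[1.5] < means[2.0]
        assert means[1.0] == pytest.approx(0.5, abs=0.05)
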