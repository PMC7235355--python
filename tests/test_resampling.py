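import numpy as np
import pytest

from bridgenet import (
    EstimatorConfig,
    ItemResponseMatrix,
    StabilityResult,
    case_dropping_bootstrap,
    case_dropping_bootstrap_multi,
    cs_coefficient,
    difference_test,
    nonparametric_bootstrap,
)
from bridgenet.resampling import centrality_difference_tests, percentile_ci
from bridgenet.synthetic import SyntheticSpec, generate_dataset

from conftest import make_items

FAST = dict(n_points=8, min_ratio=0.2)


@pytest.fixture(scope="module")
def boot_dataset():
    spec = SyntheticSpec(
        p_community_a=5, p_community_b=5, n=250, seed=11,
        n_redundant_pairs=0, missing_rate=0.0, n_reverse_coded=0,
        weight_range=(0.3, 0.5),
    )
    m, gt = generate_dataset(spec)
    return m, gt


class TestNonparametricBootstrap:
    def test_fixed_seed_is_bit_reproducible(self, boot_dataset):
        m, _ = boot_dataset
        est = EstimatorConfig(**FAST)
        a = nonparametric_bootstrap(m, est, B=2, seed=5)
        b = nonparametric_bootstrap(m, est, B=2, seed=5)
        np.testing.assert_array_equal(a.edge_samples, b.edge_samples)
        np.testing.assert_array_equal(a.ei_samples, b.ei_samples)
        c = nonparametric_bootstrap(m, est, B=2, seed=6)
        assert not np.array_equal(a.edge_samples, c.edge_samples)

    def test_strong_edge_ci_excludes_zero(self, boot_dataset):
        m, gt = boot_dataset
        est = EstimatorConfig(**FAST)
        res = nonparametric_bootstrap(m, est, B=80, seed=1)
        # strongest planted edge by |partial correlation|
        p = len(gt.item_ids)
        iu = np.triu_indices(p, 1)
        k = int(np.argmax(np.abs(gt.partial_corr[iu])))
        w = gt.partial_corr[iu][k]
        if w > 0:
            assert res.ci_lower[k] > 0
        else:
            assert res.ci_upper[k] < 0

    def test_ci_endpoints_are_order_statistics(self, boot_dataset):
        m, _ = boot_dataset
        res = nonparametric_bootstrap(m, EstimatorConfig(**FAST), B=40, seed=2)
        for k in range(res.edge_samples.shape[1]):
            col = np.sort(res.edge_samples[:, k])
            assert res.ci_lower[k] in col
            assert res.ci_upper[k] in col
            assert res.ci_lower[k] <= np.median(col) <= res.ci_upper[k]

    def test_failing_replicates_counted_and_capped(self):
        # one item's variance hinges on a single respondent: most resamples
        # that miss them produce a constant column and fail estimation
        rng = np.random.default_rng(0)
        values = np.ones((8, 4))
        values[:, :3] = rng.integers(0, 6, size=(8, 3))
        values[0, 3] = 5.0
        m = ItemResponseMatrix(
            [f"r{i}" for i in range(8)], make_items(4, lo=0, hi=6), values
        )
        with pytest.raises(RuntimeError, match="failed"):
            nonparametric_bootstrap(m, EstimatorConfig(**FAST), B=30, seed=0)


class TestCaseDroppingBootstrap:
    def test_fixed_seed_reproducible_and_multi_consistent(self, boot_dataset):
        m, _ = boot_dataset
        est = EstimatorConfig(**FAST)
        kw = dict(drop_levels=(0.2, 0.5), B=10, seed=3)
        single = case_dropping_bootstrap(m, est, statistic="ei", **kw)
        multi = case_dropping_bootstrap_multi(m, est, statistics=("ei", "bridge_ei"), **kw)
        np.testing.assert_array_equal(
            single.correlations[0.2], multi["ei"].correlations[0.2]
        )
        rerun = case_dropping_bootstrap(m, est, statistic="ei", **kw)
        for lv in (0.2, 0.5):
            np.testing.assert_array_equal(
                single.correlations[lv], rerun.correlations[lv]
            )

    def test_small_subsets_are_skipped_with_warning(self, boot_dataset):
        m, _ = boot_dataset
        sub = ItemResponseMatrix(m.respondent_ids[:12], m.items, m.values[:12])
        with pytest.warns(UserWarning, match="skipped"):
            res = case_dropping_bootstrap(
                sub, EstimatorConfig(**FAST), drop_levels=(0.1, 0.9), B=3, seed=0
            )
        assert 0.9 in res.skipped_levels
        assert res.drop_levels == [0.1]

    def test_stable_structure_keeps_high_correlation_at_small_drop(self, boot_dataset):
        m, _ = boot_dataset
        res = case_dropping_bootstrap(
            m, EstimatorConfig(**FAST), statistic="ei",
            drop_levels=(0.1,), B=25, seed=4,
        )
        cors = res.correlations[0.1]
        assert np.nanmedian(cors) > 0.8


def _stability(corrs_by_level, threshold=0.7, prob=0.95):
    return StabilityResult(
        statistic="ei",
        drop_levels=sorted(corrs_by_level),
        correlations={k: np.asarray(v, dtype=float) for k, v in corrs_by_level.items()},
        B=len(next(iter(corrs_by_level.values()))),
        seed=0,
        correlation_threshold=threshold,
        probability_level=prob,
    )


class TestCsCoefficient:
    def test_perfect_stability_gives_max_level(self):
        s = _stability({lv: np.ones(50) for lv in (0.1, 0.3, 0.5, 0.7)})
        assert cs_coefficient(s) == 0.7

    def test_no_stability_gives_zero(self):
        s = _stability({lv: np.full(50, 0.5) for lv in (0.1, 0.3)})
        assert cs_coefficient(s) == 0.0

    def test_mixed_case_matches_hand_evaluation(self):
        # level 0.1: 96% of draws ≥ 0.7 → qualifies; 0.2: 90% → fails;
        # 0.3: 100% → qualifies; CS = largest qualifying level = 0.3
        lv1 = np.concatenate([np.full(96, 0.9), np.full(4, 0.1)])
        lv2 = np.concatenate([np.full(90, 0.8), np.full(10, 0.2)])
        lv3 = np.full(100, 0.75)
        s = _stability({0.1: lv1, 0.2: lv2, 0.3: lv3})
        assert cs_coefficient(s) == 0.3

    def test_nan_replicates_excluded(self):
        lv = np.concatenate([np.full(95, 0.9), np.full(5, np.nan)])
        s = _stability({0.1: lv})
        assert cs_coefficient(s) == 0.1

    def test_value_lies_in_zero_union_levels(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            levels = (0.1, 0.2, 0.5)
            s = _stability({lv: rng.uniform(0, 1, 40) for lv in levels})
            assert cs_coefficient(s) in {0.0, *levels}


class TestDifferenceTest:
    def test_identical_samples_not_significant(self):
        x = np.random.default_rng(1).normal(size=200)
        res = difference_test(x, x, alpha=0.05)
        assert res.ci_lower == res.ci_upper == 0.0
        assert not res.significant

    def test_separated_samples_significant(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0.6, 0.05, 500)
        b = rng.normal(0.0, 0.05, 500)
        res = difference_test(a, b, alpha=0.05)
        assert res.significant and res.ci_lower > 0

    def test_significance_matches_interval_position(self):
        rng = np.random.default_rng(3)
        for shift in (0.0, 0.02, 0.2):
            a = rng.normal(shift, 0.1, 300)
            b = rng.normal(0, 0.1, 300)
            res = difference_test(a, b, alpha=0.05)
            outside = (res.ci_lower > 0) or (res.ci_upper < 0)
            assert res.significant == outside

    def test_alpha_one_flags_any_nonzero_median_difference(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0.3, 0.01, 101)
        res = difference_test(a, np.zeros(101), alpha=1.0)
        assert res.significant

    def test_mismatched_replicates_rejected(self):
        with pytest.raises(ValueError, match="mismatched"):
            difference_test(np.zeros(5), np.zeros(6))

    def test_centrality_difference_tests_paired(self, boot_dataset):
        m, _ = boot_dataset
        res = nonparametric_bootstrap(m, EstimatorConfig(**FAST), B=30, seed=9)
        diffs = centrality_difference_tests(res, metric="ei", alpha=0.05)
        assert len(diffs) == m.p * (m.p - 1) // 2
        for d in diffs:
            assert d.significant == ((d.ci_lower > 0) or (d.ci_upper < 0))


class TestPercentileCi:
    def test_quantile_ordering_and_membership(self, rng):
        samples = rng.standard_normal((101, 3))
        lo, hi = percentile_ci(samples)
        assert np.all(lo <= hi)
        for k in range(3):
            assert lo[k] in samples[:, k] and hi[k] in samples[:, k]
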