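"""Monte-Carlo null, ratio-bias null, permutation consistency, regression, KS."""

import itertools

import numpy as np
import pytest

from huetrack import (
    NullDistribution2D,
    PrecisionPair,
    empirical_tail_p,
    equal_deviation_ratio_null,
    ks_uniform_circular,
    monte_carlo_null,
    null_p_value,
    permutation_consistency,
    regression_through_origin,
)
from huetrack.validation import InsufficientSimulationWarning


def _gaussian_null(rng, mean=(8.0, 16.0), sd=(1.0, 2.0), n=1000):
    samples = np.column_stack(
        [rng.normal(mean[0], sd[0], n), rng.normal(mean[1], sd[1], n)]
    )
    return NullDistribution2D(
        mean_precise=float(samples[:, 0].mean()),
        mean_imprecise=float(samples[:, 1].mean()),
        sd_precise_axis=float(samples[:, 0].std(ddof=1)),
        sd_imprecise_axis=float(samples[:, 1].std(ddof=1)),
        n_sim=n,
        samples=samples,
    )


class TestNullPValue:
    def test_observed_at_null_mean_gives_p_one(self, rng):
        null = _gaussian_null(rng)
        obs = PrecisionPair.from_sds(null.mean_precise, null.mean_imprecise)
        assert null_p_value(obs, null) == pytest.approx(1.0)

    def test_three_sigma_on_both_axes_closed_form(self, rng):
        null = _gaussian_null(rng)
        obs = PrecisionPair.from_sds(
            null.mean_precise + 3 * null.sd_precise_axis,
            null.mean_imprecise + 3 * null.sd_imprecise_axis,
        )
        assert null_p_value(obs, null) == pytest.approx(np.exp(-9.0), rel=1e-10)

    def test_parametric_and_empirical_tails_agree(self, rng):
        null = _gaussian_null(rng, n=4000)
        for sds_out in (0.5, 1.0, 1.5):
            obs = PrecisionPair.from_sds(
                null.mean_precise + sds_out * null.sd_precise_axis,
                null.mean_imprecise + sds_out * null.sd_imprecise_axis,
            )
            p_param = null_p_value(obs, null)
            p_emp = empirical_tail_p(obs, null)
            assert p_emp == pytest.approx(p_param, abs=4 * np.sqrt(p_param / null.n_sim) + 0.01)

    def test_degenerate_null_rejected(self, rng):
        null = _gaussian_null(rng)
        null.sd_precise_axis = 0.0
        with pytest.raises(ValueError):
            null_p_value(PrecisionPair.from_sds(8, 16), null)


class TestMonteCarloNull:
    def test_seeded_determinism_and_shape(self, rng):
        targets = np.column_stack(
            [rng.uniform(0, 360, 40), np.mod(rng.uniform(0, 360, 40) + 90, 360)]
        )
        pair = PrecisionPair.from_sds(8.0, 16.0)
        with pytest.warns(InsufficientSimulationWarning):
            a = monte_carlo_null(targets, pair, n_sim=30, rng=3)
            b = monte_carlo_null(targets, pair, n_sim=30, rng=3)
        assert np.array_equal(a.samples, b.samples)
        assert a.samples.shape == (30, 2)
        assert np.all(a.samples[:, 0] <= a.samples[:, 1])

    def test_null_cloud_centers_near_generating_sds(self, rng):
        """exp2 design at (8, 16): refitted pairs scatter around the truth."""
        targets = rng.uniform(0, 360, 300)
        pair = PrecisionPair.from_sds(8.0, 16.0)
        null = monte_carlo_null(targets, pair, n_sim=120, design="exp2", rng=4)
        assert null.mean_precise == pytest.approx(8.0, rel=0.25)
        assert null.mean_imprecise == pytest.approx(16.0, rel=0.25)


class TestEqualDeviationRatioNull:
    def test_ratios_bounded_below_by_one_and_median_biased_up(self):
        res = equal_deviation_ratio_null(sd=15.0, n_errors=300, n_sim=40, rng=5)
        assert np.all(res.ratios >= 1.0)
        assert res.median_ratio > 1.0
        assert 0.0 <= res.frac_exceeding <= 1.0

    def test_bias_shrinks_with_sample_size(self):
        small = equal_deviation_ratio_null(sd=15.0, n_errors=100, n_sim=40, rng=6)
        large = equal_deviation_ratio_null(sd=15.0, n_errors=3000, n_sim=40, rng=6)
        assert large.median_ratio < small.median_ratio

    def test_invalid_sd(self):
        with pytest.raises(ValueError):
            equal_deviation_ratio_null(sd=-1.0)


class TestPermutationConsistency:
    def test_identical_pairs_give_zero_distance_and_smallest_p(self, rng):
        x = rng.uniform(5, 25, (8, 2))
        s, p = permutation_consistency(x, x, n_perm=999, rng=1)
        assert s == pytest.approx(0.0)
        assert p <= 0.05  # only permutations tying at zero can match

    def test_exhaustive_five_subject_oracle(self, rng):
        """Monte-Carlo p approaches the exhaustive 120-permutation p."""
        x = rng.uniform(5, 25, (5, 2))
        y = x + rng.normal(0, 1.0, (5, 2))
        obs = float(np.sum(np.linalg.norm(x - y, axis=1)))
        dmat = np.linalg.norm(x[:, None, :] - y[None, :, :], axis=2)
        sums = [
            dmat[np.arange(5), list(perm)].sum()
            for perm in itertools.permutations(range(5))
        ]
        exact_p = np.mean(np.asarray(sums) <= obs)
        _, p = permutation_consistency(x, y, n_perm=20000, rng=2)
        assert p == pytest.approx(exact_p, abs=0.02)

    def test_invariant_to_joint_relabeling(self, rng):
        x = rng.uniform(5, 25, (10, 2))
        y = x + rng.normal(0, 2.0, (10, 2))
        s1, _ = permutation_consistency(x, y, n_perm=100, rng=3)
        order = rng.permutation(10)
        s2, _ = permutation_consistency(x[order], y[order], n_perm=100, rng=3)
        assert s1 == pytest.approx(s2)

    def test_too_few_subjects(self, rng):
        x = rng.uniform(5, 25, (4, 2))
        with pytest.raises(ValueError):
            permutation_consistency(x, x)


class TestRegressionThroughOrigin:
    def test_exact_proportionality(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        a, f, p, df = regression_through_origin(x, 2 * x)
        assert a == pytest.approx(2.0)
        assert np.isinf(f) and p == 0.0
        assert df == (1, 3)

    def test_matches_suppressed_intercept_linear_model(self, rng):
        """Oracle: statsmodels OLS without a constant term."""
        import statsmodels.api as sm

        for _ in range(20):
            x = rng.uniform(1, 30, 12)
            y = 1.8 * x + rng.normal(0, 3, 12)
            a, f, p, df = regression_through_origin(x, y)
            fit = sm.OLS(y, x[:, None]).fit()
            assert a == pytest.approx(float(fit.params[0]), abs=1e-10)
            assert f == pytest.approx(float(fit.fvalue), rel=1e-10)
            assert p == pytest.approx(float(fit.f_pvalue), rel=1e-8)
            assert df == (1, 11)

    def test_closed_form_slope(self, rng):
        x = rng.uniform(1, 10, 20)
        y = rng.uniform(1, 10, 20)
        a, *_ = regression_through_origin(x, y)
        assert a == pytest.approx(np.sum(x * y) / np.sum(x * x), rel=1e-14)

    def test_all_zero_x_rejected(self):
        with pytest.raises(ValueError):
            regression_through_origin(np.zeros(5), np.ones(5))


class TestKsUniformCircular:
    def test_equispaced_angles_fit_uniform(self):
        d, p = ks_uniform_circular(np.arange(0, 360, 3.6) + 1.8)
        assert d <= 1 / 100
        assert p > 0.99

    def test_point_mass_rejected(self):
        d, p = ks_uniform_circular(np.full(100, 42.0))
        assert d > 0.8
        assert p < 1e-10
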