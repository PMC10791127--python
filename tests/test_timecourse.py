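"""Half-normal precision, z-normalization, spectra, PLV and v-tests."""

import numpy as np
import pytest
from scipy import optimize, stats

from huetrack import (
    ObserverModel,
    TimecourseMatrix,
    analyze_alternation,
    build_timecourses,
    design_for,
    fit_halfnormal_sd,
    plv_across_subjects,
    simulate_cohort,
    spectral_phase,
    v_test,
    znormalize_subject,
)
from huetrack.timecourse import DegenerateSubjectError, MissingCellError


class TestHalfNormal:
    def test_constant_sample(self):
        assert fit_halfnormal_sd(np.full(20, 7.5)) == pytest.approx(7.5)

    def test_recovers_folded_normal_scale(self, rng):
        x = np.abs(rng.normal(0, 12.0, 10000))
        assert fit_halfnormal_sd(x) == pytest.approx(12.0, abs=0.5)

    def test_matches_numeric_mle(self, rng):
        """Oracle: direct numeric maximization of the half-normal likelihood."""
        x = np.abs(rng.normal(0, 9.0, 400))
        nll = lambda s: -np.sum(stats.halfnorm.logpdf(x, scale=s))
        opt = optimize.minimize_scalar(nll, bounds=(1.0, 40.0), method="bounded")
        assert fit_halfnormal_sd(x) == pytest.approx(opt.x, abs=1e-4)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_halfnormal_sd([])
        with pytest.raises(ValueError):
            fit_halfnormal_sd([10.0, 200.0])


def _matrix(values, dt=0.2):
    values = np.asarray(values, dtype=float)
    n_soa = values.shape[2]
    return TimecourseMatrix(
        values=values,
        soa_grid=3.0 + dt * np.arange(n_soa),
        subjects=list(range(values.shape[0])),
    )


class TestZNormalize:
    def test_unit_cells(self):
        m = _matrix(np.arange(1.0, 7.0).reshape(1, 1, 6))
        z = znormalize_subject(m)
        assert z.normalized
        assert np.nanmean(z.values[0]) == pytest.approx(0.0)
        assert np.nanstd(z.values[0], ddof=1) == pytest.approx(1.0)

    def test_location_and_scale_invariance(self, rng):
        raw = rng.uniform(5, 25, (1, 3, 6))
        z0 = znormalize_subject(_matrix(raw)).values
        z_shift = znormalize_subject(_matrix(raw + 11.0)).values
        z_scale = znormalize_subject(_matrix(raw * 3.7)).values
        assert np.allclose(z0, z_shift)
        assert np.allclose(z0, z_scale)

    def test_zero_variance_subject_rejected(self):
        with pytest.raises(DegenerateSubjectError):
            znormalize_subject(_matrix(np.full((1, 3, 6), 5.0)))

    def test_double_normalization_rejected(self, rng):
        z = znormalize_subject(_matrix(rng.uniform(5, 25, (1, 3, 6))))
        with pytest.raises(ValueError):
            znormalize_subject(z)


class TestSpectralPhase:
    @pytest.mark.parametrize(
        "dt,expected",
        [(0.2, (0.9375, 1.25)), (0.1, (3.75,)), (0.04, (4.6875,))],
    )
    def test_frequency_axis_contains_reported_bins(self, dt, expected):
        res = spectral_phase(np.zeros(6), np.zeros(6), dt=dt, pad_to=16)
        for f in expected:
            assert np.any(np.isclose(res.freqs, f))

    def test_identical_series_have_zero_phase_difference(self, rng):
        x = rng.normal(0, 1, 6)
        res = spectral_phase(x, x, dt=0.2)
        nonzero = res.amplitude_a > 1e-9
        assert np.allclose(res.phase_diff[nonzero], 0.0, atol=1e-9)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            spectral_phase(np.zeros(6), np.zeros(6), dt=-0.1)
        with pytest.raises(ValueError):
            spectral_phase(np.zeros(20), np.zeros(20), dt=0.1, pad_to=16)


class TestPlv:
    def test_identical_phases(self):
        assert plv_across_subjects(np.full(15, 37.0)) == pytest.approx(1.0)

    def test_equispaced_phases_cancel(self):
        assert plv_across_subjects(np.arange(0, 360, 24.0)) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_trigonometry(self, rng):
        for _ in range(100):
            ph = rng.uniform(-180, 180, 15)
            manual = np.hypot(
                np.mean(np.cos(np.deg2rad(ph))), np.mean(np.sin(np.deg2rad(ph)))
            )
            assert plv_across_subjects(ph) == pytest.approx(manual, abs=1e-12)


class TestVTest:
    def test_maximal_concentration_at_target_direction(self):
        v, u, p, mean = v_test(np.full(15, 180.0), 180.0)
        assert v == pytest.approx(15.0)
        assert p == pytest.approx(stats.norm.sf(15 * np.sqrt(2 / 15)), rel=1e-12)
        assert p < 1e-7

    def test_symmetric_orthogonal_sample_is_null(self):
        angles = np.concatenate([np.full(10, 90.0), np.full(10, -90.0)])
        v, u, p, _ = v_test(angles, 0.0)
        assert v == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(0.5, abs=1e-9)

    def test_matches_brute_force_formula(self, rng):
        for _ in range(100):
            ang = rng.uniform(-180, 180, 15)
            theta0 = rng.uniform(-180, 180)
            rad = np.deg2rad(ang)
            c, s = np.mean(np.cos(rad)), np.mean(np.sin(rad))
            rbar = np.hypot(c, s)
            mean = np.arctan2(s, c)
            v_manual = 15 * rbar * np.cos(mean - np.deg2rad(theta0))
            v, u, p, _ = v_test(ang, theta0)
            assert v == pytest.approx(v_manual, abs=1e-10)
            assert u == pytest.approx(v_manual * np.sqrt(2 / 15), abs=1e-10)

    def test_too_few_angles(self):
        with pytest.raises(ValueError):
            v_test([0.0, 10.0], 0.0)


@pytest.fixture(scope="module")
def pool():
    from huetrack import make_trial_pairs

    return make_trial_pairs(30, rng=8)


class TestBuildTimecourses:
    def test_cell_counts_reproduce_design(self, pool):
        model = ObserverModel(allocation="alternating")
        rec = simulate_cohort(model, design_for("exp3a"), pool, 2, rng=1)
        m = build_timecourses(rec, normalize=False)
        assert m.values.shape == (2, 3, 6)
        i_abs = m.conditions.index("cue_absent")
        assert np.all(m.cell_counts[:, i_abs, :] == 72)
        for cond in ("cued_stream", "uncued_stream"):
            assert np.all(m.cell_counts[:, m.conditions.index(cond), :] == 36)

    def test_missing_cell_is_named(self, pool):
        model = ObserverModel()
        rec = simulate_cohort(model, design_for("exp3a"), pool, 1, rng=2)
        broken = rec[~((rec["cue_present"]) & (rec["soa"] == 3.0))]
        with pytest.raises(MissingCellError, match="cued_stream"):
            build_timecourses(broken)

    def test_antiphase_alternation_recovered_at_one_hertz(self, pool):
        model = ObserverModel(
            sd_high=8.0, sd_low=16.0, allocation="alternating",
            alternation_freq=1.0, cue_resets_phase=True,
        )
        rec = simulate_cohort(model, design_for("exp3a"), pool, 15, rng=3)
        spec = analyze_alternation(build_timecourses(rec))
        assert spec.peak_freq == pytest.approx(0.9375) or spec.peak_freq == pytest.approx(1.25)
        assert spec.v_test_180[2] < 0.05
        assert spec.plv[spec.peak_bin] > 0.5

    def test_fixed_allocation_observer_is_flat(self, pool):
        model = ObserverModel(sd_high=8.0, sd_low=16.0, allocation="fixed")
        rec = simulate_cohort(model, design_for("exp3a"), pool, 15, rng=4)
        spec = analyze_alternation(build_timecourses(rec))
        # no oscillatory structure: phase locking stays far from 1
        assert spec.plv[spec.peak_bin] < 0.7
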