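import numpy as np
import pytest

from quenchfit import (
    QuenchParams,
    SyntheticSpec,
    TitrationSeries,
    aggregate_replicates,
    bootstrap_ci,
    classify_orientation,
    fit_orientation_fraction,
    fit_sv_constant,
    generate_calibration_series,
    generate_orientation_series,
    joint_fit,
    orientation_ratio,
)
from quenchfit.inference import (
    C_IN_PREFERRED,
    JOINT_CONDITION_THRESHOLD,
    N_IN_PREFERRED,
    NO_PREFERENCE,
    CalibrationWarning,
    IdentifiabilityWarning,
)

KQ = 1.0e7


def grid_search_x(series, kq, step=1e-4):
    """Independent brute-force minimiser over x in {0, step, ..., 1}."""
    q, ratio = series.nonzero()
    grid = np.arange(0.0, 1.0 + step / 2, step)
    s = 1.0 + kq * q
    sse = [np.sum((s / (s * x + 1.0 - x) - ratio) ** 2) for x in grid]
    return float(grid[int(np.argmin(sse))])


class TestFitSvConstant:
    def test_noise_free_recovery(self, make_calibration_points):
        res = fit_sv_constant(make_calibration_points(kq=KQ))
        assert res.Kq_hat == pytest.approx(KQ, rel=1e-6)
        assert res.intercept == pytest.approx(1.0, abs=1e-9)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)
        assert res.n_points == 10

    def test_constant_intensity_errors(self):
        pts = [(q, 1000.0) for q in np.linspace(0, 1e-6, 11)]
        with pytest.raises(ValueError, match="no quenching"):
            fit_sv_constant(TitrationSeries("flat", pts))

    def test_too_few_points(self):
        s = TitrationSeries("s", [(0.0, 1000.0), (1e-7, 500.0), (2e-7, 333.0)])
        with pytest.raises(ValueError, match=">= 3"):
            fit_sv_constant(s)

    @pytest.mark.filterwarnings("ignore::quenchfit.inference.CalibrationWarning")
    def test_monte_carlo_mean_within_one_percent(self):
        # multiplicative noise is ~unbiased on the ratio scale at 2% CV
        estimates = []
        for seed in range(500):
            spec = SyntheticSpec(Kq_true=KQ, noise_cv=0.02, seed=seed)
            estimates.append(fit_sv_constant(generate_calibration_series(spec)).Kq_hat)
        assert np.mean(estimates) == pytest.approx(KQ, rel=0.01)

    def test_intercept_warning_on_baseline_drift(self):
        Q = np.linspace(0, 1e-6, 11)
        I = 1000.0 / (1.1 + KQ * Q)  # drifted baseline
        I[0] = 1000.0  # keep I0 at nominal so the intercept misfits
        with pytest.warns(CalibrationWarning):
            fit_sv_constant(TitrationSeries("drift", list(zip(Q.tolist(), I.tolist()))))


class TestFitOrientationFraction:
    @pytest.mark.parametrize("x_true", [0.64, 0.41, 0.52])
    def test_noise_free_recovery(self, make_orientation_series, x_true):
        fit = fit_orientation_fraction(make_orientation_series(x_true), KQ)
        assert fit.x_hat == pytest.approx(x_true, rel=1e-6)
        assert fit.converged and not fit.clipped

    def test_all_protected(self, make_orientation_series):
        series = make_orientation_series(1.0)
        np.testing.assert_allclose(series.ratio, 1.0, rtol=1e-12)
        fit = fit_orientation_fraction(series, KQ)
        assert fit.x_hat == pytest.approx(1.0, abs=1e-6)

    def test_noise_free_sweep_exact(self, make_orientation_series):
        for x_true in np.linspace(0.02, 0.98, 20):
            fit = fit_orientation_fraction(make_orientation_series(float(x_true)), KQ)
            assert fit.x_hat == pytest.approx(x_true, rel=1e-6)

    def test_agrees_with_grid_oracle(self, make_orientation_series):
        for seed in range(20):
            series = make_orientation_series(0.3 + 0.02 * seed, noise_cv=0.02, seed=seed)
            fit = fit_orientation_fraction(series, KQ)
            assert abs(fit.x_hat - grid_search_x(series, KQ)) <= 1e-4

    def test_median_inversion_close_to_fit(self, make_orientation_series):
        from quenchfit.inference import _invert_points

        series = make_orientation_series(0.5, noise_cv=0.02, seed=11)
        fit = fit_orientation_fraction(series, KQ)
        q, ratio = series.nonzero()
        med = float(np.median(_invert_points(KQ, q, ratio)))
        assert abs(med - fit.x_hat) < 0.03

    def test_bias_small_at_two_percent_noise(self):
        # |bias| < 0.01 at Kq*Qmax = 10 over 1000 sims per x
        for x_true in (0.1, 0.4, 0.5, 0.64, 0.9):
            est = []
            for seed in range(1000):
                spec = SyntheticSpec(Kq_true=KQ, x_true=x_true, noise_cv=0.02, seed=seed)
                series = generate_orientation_series(spec)
                est.append(fit_orientation_fraction(series, KQ).x_hat)
            assert abs(np.mean(est) - x_true) < 0.01

    def test_weak_quenching_warns(self):
        spec = SyntheticSpec(Kq_true=KQ, x_true=0.5, Q_max=4e-8)  # Kq*Qmax = 0.4
        series = generate_orientation_series(spec)
        with pytest.warns(IdentifiabilityWarning):
            fit = fit_orientation_fraction(series, KQ)
        assert fit.warnings

    def test_too_few_points(self):
        s = TitrationSeries("s", [(0.0, 1000.0), (1e-7, 600.0), (2e-7, 450.0)])
        with pytest.raises(ValueError, match=">= 3"):
            fit_orientation_fraction(s, KQ)

    def test_ci_brackets_estimate(self, make_orientation_series):
        fit = fit_orientation_fraction(make_orientation_series(0.6, noise_cv=0.02, seed=5), KQ)
        assert 0.0 <= fit.ci_low <= fit.x_hat <= fit.ci_high <= 1.0


class TestBootstrapCI:
    def test_degenerate_on_noise_free(self, make_orientation_series):
        series = make_orientation_series(0.5)
        lo, hi = bootstrap_ci(series, KQ, n_boot=200, seed=1)
        assert hi - lo < 1e-6
        assert lo == pytest.approx(0.5, abs=1e-6)

    def test_deterministic_given_seed(self, make_orientation_series):
        series = make_orientation_series(0.5, noise_cv=0.02, seed=3)
        assert bootstrap_ci(series, KQ, 200, seed=42) == bootstrap_ci(series, KQ, 200, seed=42)

    def test_invariant_to_point_order(self, make_orientation_series):
        series = make_orientation_series(0.5, noise_cv=0.02, seed=3)
        shuffled = TitrationSeries("shuffled", list(reversed(series.points)))
        assert bootstrap_ci(series, KQ, 200, seed=7) == bootstrap_ci(shuffled, KQ, 200, seed=7)

    def test_requires_enough_draws_and_seed(self, make_orientation_series):
        series = make_orientation_series(0.5)
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_ci(series, KQ, n_boot=50, seed=1)
        with pytest.raises(ValueError, match="seed"):
            bootstrap_ci(series, KQ, n_boot=200, seed=None)


class TestJointFit:
    def test_noise_free_recovery(self, make_orientation_series):
        params, cov = joint_fit(make_orientation_series(0.4))  # Kq*Qmax = 10
        assert params.Kq == pytest.approx(KQ, rel=1e-4)
        assert params.x == pytest.approx(0.4, rel=1e-4)

    def test_x_one_unidentifiable(self, make_orientation_series):
        series = make_orientation_series(1.0)
        # flat ratio curve: Kq drops out of the model, covariance must flag it
        with pytest.warns(IdentifiabilityWarning):
            params, cov = joint_fit(series)
        # the likelihood is flat in Kq near x = 1, so only x is pinned loosely
        assert params.x == pytest.approx(1.0, abs=0.01)

    def test_weak_design_prefers_two_stage(self):
        # at Kq*Qmax = 0.2 the joint fit spreads much wider than fixed-Kq
        joint_est, two_stage_est = [], []
        import warnings as _w

        for seed in range(200):
            spec = SyntheticSpec(Kq_true=KQ, x_true=0.5, Q_max=2e-8, noise_cv=0.02, seed=seed)
            series = generate_orientation_series(spec)
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                params, _ = joint_fit(series)
                joint_est.append(params.x)
                two_stage_est.append(fit_orientation_fraction(series, KQ).x_hat)
        assert np.std(joint_est) > np.std(two_stage_est)


class TestAggregateReplicates:
    def _fit(self, x):
        return fit_orientation_fraction(
            generate_orientation_series(SyntheticSpec(Kq_true=KQ, x_true=x)), KQ
        )

    def test_hand_arithmetic(self):
        s = aggregate_replicates([self._fit(x) for x in (0.62, 0.63, 0.65)])
        assert s.x_mean == pytest.approx(0.6333333, abs=1e-6)
        assert s.x_err == pytest.approx(0.0088192, abs=1e-6)
        assert s.n_replicates == 3

    def test_single_replicate(self):
        s = aggregate_replicates([self._fit(0.5)])
        assert s.x_mean == pytest.approx(0.5, rel=1e-6)
        assert s.x_err == 0.0

    def test_identical_replicates(self):
        s = aggregate_replicates([self._fit(0.4)] * 5)
        assert s.x_mean == pytest.approx(0.4, rel=1e-6)
        assert s.x_err == pytest.approx(0.0, abs=1e-12)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            aggregate_replicates([])


class TestClassifyOrientation:
    @staticmethod
    def _summary(mean, err):
        from quenchfit import ReplicateSummary

        return ReplicateSummary(x_mean=mean, x_err=err, n_replicates=3, member_fits=[])

    @pytest.mark.parametrize(
        "mean,err,label",
        [
            (0.63, 0.02, N_IN_PREFERRED),
            (0.40, 0.01, C_IN_PREFERRED),
            (0.53, 0.01, NO_PREFERENCE),
        ],
    )
    def test_reference_calls(self, mean, err, label):
        call = classify_orientation(self._summary(mean, err))
        assert call.label == label
        assert call.margin == pytest.approx(abs(mean - 0.5))

    def test_symmetry(self):
        swap = {N_IN_PREFERRED: C_IN_PREFERRED, C_IN_PREFERRED: N_IN_PREFERRED, NO_PREFERENCE: NO_PREFERENCE}
        for mean in np.linspace(0.0, 1.0, 101):
            if abs(abs(mean - 0.5) - 0.04) < 1e-9:
                continue  # float rounding exactly on the band edge
            a = classify_orientation(self._summary(float(mean), 0.01))
            b = classify_orientation(self._summary(float(1.0 - mean), 0.01))
            assert swap[a.label] == b.label
            assert a.margin == pytest.approx(b.margin)
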