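"""P-I curve model, fitting, and Welch comparison tests."""

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import curve_fit

from kelpcarb import (
    LightCurveModel,
    fit_light_curve,
    jassby_platt,
    saturation_irradiance,
    welch_from_samples,
    welch_from_summary,
)

LIGHT_LEVELS = np.array([0.0, 26.0, 85.8, 156.0, 208.0, 260.0])


class TestJassbyPlatt:
    def test_zero_irradiance_gives_zero(self):
        assert jassby_platt(0.0, 32.44, 0.16) == 0.0

    def test_saturates_at_pmax(self):
        E = 100 * 32.44 / 0.16
        assert jassby_platt(E, 32.44, 0.16) == pytest.approx(32.44, abs=1e-6)

    def test_value_at_saturation_irradiance(self):
        # at E = Ek the argument of tanh is 1 (E=210.97 is Ek to 4 figures)
        assert jassby_platt(210.97, 32.44, 0.1538) == pytest.approx(
            32.44 * np.tanh(1.0), rel=5e-4)
        assert 32.44 * np.tanh(1.0) == pytest.approx(24.71, abs=0.005)

    def test_monotone_nondecreasing(self):
        E = np.linspace(0, 600, 200)
        P = jassby_platt(E, 20.0, 0.1)
        assert np.all(np.diff(P) >= 0)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            jassby_platt(10, -1.0, 0.1)
        with pytest.raises(ValueError):
            jassby_platt(10, 1.0, -0.1)


class _Params:
    def __init__(self, p_max, alpha):
        self.p_max, self.alpha = p_max, alpha


class TestSaturationIrradiance:
    @pytest.mark.parametrize("p_max, alpha, expected", [
        (32.44, 0.1538, 210.9),   # reported ambient/low-flow DO pair
        (1.0, 1.0, 1.0),
        (20.54, 0.1007, 203.98),  # inversion of the reported Pmax and Ek
    ])
    def test_values(self, p_max, alpha, expected):
        assert saturation_irradiance(_Params(p_max, alpha)) == pytest.approx(
            expected, abs=0.06)

    def test_consistent_with_fitted_curve(self):
        fit = fit_light_curve(LIGHT_LEVELS, jassby_platt(LIGHT_LEVELS, 32.44, 0.1538))
        assert saturation_irradiance(fit) == pytest.approx(32.44 / 0.1538, rel=1e-4)

    def test_zero_alpha_undefined(self):
        with pytest.raises(ZeroDivisionError):
            saturation_irradiance(_Params(1.0, 0.0))


class TestLightCurveFit:
    def test_noiseless_exact_recovery(self):
        P = jassby_platt(LIGHT_LEVELS, 32.44, 0.16)
        fit = fit_light_curve(LIGHT_LEVELS, P)
        assert fit.p_max == pytest.approx(32.44, rel=1e-4)
        assert fit.alpha == pytest.approx(0.16, rel=1e-4)
        assert fit.converged
        assert fit.e_k == fit.p_max / fit.alpha

    def test_never_beaten_by_grid_search(self):
        """Brute-force grid over (Pmax, alpha) spanning 0.25-4x the fit never
        undercuts the simplex RSS by more than 1e-6."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            P = jassby_platt(LIGHT_LEVELS, 30.0, 0.15) + rng.normal(0, 2.0, 6)
            fit = fit_light_curve(LIGHT_LEVELS, P)
            pg = np.linspace(0.25 * fit.p_max, 4 * fit.p_max, 200)
            ag = np.linspace(0.25 * fit.alpha, 4 * fit.alpha, 200)
            E, Pobs = LIGHT_LEVELS[1:], P[1:]
            PG, AG = np.meshgrid(pg, ag)
            pred = PG[..., None] * np.tanh(AG[..., None] * E / PG[..., None])
            rss_grid = ((Pobs - pred) ** 2).sum(axis=-1).min()
            assert fit.rss <= rss_grid + 1e-6

    def test_matches_levenberg_marquardt_oracle(self):
        """The simplex least-squares fit lands on the same optimum as an
        independent gradient-based least-squares fit, and the intrinsic
        statistical error of Pmax at 10% noise stays bounded."""
        import warnings

        from scipy.optimize import OptimizeWarning

        rng = np.random.default_rng(42)
        jp = lambda e, p, a: p * np.tanh(a * e / p)
        rel_errors = []
        for _ in range(100):
            P = jassby_platt(LIGHT_LEVELS, 32.44, 0.16) + rng.normal(0, 3.244, 6)
            fit = fit_light_curve(LIGHT_LEVELS, P)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", OptimizeWarning)
                popt, _ = curve_fit(jp, LIGHT_LEVELS[1:], P[1:],
                                    p0=[max(P), 0.1], maxfev=20000)
            lm_rss = float(((P[1:] - jp(LIGHT_LEVELS[1:], *popt)) ** 2).sum())
            if popt[0] <= 50.0 * np.max(np.abs(P)):
                # compare only identified optima: on non-saturating noise
                # draws the unbounded LM fit runs along the Pmax ridge that
                # the simplex fit deliberately caps
                assert fit.rss <= lm_rss + 1e-6
            rel_errors.append(abs(fit.p_max / 32.44 - 1.0))
        assert np.median(rel_errors) <= 0.25

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        P = jassby_platt(LIGHT_LEVELS, 25.0, 0.12) + rng.normal(0, 1.0, 6)
        f1 = fit_light_curve(LIGHT_LEVELS, P)
        f2 = fit_light_curve(LIGHT_LEVELS, 3.0 * P)
        assert f2.p_max == pytest.approx(3.0 * f1.p_max, rel=1e-3)
        assert f2.alpha == pytest.approx(3.0 * f1.alpha, rel=1e-3)

    def test_dark_step_excluded_by_default(self):
        P = jassby_platt(LIGHT_LEVELS, 30.0, 0.15)
        P[0] = -5.0  # dark respiration
        fit = fit_light_curve(LIGHT_LEVELS, P)
        assert fit.n_points == 5
        assert fit.p_max == pytest.approx(30.0, rel=1e-4)

    def test_dark_offset_model_recovers_respiration(self):
        P = jassby_platt(LIGHT_LEVELS, 30.0, 0.15) - 4.0
        fit = fit_light_curve(LIGHT_LEVELS, P, fit_dark_offset=True)
        assert fit.p_max == pytest.approx(30.0, rel=1e-3)
        assert fit.dark_offset == pytest.approx(4.0, rel=1e-3)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            fit_light_curve(LIGHT_LEVELS, np.zeros(6))
        with pytest.raises(ValueError):
            fit_light_curve([0, 10], [0, 1])  # too few levels

    def test_summary_mentions_parameters(self):
        fit = fit_light_curve(LIGHT_LEVELS, jassby_platt(LIGHT_LEVELS, 30.0, 0.15))
        s = fit.summary()
        assert "Pmax" in s and "Ek" in s


class TestWelch:
    def test_reported_do_pmax_row(self):
        """The ambient DO Pmax flow comparison from the treatment summary
        table: means 32.44/20.54, SEs 3.58/1.96, n=5/5."""
        w = welch_from_summary(32.44, 3.58, 5, 20.54, 1.96, 5)
        assert w.t == pytest.approx(-2.91, abs=0.02)
        assert w.df == pytest.approx(6.19, abs=0.05)
        assert w.p_value == pytest.approx(0.026, abs=0.005)

    def test_equal_means_give_t_zero_p_one(self):
        w = welch_from_summary(5.0, 1.0, 4, 5.0, 2.5, 9)
        assert w.t == 0.0
        assert w.p_value == 1.0

    def test_hand_computed_formula(self):
        m1, se1, n1, m2, se2, n2 = 10.0, 2.0, 4, 16.0, 3.0, 6
        v = se1 ** 2 + se2 ** 2
        w = welch_from_summary(m1, se1, n1, m2, se2, n2)
        assert w.t == pytest.approx((m2 - m1) / np.sqrt(v), rel=1e-12)
        assert w.df == pytest.approx(v ** 2 / (se1 ** 4 / 3 + se2 ** 4 / 5), rel=1e-12)

    def test_samples_equal_summary_route(self):
        rng = np.random.default_rng(0)
        x1 = rng.normal(32.44, 8, 5)
        x2 = rng.normal(20.54, 4, 5)
        ws = welch_from_samples(x1, x2)
        wm = welch_from_summary(x1.mean(), x1.std(ddof=1) / np.sqrt(5), 5,
                                x2.mean(), x2.std(ddof=1) / np.sqrt(5), 5)
        assert ws.t == pytest.approx(wm.t, abs=1e-10)
        assert ws.df == pytest.approx(wm.df, abs=1e-10)

    def test_matches_scipy_ttest(self):
        rng = np.random.default_rng(3)
        x1, x2 = rng.normal(0, 1, 7), rng.normal(0.5, 2, 5)
        w = welch_from_samples(x1, x2)
        ref = stats.ttest_ind(x2, x1, equal_var=False)
        assert w.t == pytest.approx(ref.statistic, rel=1e-10)
        assert w.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_identical_samples_t_zero(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert welch_from_samples(x, x).t == 0.0

    def test_zero_variance_both_raises(self):
        with pytest.raises(ValueError):
            welch_from_samples([1.0, 1.0], [1.0, 1.0])

    def test_df_between_welch_bounds(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            n1, n2 = rng.integers(2, 10, 2)
            x1 = rng.normal(0, rng.uniform(0.5, 3), n1)
            x2 = rng.normal(0, rng.uniform(0.5, 3), n2)
            try:
                w = welch_from_samples(x1, x2)
            except ValueError:
                continue
            assert min(n1, n2) - 1 <= w.df + 1e-9
            assert w.df <= n1 + n2 - 2 + 1e-9

    def test_p_uniform_under_null(self):
        """Across 2000 null replicates the Welch p-value is ~Uniform(0,1)."""
        rng = np.random.default_rng(11)
        ps = [welch_from_samples(rng.normal(0, 1, 6), rng.normal(0, 1, 6)).p_value
              for _ in range(2000)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01
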