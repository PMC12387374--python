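"""Tests for the 12-month cosinor fit, phase conventions and significance tests."""

import math

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

from infoseason import (
    amplitude_test,
    fit_cosinor,
    peak_month_from_acrophase,
    predict,
)
from infoseason.exceptions import DegreesOfFreedomError, RankError


def nls_oracle_sse(y, t):
    """Brute-force nonlinear least squares over (M, A, theta).

    Independent of the linearized route: profiles M and A by OLS on a dense
    grid of phases, then polishes the best candidate with Nelder-Mead.
    """
    y = np.asarray(y, float)
    t = np.asarray(t, float)

    def sse_at(params):
        m, a, th = params
        r = y - (m + a * np.sin(2 * np.pi * t / 12 + th))
        return float(r @ r)

    best = None
    for th in np.linspace(0, 2 * np.pi, 241):
        basis = np.column_stack([np.ones_like(t), np.sin(2 * np.pi * t / 12 + th)])
        coef, _, _, _ = np.linalg.lstsq(basis, y, rcond=None)
        cand = (coef[0], coef[1], th)
        if best is None or sse_at(cand) < sse_at(best):
            best = cand
    res = optimize.minimize(sse_at, best, method="Nelder-Mead",
                            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000})
    return float(res.fun)


class TestFit:
    def test_exact_sinusoid_recovered(self):
        t = np.arange(12, dtype=float)
        y = 10 + 5 * np.sin(2 * np.pi * t / 12 + np.pi / 2)
        fit = fit_cosinor(y, t)
        assert fit.mesor == pytest.approx(10, abs=1e-9)
        assert fit.amplitude == pytest.approx(5, abs=1e-9)
        # sin(. + pi/2) peaks at t=0 under the internal argument convention
        assert fit.peak_time == pytest.approx(0, abs=1e-9)
        assert fit.peak_month == 1
        assert fit.sse == 0
        assert fit.perfect_fit

    def test_reported_acrophase_pi_half_means_april(self):
        assert peak_month_from_acrophase(math.pi / 2) == 4
        # and a fit whose peak is in April reports acrophase pi/2
        t = np.arange(12, dtype=float)
        y = 50 + 10 * np.sin(2 * np.pi * (t - 3.0) / 12 + np.pi / 2)
        fit = fit_cosinor(y, t)
        assert fit.peak_time == pytest.approx(3.0, abs=1e-9)
        assert fit.peak_month == 4
        assert fit.acrophase == pytest.approx(math.pi / 2, abs=1e-9)
        assert peak_month_from_acrophase(fit.acrophase) == 4

    def test_matches_nonlinear_least_squares_oracle(self):
        rng = np.random.default_rng(42)
        t = np.arange(12, dtype=float)
        y = 50 + 12 * np.sin(2 * np.pi * t / 12 + 1.1) + rng.normal(0, 3, 12)
        fit = fit_cosinor(y, t)
        assert fit.sse == pytest.approx(nls_oracle_sse(y, t), rel=1e-6)
        # recovered parameters minimize SSE: perturbing any worsens it
        for dm, da, dth in [(0.01, 0, 0), (0, 0.01, 0), (0, 0, 0.01)]:
            m, a, th = fit.mesor + dm, fit.amplitude + da, fit.phase_internal + dth
            r = y - (m + a * np.sin(2 * np.pi * t / 12 + th))
            assert r @ r >= fit.sse

    @pytest.mark.parametrize("n", [8, 12, 24, 132])
    def test_oracle_equivalence_random_instances(self, n):
        rng = np.random.default_rng(n)
        for _ in range(25):
            t = np.arange(n, dtype=float)
            y = (rng.uniform(20, 80)
                 + rng.uniform(0, 25) * np.sin(2 * np.pi * t / 12 + rng.uniform(0, 2 * np.pi))
                 + rng.normal(0, rng.uniform(0.5, 8), n))
            fit = fit_cosinor(y, t)
            assert fit.sse == pytest.approx(nls_oracle_sse(y, t), rel=1e-6, abs=1e-9)

    def test_rank_error_on_degenerate_phases(self):
        # only 2 distinct phases of the annual cycle
        t = np.array([0.0, 6.0, 12.0, 18.0, 24.0, 30.0])
        y = np.array([1.0, 2.0, 1.0, 2.0, 1.0, 2.0])
        with pytest.raises(RankError):
            fit_cosinor(y, t)

    def test_df_error_when_too_few_points(self):
        with pytest.raises(DegreesOfFreedomError):
            fit_cosinor(np.array([1.0, 2.0, 3.0]), np.array([0.0, 1.0, 2.0]))

    def test_amplitude_identity(self):
        rng = np.random.default_rng(1)
        t = np.arange(12, dtype=float)
        y = 50 + 8 * np.sin(2 * np.pi * t / 12 + 0.3) + rng.normal(0, 2, 12)
        fit = fit_cosinor(y, t)
        assert fit.amplitude == pytest.approx(
            math.hypot(fit.beta_sin, fit.beta_cos), abs=1e-12
        )


class TestSignificance:
    def test_perfect_fit_flags_seasonality(self):
        t = np.arange(12, dtype=float)
        y = 10 + 5 * np.sin(2 * np.pi * t / 12)
        fit = fit_cosinor(y, t)
        assert fit.perfect_fit
        assert fit.p_amplitude == 0.0
        assert fit.p_seasonality_F == 0.0
        t_stat, p = amplitude_test(fit)
        assert p == 0.0 and t_stat == math.inf

    def test_f_test_matches_nested_ols_oracle(self):
        rng = np.random.default_rng(3)
        t = np.arange(12, dtype=float)
        y = 50 + 6 * np.sin(2 * np.pi * t / 12 + 0.8) + rng.normal(0, 4, 12)
        fit = fit_cosinor(y, t)
        # independent route: statsmodels OLS of full vs intercept-only model
        X1 = sm.add_constant(
            np.column_stack([np.sin(2 * np.pi * t / 12), np.cos(2 * np.pi * t / 12)])
        )
        full = sm.OLS(y, X1).fit()
        null = sm.OLS(y, np.ones((12, 1))).fit()
        f = ((null.ssr - full.ssr) / 2) / (full.ssr / (12 - 3))
        p = stats.f.sf(f, 2, 9)
        assert fit.p_seasonality_F == pytest.approx(p, abs=1e-10)
        assert fit.f_stat == pytest.approx(f, rel=1e-10)

    def test_null_rejection_rate_is_calibrated(self):
        """Pure iid noise: F test rejects at ~alpha (2000 replicates)."""
        rng = np.random.default_rng(2024)
        t = np.arange(12, dtype=float)
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            y = 50 + rng.normal(0, 5, 12)
            fit = fit_cosinor(y, t)
            rejections += fit.p_seasonality_F < 0.05
        assert 0.035 <= rejections / n_rep <= 0.065

    def test_amplitude_t_anticonservative_vs_f_under_null(self):
        """The delta-method amplitude t test rejects more often than the F test
        at the A=0 boundary, which is why the F test is the default flag."""
        rng = np.random.default_rng(9)
        t = np.arange(12, dtype=float)
        rej_t = rej_f = 0
        for _ in range(500):
            y = 50 + rng.normal(0, 5, 12)
            fit = fit_cosinor(y, t)
            rej_t += fit.p_amplitude < 0.05
            rej_f += fit.p_seasonality_F < 0.05
        assert rej_t > rej_f

    def test_p_monotone_in_planted_amplitude(self):
        rng = np.random.default_rng(17)
        t = np.arange(12, dtype=float)
        noise = rng.normal(0, 5, 12)
        p_prev = None
        for amp in [0.0, 2.0, 5.0, 10.0, 20.0]:
            y = 50 + amp * np.sin(2 * np.pi * t / 12 + 1.0) + noise
            p = fit_cosinor(y, t).p_seasonality_F
            if p_prev is not None:
                assert p <= p_prev + 1e-12
            p_prev = p


class TestPredict:
    def test_peak_and_antiphase_values(self):
        rng = np.random.default_rng(5)
        t = np.arange(12, dtype=float)
        y = 40 + 7 * np.sin(2 * np.pi * t / 12 + 0.6) + rng.normal(0, 2, 12)
        fit = fit_cosinor(y, t)
        assert predict(fit, fit.peak_time) == pytest.approx(fit.mesor + fit.amplitude, abs=1e-9)
        assert predict(fit, fit.peak_time + 6) == pytest.approx(fit.mesor - fit.amplitude, abs=1e-9)
        assert np.mean(predict(fit, np.arange(12))) == pytest.approx(fit.mesor, abs=1e-12)

    def test_peak_time_is_argmax_on_fine_grid(self):
        rng = np.random.default_rng(8)
        t = np.arange(12, dtype=float)
        y = 40 + 9 * np.sin(2 * np.pi * t / 12 + 2.2) + rng.normal(0, 2, 12)
        fit = fit_cosinor(y, t)
        grid = np.linspace(0, 12, 100001)[:-1]
        assert grid[np.argmax(predict(fit, grid))] == pytest.approx(fit.peak_time, abs=1e-3)


class TestEquivariance:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.integers(0, 2**31 - 1),
        st.floats(-40, 40),
        st.floats(0.1, 5),
    )
    def test_shift_and_scale(self, seed, shift, scale):
        rng = np.random.default_rng(seed)
        t = np.arange(12, dtype=float)
        y = 50 + 10 * np.sin(2 * np.pi * t / 12 + 1.3) + rng.normal(0, 3, 12)
        base = fit_cosinor(y, t)
        shifted = fit_cosinor(y + shift, t)
        assert shifted.mesor == pytest.approx(base.mesor + shift, abs=1e-8)
        assert shifted.amplitude == pytest.approx(base.amplitude, abs=1e-8)
        assert shifted.sse == pytest.approx(base.sse, abs=1e-6)
        scaled = fit_cosinor(y * scale, t)
        assert scaled.mesor == pytest.approx(base.mesor * scale, rel=1e-8)
        assert scaled.amplitude == pytest.approx(base.amplitude * scale, rel=1e-8)
        assert math.sqrt(scaled.sse) == pytest.approx(math.sqrt(base.sse) * scale, rel=1e-6)

    @settings(max_examples=24, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 11))
    def test_circular_shift_moves_peak(self, seed, m):
        rng = np.random.default_rng(seed)
        t = np.arange(12, dtype=float)
        y = 50 + 10 * np.sin(2 * np.pi * t / 12 + 0.7) + rng.normal(0, 2, 12)
        base = fit_cosinor(y, t)
        rolled = fit_cosinor(np.roll(y, m), t)
        assert rolled.amplitude == pytest.approx(base.amplitude, abs=1e-9)
        assert (rolled.peak_time - base.peak_time) % 12 == pytest.approx(m, abs=1e-9) or (
            rolled.peak_time - base.peak_time
        ) % 12 == pytest.approx(m - 12, abs=1e-9)
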