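"""Single-harmonic (12-month) cosinor fitting and seasonality inference.

The cosinor model describes a seasonal rhythm as

    y(t) = M + A * sin(2*pi*t/12 + theta)

with mesor M (midline level), amplitude A >= 0 (half the peak-to-trough
swing) and a phase angle locating the peak within the year.  Because the
model is linear in the sine/cosine basis,

    y(t) = M + b1 * sin(2*pi*t/12) + b2 * cos(2*pi*t/12),

it is fitted exactly by ordinary least squares; A = sqrt(b1^2 + b2^2) and
the internal phase is theta = atan2(b2, b1).

Two phase conventions coexist.  The *internal* phase theta is the argument
shift of the regression sinusoid.  The *reported* acrophase phi is anchored
to calendar time: phi = 2*pi*t_peak/12 where t_peak in [0, 12) is the month
(0 = January 1) at which the fitted curve attains its maximum, so phi = pi/2
corresponds to a peak 3 months into the year, i.e. April.  Both are stored
on the fit.

Significance is assessed two ways: a two-tailed t test on the amplitude
(delta-method standard error), and an exact F test of joint nullity of both
harmonic coefficients (2 and n-3 degrees of freedom).  The F test is the
package's default significance flag; the amplitude t test is available as
an alternative (it is anti-conservative near A = 0, where the amplitude's
sampling distribution is folded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import DegreesOfFreedomError, RankError

#: Relative tolerance below which a residual sum of squares counts as zero.
_SSE_RTOL = 1e-10


@dataclass
class CosinorFit:
    """Result of a 12-month cosinor fit.

    ``acrophase`` follows the calendar-anchored convention (phi = pi/2 means
    an April peak); ``phase_internal`` is the raw regression phase theta in
    ``M + A*sin(2*pi*t/12 + theta)``.  ``peak_time`` is continuous months in
    [0, 12) with 0 = January 1; ``peak_month`` = floor(peak_time) + 1 is the
    1-based calendar month, or None when A = 0 leaves the peak undefined.
    """

    mesor: float
    amplitude: float
    acrophase: float
    phase_internal: float
    beta_sin: float
    beta_cos: float
    sse: float
    sst: float
    n: int
    k: int
    amplitude_se: float
    t_stat: float
    p_amplitude: float
    f_stat: float
    p_seasonality_F: float
    peak_time: float | None
    peak_month: int | None
    perfect_fit: bool
    coef_cov: np.ndarray  # 3x3 scaled OLS covariance of (M, b1, b2)

    def significance_p(self, mode: str = "f_test") -> float:
        """p-value under the chosen significance mode.

        ``"f_test"`` — joint F test of both harmonic coefficients (default);
        ``"amplitude_t"`` — two-tailed delta-method t test on the amplitude.
        """
        if mode == "f_test":
            return self.p_seasonality_F
        if mode == "amplitude_t":
            return self.p_amplitude
        raise ValueError(f"unknown significance mode {mode!r}")


def _design(t: np.ndarray, periods: tuple[float, ...]) -> np.ndarray:
    cols = [np.ones_like(t, dtype=float)]
    for period in periods:
        w = 2.0 * math.pi / period
        cols.append(np.sin(w * t))
        cols.append(np.cos(w * t))
    return np.column_stack(cols)


def _ols(y: np.ndarray, X: np.ndarray):
    """Exact OLS with rank check; returns (beta, sse, sst, XtX_inv)."""
    n, k = X.shape
    if np.linalg.matrix_rank(X) < k:
        raise RankError(
            "design matrix is rank deficient: too few distinct phases in t"
        )
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    XtX_inv = np.linalg.inv(X.T @ X)
    return beta, sse, sst, XtX_inv


def peak_time_from_phase(theta: float, period: float = 12.0) -> float:
    """Time in [0, period) at which sin(2*pi*t/period + theta) is maximal."""
    quarter = period / 4.0
    return float((quarter - theta * period / (2.0 * math.pi)) % period)


def acrophase_from_peak_time(peak_time: float, period: float = 12.0) -> float:
    """Calendar-anchored acrophase phi = 2*pi*peak_time/period in [0, 2*pi)."""
    return float((2.0 * math.pi * peak_time / period) % (2.0 * math.pi))


def peak_month_from_acrophase(phi: float) -> int:
    """Map a reported acrophase to its 1-based calendar peak month.

    phi = pi/2 maps to month 4 (April): the peak sits a quarter of the way
    through the 12-month cycle.
    """
    peak_time = (phi % (2.0 * math.pi)) * 12.0 / (2.0 * math.pi)
    return int(math.floor(round(peak_time, 9))) % 12 + 1


def fit_cosinor(y, t) -> CosinorFit:
    """Fit the 12-month cosinor model by exact linearized least squares.

    Parameters
    ----------
    y : array-like
        Observed values (climatology means or raw monthly values).
    t : array-like
        Matching 0-based month indices (January of the origin year = 0).

    The fit records mesor, amplitude, both phase conventions, the peak time
    and month, the residual SSE and the two significance tests (amplitude t,
    joint F).  Raises :class:`RankError` when t covers fewer than 3 distinct
    phases of the 12-month cycle and :class:`DegreesOfFreedomError` when
    n <= 3 leaves no residual degrees of freedom.
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    if y.shape != t.shape or y.ndim != 1:
        raise ValueError("y and t must be matching 1-d sequences")
    if not np.all(np.isfinite(y)):
        raise ValueError("y must be finite")
    n = y.size
    k = 3
    if n <= k:
        raise DegreesOfFreedomError(f"n={n} leaves no residual df for k={k}")

    X = _design(t, (12.0,))
    beta, sse, sst, XtX_inv = _ols(y, X)
    mesor, b1, b2 = (float(b) for b in beta)
    amplitude = math.hypot(b1, b2)
    theta = math.atan2(b2, b1)

    df_resid = n - k
    perfect = sse <= _SSE_RTOL * max(sst, 1.0)
    sigma2 = sse / df_resid
    coef_cov = sigma2 * XtX_inv

    # delta method: A = sqrt(b1^2+b2^2), grad = (b1, b2)/A
    if amplitude > 0 and not perfect:
        grad = np.array([b1, b2]) / amplitude
        var_a = float(grad @ coef_cov[1:, 1:] @ grad)
        amplitude_se = math.sqrt(max(var_a, 0.0))
    else:
        amplitude_se = math.sqrt(float(np.trace(coef_cov[1:, 1:])) / 2.0)
    if perfect:
        t_stat, p_amp = math.inf, 0.0
        f_stat, p_f = math.inf, 0.0
    else:
        t_stat = amplitude / amplitude_se if amplitude_se > 0 else math.inf
        p_amp = float(2.0 * stats.t.sf(abs(t_stat), df_resid))
        sse0 = sst  # intercept-only model
        f_stat = ((sse0 - sse) / 2.0) / (sse / df_resid)
        f_stat = max(f_stat, 0.0)
        p_f = float(stats.f.sf(f_stat, 2, df_resid))

    if amplitude > 0:
        peak_time = peak_time_from_phase(theta)
        acrophase = acrophase_from_peak_time(peak_time)
        # snap to a 1e-9 grid so a peak at an exact month boundary is not
        # pushed into the previous month by floating-point error
        peak_month = int(math.floor(round(peak_time, 9))) % 12 + 1
    else:
        peak_time, acrophase, peak_month = None, float("nan"), None

    return CosinorFit(
        mesor=mesor,
        amplitude=amplitude,
        acrophase=acrophase,
        phase_internal=theta,
        beta_sin=b1,
        beta_cos=b2,
        sse=0.0 if perfect else sse,
        sst=sst,
        n=n,
        k=k,
        amplitude_se=amplitude_se,
        t_stat=t_stat,
        p_amplitude=p_amp,
        f_stat=f_stat,
        p_seasonality_F=p_f,
        peak_time=peak_time,
        peak_month=peak_month,
        perfect_fit=perfect,
        coef_cov=coef_cov,
    )


def amplitude_test(fit: CosinorFit) -> tuple[float, float]:
    """Two-tailed t test for the amplitude (delta-method standard error).

    Returns ``(t_stat, p_amplitude)`` recomputed from the stored coefficients
    and covariance.  A zero-residual fit reports (inf, 0.0): the rhythm is
    deterministic in the data.
    """
    if fit.n - fit.k < 1:
        raise DegreesOfFreedomError("no residual degrees of freedom")
    if fit.perfect_fit:
        return math.inf, 0.0
    a = fit.amplitude
    if a == 0:
        return 0.0, 1.0
    grad = np.array([fit.beta_sin, fit.beta_cos]) / a
    se = math.sqrt(max(float(grad @ fit.coef_cov[1:, 1:] @ grad), 0.0))
    t_stat = a / se if se > 0 else math.inf
    p = float(2.0 * stats.t.sf(abs(t_stat), fit.n - fit.k))
    return t_stat, p


def predict(fit: CosinorFit, t) -> np.ndarray | float:
    """Evaluate the fitted curve M + A*sin(2*pi*t/12 + theta) at t (months)."""
    t_arr = np.asarray(t, dtype=float)
    out = fit.mesor + fit.amplitude * np.sin(
        2.0 * math.pi * t_arr / 12.0 + fit.phase_internal
    )
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out
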