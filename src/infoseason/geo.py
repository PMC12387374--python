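"""Latitude-amplitude gradient analysis.

Seasonal forcing strengthens away from the equator, so if search interest
tracks a climate-driven disease rhythm its fitted seasonal amplitude should
grow with |latitude|.  This module quantifies that relation across locations
three ways on the same scatter: an OLS slope of amplitude on latitude with a
t-based 95% CI, the Pearson correlation (t test, Fisher-z CI), and the
Spearman rank correlation (t approximation, Fisher-z CI with variance
1.06/(n-3)), the last being sensitive to monotone but nonlinear gradients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import DomainError, RankError


@dataclass
class GeoGradientResult:
    n_points: int
    slope: float
    intercept: float
    slope_ci_95: tuple[float, float]
    r_squared: float
    p_linear: float
    pearson_r: float
    pearson_p: float
    pearson_ci_95: tuple[float, float]
    spearman_rho: float
    spearman_p: float
    spearman_ci_95: tuple[float, float]

    def to_dict(self) -> dict:
        d = {
            "n_points": self.n_points,
            "slope": self.slope,
            "intercept": self.intercept,
            "slope_ci_low": self.slope_ci_95[0],
            "slope_ci_high": self.slope_ci_95[1],
            "r_squared": self.r_squared,
            "p_linear": self.p_linear,
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
            "pearson_ci_low": self.pearson_ci_95[0],
            "pearson_ci_high": self.pearson_ci_95[1],
            "spearman_rho": self.spearman_rho,
            "spearman_p": self.spearman_p,
            "spearman_ci_low": self.spearman_ci_95[0],
            "spearman_ci_high": self.spearman_ci_95[1],
        }
        return d


def _fisher_ci(r: float, n: int, var_scale: float = 1.0) -> tuple[float, float]:
    """95% CI for a correlation via the Fisher z transform.

    ``var_scale`` = 1 for Pearson, 1.06 for Spearman (the standard variance
    inflation of the rank correlation's z transform).
    """
    if n <= 3 or abs(r) >= 1.0:
        return (r, r)
    z = math.atanh(r)
    se = math.sqrt(var_scale / (n - 3))
    lo, hi = z - 1.959963984540054 * se, z + 1.959963984540054 * se
    return (math.tanh(lo), math.tanh(hi))


def fit_latitude_gradient(latitudes, amplitudes) -> GeoGradientResult:
    """Relate seasonal amplitude to latitude across locations.

    Requires at least 4 points with non-constant latitude.  Returns the OLS
    slope (amplitude units per degree) with its 95% CI, R-squared, and both
    Pearson and Spearman correlations with p-values and Fisher-z CIs.
    """
    lat = np.asarray(latitudes, dtype=float)
    amp = np.asarray(amplitudes, dtype=float)
    if lat.shape != amp.shape or lat.ndim != 1:
        raise ValueError("latitudes and amplitudes must match in length")
    n = lat.size
    if n < 4:
        raise DomainError(f"need at least 4 points, got {n}")
    if np.ptp(lat) == 0:
        raise RankError("latitude is constant: gradient undefined")

    reg = stats.linregress(lat, amp)
    t_crit = stats.t.ppf(0.975, n - 2)
    slope_ci = (reg.slope - t_crit * reg.stderr, reg.slope + t_crit * reg.stderr)

    pear = stats.pearsonr(lat, amp)
    spear = stats.spearmanr(lat, amp)

    r = float(pear.statistic)
    rho = float(spear.statistic)
    return GeoGradientResult(
        n_points=n,
        slope=float(reg.slope),
        intercept=float(reg.intercept),
        slope_ci_95=(float(slope_ci[0]), float(slope_ci[1])),
        r_squared=r * r,
        p_linear=float(reg.pvalue),
        pearson_r=r,
        pearson_p=float(pear.pvalue),
        pearson_ci_95=_fisher_ci(r, n, 1.0),
        spearman_rho=rho,
        spearman_p=float(spear.pvalue),
        spearman_ci_95=_fisher_ci(rho, n, 1.06),
    )
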