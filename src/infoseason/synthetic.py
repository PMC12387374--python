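"""Seeded generator of Google-Trends-like monthly search-interest panels.

Every downstream stage is testable without live downloads because this
module emits series with the statistical structure the analysis assumes: a
12-month sinusoid (optionally plus a 6-month harmonic for bimodal terms), a
linear drift, AR(1) Gaussian noise, hemisphere-opposed peak timing and a
latitude-graded amplitude, followed by the export's max-anchored 0-100
rescaling and integer rounding.  Peak months are given in calendar terms; a
series peaking "in April" peaks at month index t = 3, i.e. at reported
acrophase pi/2.

The latent process is

    x_t = mesor + A12*sin(2*pi*t/12 + phase(peak12))
                + amp6*sin(2*pi*t/6 + phase(peak6))
                + trend_per_month * t + eps_t

with A12 = amp12 + amp_lat_slope*|latitude| and AR(1) innovations of scale
``noise_sd``.  Southern-hemisphere locations have their annual peak shifted
by 6 months.

Default parameter choices emulate the analyzed data: 11 years of monthly
observations starting 2014-01, a mesor of 50 on the 0-100 scale, an annual
amplitude of 20 (a clear but not extreme rhythm), innovation sd 5, April
peak, rescaling and rounding on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import DomainError
from .trends import Group, Hemisphere, LocationMeta, MonthlySeries


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic monthly search-interest series."""

    years: int = 11
    start: str = "2014-01"
    mesor: float = 50.0
    amp12: float = 20.0
    peak_month_12: int = 4  # calendar month of the annual peak (April)
    amp6: float = 0.0
    peak_month_6: int = 1
    trend_per_month: float = 0.0
    noise_sd: float = 5.0
    ar1: float = 0.0
    hemisphere: Hemisphere = Hemisphere.north
    latitude: float = 40.0
    amp_lat_slope: float = 0.0
    rescale_0_100: bool = True
    integer_round: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.hemisphere = Hemisphere(self.hemisphere)
        if self.years < 2:
            raise DomainError("need at least 2 years of monthly data")
        if self.amp12 < 0 or self.amp6 < 0 or self.noise_sd < 0:
            raise DomainError("amplitudes and noise_sd must be non-negative")
        if not 0 <= self.ar1 < 1:
            raise DomainError("ar1 must lie in [0, 1)")
        if not -90 <= self.latitude <= 90:
            raise DomainError("latitude outside [-90, 90]")


def _phase_for_peak(peak_month: int, period: float) -> float:
    """Internal phase theta so that sin(2*pi*t/period + theta) peaks at the month.

    ``peak_month`` is 1-based; the peak is placed at t = peak_month - 1 (the
    sampled time point of that calendar month), so an April annual peak sits
    at t = 3 — exactly the acrophase-pi/2 convention of the cosinor fit.
    """
    peak_time = (peak_month - 1.0) % period
    # sin peaks where 2*pi*t/period + theta = pi/2
    return math.pi / 2.0 - 2.0 * math.pi * peak_time / period


def _ar1_noise(rng: np.random.Generator, n: int, sd: float, ar1: float) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    if ar1 == 0:
        return rng.normal(0.0, sd, size=n)
    eps = np.empty(n)
    # stationary initial condition
    eps[0] = rng.normal(0.0, sd / math.sqrt(1.0 - ar1 * ar1))
    innov = rng.normal(0.0, sd, size=n - 1)
    for i in range(1, n):
        eps[i] = ar1 * eps[i - 1] + innov[i - 1]
    return eps


def generate_series(
    spec: SyntheticSpec,
    location_id: str = "synthetic",
    group: Group | str = Group.symptoms,
) -> MonthlySeries:
    """Generate one seeded synthetic monthly series.

    Deterministic for a fixed ``spec.seed``.  With ``rescale_0_100`` the
    latent series is scaled so its maximum is exactly 100 (the export's
    max-anchored normalization) and clipped at 0; with ``integer_round``
    values are rounded half-up to integers.  Rescaling a constant latent
    series raises :class:`DomainError`.
    """
    n = spec.years * 12
    t = np.arange(n, dtype=float)
    rng = np.random.default_rng(spec.seed)

    peak12 = spec.peak_month_12
    if spec.hemisphere is Hemisphere.south:
        peak12 = (peak12 - 1 + 6) % 12 + 1
    a12 = spec.amp12 + spec.amp_lat_slope * abs(spec.latitude)

    x = (
        spec.mesor
        + a12 * np.sin(2 * math.pi * t / 12.0 + _phase_for_peak(peak12, 12.0))
        + spec.amp6 * np.sin(2 * math.pi * t / 6.0 + _phase_for_peak(spec.peak_month_6, 6.0))
        + spec.trend_per_month * t
        + _ar1_noise(rng, n, spec.noise_sd, spec.ar1)
    )

    if spec.rescale_0_100:
        if np.ptp(x) == 0:
            raise DomainError("cannot rescale a constant latent series to 0-100")
        peak = x.max()
        if peak <= 0:
            raise DomainError("latent series non-positive: max-anchored rescale undefined")
        x = np.clip(100.0 * x / peak, 0.0, 100.0)
    if spec.integer_round:
        x = np.floor(x + 0.5)  # round half-up, like the exports
    x = np.clip(x, 0.0, 100.0)

    return MonthlySeries(
        location_id=location_id,
        group=Group(group),
        start=pd.Period(spec.start, freq="M"),
        values=x,
    )


def generate_panel(
    n_locations: int,
    template: SyntheticSpec,
    latitude_range: tuple[float, float] = (25.0, 49.0),
    frac_null: float = 0.0,
    seed: int = 0,
    group: Group | str = Group.na_cities,
    id_prefix: str = "loc",
) -> tuple[list[MonthlySeries], list[LocationMeta]]:
    """Generate a panel of locations sharing a template spec.

    Latitudes are drawn uniformly in ``latitude_range``; a fraction
    ``frac_null`` of locations (rounded, chosen at random) carry no seasonal
    signal at all (amp12 = amp6 = 0).  Hemisphere follows the sign of each
    drawn latitude.  Per-location seeds are derived deterministically from
    ``seed``, so the panel is reproducible as a whole.
    """
    if n_locations < 1:
        raise DomainError("n_locations must be >= 1")
    if not 0.0 <= frac_null <= 1.0:
        raise DomainError("frac_null must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_locations) & 0x7FFFFFFF
    lats = rng.uniform(latitude_range[0], latitude_range[1], size=n_locations)
    n_null = int(round(frac_null * n_locations))
    null_idx = set(rng.choice(n_locations, size=n_null, replace=False).tolist())

    series_list: list[MonthlySeries] = []
    metas: list[LocationMeta] = []
    width = max(3, len(str(n_locations - 1)))
    for i in range(n_locations):
        lat = float(lats[i])
        hemi = Hemisphere.south if lat < 0 else Hemisphere.north
        spec_i = replace(
            template,
            latitude=lat,
            hemisphere=hemi,
            seed=int(child_seeds[i]),
        )
        if i in null_idx:
            spec_i = replace(spec_i, amp12=0.0, amp6=0.0, amp_lat_slope=0.0)
        loc_id = f"{id_prefix}{i:0{width}d}"
        series_list.append(generate_series(spec_i, location_id=loc_id, group=group))
        metas.append(
            LocationMeta(
                location_id=loc_id,
                latitude=lat,
                hemisphere=hemi,
                display_name=loc_id,
            )
        )
    return series_list, metas
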