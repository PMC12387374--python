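"""Parsing and shaping of Google-Trends-style monthly search-interest series.

Google Trends "multiTimeline" exports are CSV files with a short header
block, a ``Month,<query>`` column row and one row per calendar month holding
a relative search volume on a 0-100 scale (100 marks the series' own
maximum; months with too little traffic are exported as the literal
``"<1"``).  This module parses that dialect into a validated
:class:`MonthlySeries`, computes per-calendar-month climatologies (the
"averaged monthly data" the seasonal fits operate on) and round-trips series
to a canonical long-format table.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .exceptions import DomainError, FormatError, GapError, SeriesLengthError

#: Value substituted for censored ("<1") export entries: the midpoint of the
#: censoring interval (0, 1).  Configurable per call in parse_trends_csv.
CENSORED_VALUE = 0.5

#: Minimum number of months a series must span before it may be fitted.
MIN_MONTHS = 24


class Group(str, Enum):
    """The five predefined subgroups search-interest units belong to."""

    countries_english = "countries_english"
    countries_language = "countries_language"
    us_states = "us_states"
    na_cities = "na_cities"
    symptoms = "symptoms"


class Hemisphere(str, Enum):
    north = "north"
    south = "south"


def month_index(year_month: str | pd.Period, origin: str | pd.Period) -> int:
    """Months elapsed since ``origin`` (0-based).

    ``month_index("2014-04", "2014-01") == 3``.  Raises :class:`DomainError`
    when ``year_month`` precedes the origin.
    """
    ym = pd.Period(year_month, freq="M")
    og = pd.Period(origin, freq="M")
    t = (ym - og).n
    if t < 0:
        raise DomainError(f"{ym} precedes origin {og}")
    return int(t)


@dataclass
class MonthlySeries:
    """One location's ordered monthly relative-search-volume series.

    ``values`` live on the dimensionless 0-100 Trends scale; ``censored_mask``
    flags months that the export reported as ``"<1"``.
    """

    location_id: str
    group: Group
    start: pd.Period  # first calendar month, freq "M"
    values: np.ndarray
    censored_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.group = Group(self.group)
        self.start = pd.Period(self.start, freq="M")
        self.values = np.asarray(self.values, dtype=float)
        if self.censored_mask is None:
            self.censored_mask = np.zeros(self.values.shape, dtype=bool)
        self.censored_mask = np.asarray(self.censored_mask, dtype=bool)
        if self.values.ndim != 1 or self.values.size == 0:
            raise FormatError("values must be a non-empty 1-d sequence")
        if self.censored_mask.shape != self.values.shape:
            raise FormatError("censored_mask must match values in length")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("values must be finite")
        if self.values.min() < 0 or self.values.max() > 100:
            raise FormatError("values must lie within [0, 100]")

    def __len__(self) -> int:
        return self.values.size

    @property
    def periods(self) -> pd.PeriodIndex:
        return pd.period_range(self.start, periods=len(self), freq="M")

    @property
    def calendar_months(self) -> np.ndarray:
        """Calendar month (1..12) of every observation."""
        return self.periods.month.to_numpy()

    @property
    def t(self) -> np.ndarray:
        """0-based month index of every observation (t=0 at ``start``)."""
        return np.arange(len(self))

    def to_frame(self) -> pd.DataFrame:
        """Canonical long format: location_id, group, year_month, value, censored."""
        return pd.DataFrame(
            {
                "location_id": self.location_id,
                "group": self.group.value,
                "year_month": self.periods.strftime("%Y-%m"),
                "value": self.values,
                "censored": self.censored_mask,
            }
        )


@dataclass
class LocationMeta:
    """Geographic metadata used by the latitude-gradient analysis."""

    location_id: str
    latitude: float
    hemisphere: Hemisphere
    display_name: str = ""

    def __post_init__(self) -> None:
        self.hemisphere = Hemisphere(self.hemisphere)
        if not np.isfinite(self.latitude) or not -90 <= self.latitude <= 90:
            raise DomainError(f"latitude {self.latitude} outside [-90, 90]")
        if self.latitude > 0 and self.hemisphere is Hemisphere.south:
            raise DomainError("positive latitude labelled southern hemisphere")
        if self.latitude < 0 and self.hemisphere is Hemisphere.north:
            raise DomainError("negative latitude labelled northern hemisphere")


@dataclass
class Climatology:
    """Calendar-month means of a multi-year series (January..December)."""

    location_id: str
    monthly_mean: np.ndarray  # 12 values, 0-100 scale
    monthly_n: np.ndarray  # contributing years per month
    monthly_ci_halfwidth: np.ndarray  # 1.96 * sd / sqrt(n), 0 when n < 2

    def __post_init__(self) -> None:
        self.monthly_mean = np.asarray(self.monthly_mean, dtype=float)
        self.monthly_n = np.asarray(self.monthly_n, dtype=int)
        self.monthly_ci_halfwidth = np.asarray(self.monthly_ci_halfwidth, dtype=float)
        for arr in (self.monthly_mean, self.monthly_n, self.monthly_ci_halfwidth):
            if arr.shape != (12,):
                raise FormatError("climatology arrays must have exactly 12 entries")
        if (self.monthly_n < 1).any():
            raise FormatError("every calendar month needs at least one observation")

    @property
    def t(self) -> np.ndarray:
        """Month indices 0..11 (January = 0) matching ``monthly_mean``."""
        return np.arange(12)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "location_id": self.location_id,
                "month": np.arange(1, 13),
                "mean": self.monthly_mean,
                "n": self.monthly_n,
                "ci_halfwidth": self.monthly_ci_halfwidth,
            }
        )


# ---------------------------------------------------------------------------
# multiTimeline parsing / serialization


def parse_trends_csv(
    text: str,
    location_id: str,
    group: Group | str,
    censored_value: float = CENSORED_VALUE,
) -> MonthlySeries:
    """Parse a multiTimeline CSV export into a :class:`MonthlySeries`.

    The export has a 2-3 line header block (category line, blank line) before
    a ``Month,...`` column row; data rows are ``YYYY-MM,<value>`` with integer
    values 0-100 or the literal ``"<1"``, which is mapped to
    ``censored_value`` and flagged in the censored mask.

    Raises :class:`GapError` for missing or duplicated months (naming the
    month), :class:`FormatError` for out-of-range or non-numeric values, and
    :class:`SeriesLengthError` for series shorter than 24 months.
    """
    lines = [ln.strip() for ln in text.splitlines()]
    try:
        start_idx = next(
            i for i, ln in enumerate(lines) if ln.lower().startswith("month,")
        )
    except StopIteration:
        raise FormatError("no 'Month,...' column row found in export") from None

    periods: list[pd.Period] = []
    values: list[float] = []
    censored: list[bool] = []
    for ln in lines[start_idx + 1 :]:
        if not ln:
            continue
        parts = ln.split(",")
        if len(parts) != 2:
            raise FormatError(f"expected 'YYYY-MM,<value>' row, got {ln!r}")
        raw_month, raw_value = parts[0].strip(), parts[1].strip()
        try:
            period = pd.Period(raw_month, freq="M")
        except Exception:
            raise FormatError(f"unparseable month {raw_month!r}") from None
        if raw_value == "<1":
            value, is_censored = float(censored_value), True
        else:
            try:
                value = float(raw_value)
            except ValueError:
                raise FormatError(
                    f"non-numeric value {raw_value!r} at {raw_month}"
                ) from None
            if not 0 <= value <= 100:
                raise FormatError(f"value {value} at {raw_month} outside [0, 100]")
            is_censored = False
        periods.append(period)
        values.append(value)
        censored.append(is_censored)

    if len(periods) < MIN_MONTHS:
        raise SeriesLengthError(
            f"series has {len(periods)} months; at least {MIN_MONTHS} required"
        )

    expected = pd.period_range(periods[0], periods=len(periods), freq="M")
    for got, want in zip(periods, expected):
        if got != want:
            if got > want:
                raise GapError(f"missing month {want}")
            raise GapError(f"duplicated or out-of-order month {got}")

    return MonthlySeries(
        location_id=location_id,
        group=Group(group),
        start=periods[0],
        values=np.array(values),
        censored_mask=np.array(censored),
    )


def serialize_trends_csv(series: MonthlySeries, query: str = "query") -> str:
    """Emit the multiTimeline dialect that :func:`parse_trends_csv` accepts.

    Censored months are written back as ``"<1"``; integral values are written
    without a decimal point, matching real exports.
    """
    out = _io.StringIO()
    out.write("Category: All categories\n\n")
    out.write(f"Month,{query}: ({series.location_id})\n")
    for period, value, cens in zip(series.periods, series.values, series.censored_mask):
        if cens:
            cell = "<1"
        elif float(value).is_integer():
            cell = str(int(value))
        else:
            cell = repr(float(value))
        out.write(f"{period.strftime('%Y-%m')},{cell}\n")
    return out.getvalue()


def read_location_meta(text: str) -> list[LocationMeta]:
    """Read a metadata CSV with columns location_id, group, latitude, display_name.

    Hemisphere is derived from the sign of latitude (0 counts as northern).
    """
    df = pd.read_csv(_io.StringIO(text))
    required = {"location_id", "latitude"}
    if not required <= set(df.columns):
        raise FormatError(f"metadata CSV must contain columns {sorted(required)}")
    metas = []
    for _, row in df.iterrows():
        lat = float(row["latitude"])
        metas.append(
            LocationMeta(
                location_id=str(row["location_id"]),
                latitude=lat,
                hemisphere=Hemisphere.south if lat < 0 else Hemisphere.north,
                display_name=str(row.get("display_name", "")),
            )
        )
    return metas


def location_meta_frame(metas: list[LocationMeta]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "location_id": [m.location_id for m in metas],
            "latitude": [m.latitude for m in metas],
            "hemisphere": [m.hemisphere.value for m in metas],
            "display_name": [m.display_name for m in metas],
        }
    )


# ---------------------------------------------------------------------------
# climatology


def monthly_climatology(series: MonthlySeries) -> Climatology:
    """Average a multi-year series by calendar month.

    Returns the 12 calendar-month means (January..December), the number of
    contributing years per month and a normal-approximation 95% CI halfwidth
    (1.96 * sd / sqrt(n); 0 when fewer than two years contribute).
    """
    if len(series) < MIN_MONTHS:
        raise SeriesLengthError(
            f"series has {len(series)} months; at least {MIN_MONTHS} required"
        )
    df = pd.DataFrame({"month": series.calendar_months, "value": series.values})
    grouped = df.groupby("month")["value"]
    mean = grouped.mean().reindex(range(1, 13))
    n = grouped.size().reindex(range(1, 13), fill_value=0)
    sd = grouped.std(ddof=1).reindex(range(1, 13))
    halfwidth = np.where(
        n.to_numpy() >= 2, 1.96 * sd.to_numpy() / np.sqrt(n.to_numpy()), 0.0
    )
    return Climatology(
        location_id=series.location_id,
        monthly_mean=mean.to_numpy(),
        monthly_n=n.to_numpy(),
        monthly_ci_halfwidth=halfwidth,
    )


def long_frame(series_list: list[MonthlySeries]) -> pd.DataFrame:
    """Concatenate series into one canonical long-format table."""
    return pd.concat([s.to_frame() for s in series_list], ignore_index=True)


def climatology_frame(climatologies: list[Climatology]) -> pd.DataFrame:
    return pd.concat([c.to_frame() for c in climatologies], ignore_index=True)
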