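"""Tests for multiTimeline parsing, validation and climatology computation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from infoseason import (
    Group,
    MonthlySeries,
    month_index,
    monthly_climatology,
    parse_trends_csv,
    serialize_trends_csv,
)
from infoseason.exceptions import (
    DomainError,
    FormatError,
    GapError,
    SeriesLengthError,
)
from infoseason.trends import LocationMeta, read_location_meta


class TestParse:
    def test_well_formed_export_round_trips(self, export_text):
        text, values, months = export_text
        s = parse_trends_csv(text, "US", Group.countries_english)
        assert len(s) == 132
        assert str(s.start) == "2014-01"
        np.testing.assert_array_equal(s.values, values)
        assert not s.censored_mask.any()
        # serialize -> parse reproduces the value sequence exactly
        s2 = parse_trends_csv(serialize_trends_csv(s), "US", Group.countries_english)
        np.testing.assert_array_equal(s2.values, s.values)
        np.testing.assert_array_equal(s2.censored_mask, s.censored_mask)

    def test_censored_entry_maps_to_half_and_is_flagged(self, export_text):
        text, _, _ = export_text
        lines = [
            ("2019-06,<1" if ln.startswith("2019-06,") else ln)
            for ln in text.splitlines()
        ]
        s = parse_trends_csv("\n".join(lines), "US", "countries_english")
        idx = list(s.periods.strftime("%Y-%m")).index("2019-06")
        assert s.values[idx] == 0.5
        assert s.censored_mask[idx]
        assert s.censored_mask.sum() == 1
        # configurable censoring constant
        s0 = parse_trends_csv("\n".join(lines), "US", "countries_english", censored_value=0.0)
        assert s0.values[idx] == 0.0

    def test_missing_month_is_gap_error_naming_the_month(self, export_text):
        text, _, _ = export_text
        lines = [ln for ln in text.splitlines() if not ln.startswith("2019-06,")]
        with pytest.raises(GapError, match="2019-06"):
            parse_trends_csv("\n".join(lines), "US", "countries_english")

    def test_duplicated_month_is_gap_error(self, export_text):
        text, _, _ = export_text
        lines = text.splitlines()
        i = next(j for j, ln in enumerate(lines) if ln.startswith("2019-06,"))
        lines.insert(i, lines[i])
        with pytest.raises(GapError):
            parse_trends_csv("\n".join(lines), "US", "countries_english")

    @pytest.mark.parametrize(
        "bad_value", ["101", "-3", "abc", "<2"],
    )
    def test_out_of_range_or_non_numeric_value_rejected(self, export_text, bad_value):
        text, _, _ = export_text
        lines = [
            (f"2019-06,{bad_value}" if ln.startswith("2019-06,") else ln)
            for ln in text.splitlines()
        ]
        with pytest.raises(FormatError):
            parse_trends_csv("\n".join(lines), "US", "countries_english")

    def test_short_series_rejected(self):
        lines = ["Month,q"] + [f"2014-{m:02d},{m}" for m in range(1, 13)]
        with pytest.raises(SeriesLengthError):
            parse_trends_csv("\n".join(lines), "x", "symptoms")


class TestMonthIndex:
    @pytest.mark.parametrize(
        "ym,origin,expected",
        [("2014-01", "2014-01", 0), ("2014-04", "2014-01", 3), ("2024-12", "2014-01", 131)],
    )
    def test_elapsed_months(self, ym, origin, expected):
        assert month_index(ym, origin) == expected

    def test_before_origin_rejected(self):
        with pytest.raises(DomainError):
            month_index("2013-12", "2014-01")


class TestClimatology:
    def test_constant_series(self):
        s = MonthlySeries("c", Group.symptoms, "2014-01", np.full(120, 50.0))
        clim = monthly_climatology(s)
        np.testing.assert_allclose(clim.monthly_mean, 50.0)
        np.testing.assert_allclose(clim.monthly_ci_halfwidth, 0.0)
        np.testing.assert_array_equal(clim.monthly_n, 10)

    def test_month_identity_series(self):
        values = np.tile(np.arange(1, 13, dtype=float), 10)
        s = MonthlySeries("c", Group.symptoms, "2014-01", values)
        clim = monthly_climatology(s)
        np.testing.assert_allclose(clim.monthly_mean, np.arange(1, 13))
        np.testing.assert_array_equal(clim.monthly_n, 10)

    def test_matches_groupby_oracle_on_synthetic_series(self):
        from infoseason import SyntheticSpec, generate_series

        s = generate_series(SyntheticSpec(seed=11))
        clim = monthly_climatology(s)
        # independent oracle: plain dict-of-lists accumulation
        buckets = {m: [] for m in range(1, 13)}
        for month, v in zip(s.calendar_months, s.values):
            buckets[month].append(v)
        expected = np.array([np.mean(buckets[m]) for m in range(1, 13)])
        np.testing.assert_allclose(clim.monthly_mean, expected, atol=1e-12)
        sd = np.array([np.std(buckets[m], ddof=1) for m in range(1, 13)])
        n = np.array([len(buckets[m]) for m in range(1, 13)])
        np.testing.assert_allclose(
            clim.monthly_ci_halfwidth, 1.96 * sd / np.sqrt(n), atol=1e-12
        )

    def test_periodic_series_climatology_equals_one_period(self):
        period = np.array([30, 35, 48, 70, 90, 85, 60, 44, 33, 28, 25, 27], dtype=float)
        s = MonthlySeries("p", Group.symptoms, "2014-01", np.tile(period, 11))
        np.testing.assert_allclose(monthly_climatology(s).monthly_mean, period)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 6))
    def test_year_shuffle_invariance(self, seed, years):
        """Monthly means do not depend on the order of the years."""
        rng = np.random.default_rng(seed)
        values = rng.uniform(0, 100, size=years * 12)
        s = MonthlySeries("a", Group.symptoms, "2014-01", values)
        blocks = values.reshape(years, 12)[rng.permutation(years)]
        s_shuffled = MonthlySeries("a", Group.symptoms, "2014-01", blocks.ravel())
        np.testing.assert_allclose(
            monthly_climatology(s).monthly_mean,
            monthly_climatology(s_shuffled).monthly_mean,
            atol=1e-12,
        )

    def test_short_series_rejected(self):
        s = MonthlySeries("c", Group.symptoms, "2014-01", np.full(23, 50.0))
        with pytest.raises(SeriesLengthError):
            monthly_climatology(s)


class TestMeta:
    def test_hemisphere_must_match_latitude_sign(self):
        with pytest.raises(DomainError):
            LocationMeta("x", latitude=40.0, hemisphere="south")
        with pytest.raises(DomainError):
            LocationMeta("x", latitude=-12.0, hemisphere="north")

    def test_read_metadata_csv_derives_hemisphere(self):
        text = "location_id,group,latitude,display_name\nsyd,na_cities,-33.9,Sydney\nnyc,na_cities,40.7,New York\n"
        metas = read_location_meta(text)
        assert [m.hemisphere.value for m in metas] == ["south", "north"]

    def test_series_values_validated(self):
        with pytest.raises(FormatError):
            MonthlySeries("x", Group.symptoms, "2014-01", np.array([1.0, 101.0]))

    def test_long_frame_round_trip(self, export_text):
        text, _, _ = export_text
        s = parse_trends_csv(text, "US", "countries_english")
        df = s.to_frame()
        assert list(df.columns) == ["location_id", "group", "year_month", "value", "censored"]
        assert len(df) == 132
        assert (df["group"] == "countries_english").all()
        pd.testing.assert_series_equal(
            df["value"], pd.Series(s.values, name="value"), check_index=False
        )
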