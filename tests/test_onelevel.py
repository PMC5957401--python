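import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mldendro.hierdata import HierSeries, RadiusVector, parse_long_growth
from mldendro.onelevel import amod, move_yr, recursive_eval, rtimes, scacum


def series_from(rows):
    return parse_long_growth(pd.DataFrame(rows, columns=["x", "year", "sample", "tree", "plot"]))


def two_core_tree(years_a, years_b):
    rows = [(1.0, y, "a", "1", "P1") for y in years_a]
    rows += [(1.0, y, "b", "1", "P1") for y in years_b]
    return series_from(rows)


class TestRtimes:
    def test_overlap_filter_keeps_shared_times(self):
        hs = two_core_tree(range(1990, 1995), range(1992, 1995))
        out = rtimes(hs, lv="tree", only_dup=True)
        assert len(out) == 6
        assert sorted(out.data["time"].unique()) == [3, 4, 5]
        for _, grp in out.data.groupby("sample"):
            assert sorted(grp["time"]) == [3, 4, 5]

    def test_single_replicate_filter_skipped(self):
        rows = [(1.0, y, "a", "1", "P1") for y in range(1990, 1995)]
        out = rtimes(series_from(rows), lv="tree", only_dup=True)
        assert len(out) == 5
        assert sorted(out.data["time"]) == [1, 2, 3, 4, 5]

    def test_identical_spans_nothing_removed(self):
        hs = two_core_tree(range(1990, 1995), range(1990, 1995))
        out = rtimes(hs, lv="tree", only_dup=True)
        assert len(out) == 10

    def test_every_kept_time_in_two_replicates(self, growth_series):
        out = rtimes(growth_series, lv="tree", only_dup=True)
        for _, grp in out.data.groupby(["plot", "tree"]):
            counts = grp.groupby("time")["sample"].nunique()
            assert (counts >= 2).all()

    def test_empty_group_rejected(self, growth_series):
        empty = growth_series.copy_with(growth_series.data.iloc[0:0])
        with pytest.raises(ValueError, match="empty"):
            rtimes(empty)


class TestScacum:
    def test_plain_cumsum(self):
        rows = [(v, 2000 + i, "a", "1", "P1") for i, v in enumerate([1.0, 2.0, 3.0])]
        out = scacum(series_from(rows))
        assert out.data["csx"].tolist() == [1.0, 3.0, 6.0]

    def test_offset_hits_constant_at_reference(self):
        rows = [(v, 2000 + i, "a", "1", "P1") for i, v in enumerate([1.0, 2.0, 3.0])]
        out = scacum(series_from(rows), sc_c=10.0)
        assert out.data["csx"].tolist() == [5.0, 7.0, 10.0]

    @given(
        x=st.lists(st.floats(0.01, 10.0), min_size=2, max_size=12),
        const=st.floats(1.0, 500.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_offset_preserves_increments(self, x, const):
        rows = [(v, 2000 + i, "a", "1", "P1") for i, v in enumerate(x)]
        out = scacum(series_from(rows), sc_c=const)
        csx = out.data.sort_values("year")["csx"].to_numpy()
        np.testing.assert_allclose(np.diff(csx), np.asarray(x)[1:], rtol=1e-9)
        assert csx[-1] == pytest.approx(const)

    def test_reference_outside_range(self):
        rows = [(1.0, 2000, "a", "1", "P1"), (1.0, 2001, "a", "1", "P1")]
        with pytest.raises(ValueError, match="outside"):
            scacum(series_from(rows), sc_c=10.0, rf_t=1990)

    def test_missing_vector_entry(self):
        rows = [(1.0, 2000, "a", "1", "P1"), (1.0, 2001, "a", "1", "P1")]
        rv = RadiusVector({"P9.9": 50.0}, year=2001)
        with pytest.raises(ValueError, match="matches"):
            scacum(series_from(rows), sc_c=rv)

    def test_radius_vector_matched_by_tree_prefix(self):
        rows = [(1.0, 2000, "a", "1", "P1"), (2.0, 2001, "a", "1", "P1")]
        rv = RadiusVector({"P1.1": 30.0}, year=2001)
        out = scacum(series_from(rows), sc_c=rv)
        assert out.data["csx"].tolist() == [28.0, 30.0]


def cumulated(values):
    rows = [(v, 2000 + i, "a", "1", "P1") for i, v in enumerate(values)]
    return scacum(series_from(rows))


class TestAmod:
    def test_identity_parameters(self):
        hs = cumulated([1.0, 2.0, 3.0])
        out = amod(hs, mp=(1.0, 1.0))
        assert out.data["csx"].tolist() == hs.data["csx"].tolist()
        assert out.data["x"].tolist() == [1.0, 2.0, 3.0]

    def test_radius_to_diameter(self):
        hs = cumulated([5.0])
        assert amod(hs, mp=(2.0, 1.0)).data["csx"].iloc[0] == 10.0

    def test_basal_area(self):
        hs = cumulated([2.0])
        out = amod(hs, mp=(0.25 * np.pi, 2.0))
        assert out.data["csx"].iloc[0] == pytest.approx(np.pi, abs=1e-5)

    def test_chained_dbh_equation(self):
        # radius 500 mm -> 50 cm -> dib 100 cm -> 2.87 * 100**0.85 DBH
        hs = cumulated([500.0])
        out = amod(hs, mp=(2.0, 1.0, 2.87, 0.85), to_cm=True)
        assert out.data["csx"].iloc[0] == pytest.approx(2.87 * 100**0.85, rel=1e-6)
        assert out.data["csx"].iloc[0] == pytest.approx(143.84, abs=0.01)

    def test_increments_are_differences(self):
        hs = cumulated([1.0, 2.0, 3.0])
        out = amod(hs, mp=(0.25 * np.pi, 2.0))
        csx = out.data.sort_values("year")["csx"].to_numpy()
        x = out.data.sort_values("year")["x"].to_numpy()
        np.testing.assert_allclose(np.diff(csx, prepend=0.0), x)

    def test_odd_parameter_vector(self):
        with pytest.raises(ValueError, match="even"):
            amod(cumulated([1.0]), mp=(2.0, 1.0, 2.87))

    def test_nonpositive_base_under_power(self):
        hs = cumulated([-1.0, 2.0])
        with pytest.raises(ValueError, match="non-positive"):
            amod(hs, mp=(1.0, 2.0))


def climate_series(years, plots=("P1",)):
    rows = [
        (10.0, 12.0, m, y, p)
        for p in plots
        for y in years
        for m in range(1, 13)
    ]
    df = pd.DataFrame(rows, columns=["prec", "temp", "month", "year", "plot"])
    return HierSeries(df, ("prec", "temp"), ("month", "year"), ("plot",))


class TestMoveYr:
    def test_october_starts_next_seasonal_year(self):
        hs = climate_series([1949, 1950, 1951])
        out = move_yr(hs, ini_mnt="Oct")
        oct_1950 = out.data.query("month == 10")
        # October 1950 belongs to seasonal year 1951
        assert 1951 in oct_1950["year"].tolist()
        sep = out.data.query("month == 9")
        assert set(sep["year"]) <= {1950, 1951}

    def test_complete_seasonal_years_only(self):
        hs = climate_series([1949, 1950, 1951])
        out = move_yr(hs, ini_mnt="Oct")
        sizes = out.data.groupby(["plot", "year"]).size()
        assert (sizes == 12).all()
        # 3 calendar years -> 2 complete seasonal years
        assert set(out.data["year"]) == {1950, 1951}

    def test_january_is_identity(self):
        hs = climate_series([1990, 1991])
        out = move_yr(hs, ini_mnt="Jan")
        assert len(out) == len(hs)
        pd.testing.assert_frame_equal(
            out.sort().data.reset_index(drop=True), hs.sort().data
        )

    def test_record_bijection_on_complete_years(self):
        hs = climate_series([1980, 1981, 1982, 1983])
        out = move_yr(hs, ini_mnt="Oct")
        # every output record maps to exactly one input record
        key_in = set(map(tuple, hs.data[["plot", "month"]].assign(
            cal=hs.data["year"]).to_numpy()))
        cal = out.data["year"] - (out.data["month"] >= 10).astype(int)
        key_out = set(map(tuple, out.data[["plot", "month"]].assign(cal=cal).to_numpy()))
        assert key_out <= key_in
        assert len(key_out) == len(out)

    def test_invalid_month(self):
        with pytest.raises(ValueError, match="month"):
            move_yr(climate_series([1990]), ini_mnt="Movember")


class TestRecursiveEval:
    def test_empty_chain_is_noop(self, growth_series):
        out = recursive_eval(growth_series)
        pd.testing.assert_frame_equal(out.data, growth_series.data)

    def test_length_mismatch(self, growth_series):
        with pytest.raises(ValueError, match="must match"):
            recursive_eval(growth_series, ("rtimes",), ("tree", "sample"))

    def test_unknown_routine(self, growth_series):
        with pytest.raises(ValueError, match="unknown routine"):
            recursive_eval(growth_series, ("nope",), ("tree",))

    def test_default_growth_chain(self, growth_series):
        out = recursive_eval(
            growth_series, ("rtimes", "scacum", "amod"), ("tree", "sample", "sample")
        )
        assert {"time", "csx"} <= set(out.data.columns)
        # csx non-decreasing within each core (all increments positive)
        for _, grp in out.data.groupby(["plot", "tree", "sample"]):
            csx = grp.sort_values("year")["csx"].to_numpy()
            assert (np.diff(csx) >= 0).all()

    def test_climate_chain_produces_annual_index(self, climate_tables):
        from mldendro.hierdata import parse_wide_climate

        hs = parse_wide_climate(*climate_tables)
        out = recursive_eval(hs, ("moveYr", "wlai"), ("year", "year"))
        assert out.value_cols == ("AI",)
        assert not out.data.duplicated(["plot", "year"]).any()

    def test_vector_argument_matched_by_group(self, growth_series, radius_vector):
        out = recursive_eval(
            growth_series,
            ("rtimes", "scacum"),
            ("tree", "sample"),
            sc_c=radius_vector,
        )
        last = out.data.sort_values("year").groupby(["plot", "tree", "sample"]).tail(1)
        for _, rec in last.iterrows():
            expected = radius_vector.entries[f"{rec['plot']}.{rec['tree']}"]
            assert rec["csx"] == pytest.approx(expected)
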