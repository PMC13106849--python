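"""Sample model: pattern parsing, dedup, tabulation, time windows."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from honeygeo import samples
from honeygeo.samples import (
    PATTERNS,
    PatternParseError,
    assign_time_window,
    dedup_unique,
    format_percent,
    grid_density,
    load_region_map,
    parse_pattern,
    read_samples,
    round_half_up,
    tabulate,
    write_samples,
)

from conftest import make_table


class TestParsePattern:
    @pytest.mark.parametrize(
        "token,canonical",
        [("acm", "ACM"), ("MCA", "ACM"), ("C", "C"), ("ma", "AM"), ("  cm ", "CM")],
    )
    def test_canonicalization(self, token, canonical):
        assert parse_pattern(token).canonical == canonical

    @pytest.mark.parametrize("token", ["", "   ", "X", "AB", "AA", "ACMA", "A C"])
    def test_invalid_tokens_rejected(self, token):
        with pytest.raises(PatternParseError):
            parse_pattern(token)

    def test_error_names_offending_row(self):
        with pytest.raises(PatternParseError, match="S0042"):
            parse_pattern("Q", row="S0042")

    def test_exactly_seven_patterns_exist(self):
        # every subset of {A,C,M} except the empty set
        seen = {parse_pattern("".join(c)).canonical
                for c in ["A", "C", "M", "AC", "AM", "CM", "ACM"]}
        assert seen == set(PATTERNS)

    @given(st.sets(st.sampled_from("ACM"), min_size=1))
    def test_roundtrip_any_pattern(self, lineages):
        tok = "".join(lineages)
        p = parse_pattern(tok)
        assert parse_pattern(p.canonical) == p
        assert p.diversity == len(lineages)


class TestDedupUnique:
    def test_one_per_beekeeper_year(self):
        df = make_table({"C": 3})
        df["beekeeper_id"] = "BK1"  # same beekeeper, same year
        out = dedup_unique(df, seed=0)
        assert len(out) == 1
        assert out.iloc[0]["sample_id"] in set(df["sample_id"])

    def test_distinct_years_all_retained(self):
        frames = [make_table({"C": 1}, year=y) for y in (2018, 2019, 2020, 2021)]
        df = pd.concat(frames, ignore_index=True)
        df["beekeeper_id"] = "BK1"
        assert len(dedup_unique(df, seed=0)) == 4

    def test_unique_count_equals_distinct_pairs(self, small_survey):
        out = dedup_unique(small_survey, seed=3)
        expected = len({(b, y) for b, y in zip(small_survey["beekeeper_id"],
                                               small_survey["year"])})
        assert len(out) == expected

    def test_idempotent_and_deterministic(self, small_survey):
        once = dedup_unique(small_survey, seed=11)
        assert once.equals(dedup_unique(small_survey, seed=11))
        assert once.equals(dedup_unique(once, seed=11))


class TestTabulate:
    def test_published_regional_percentages(self, emilia_table):
        t = tabulate(emilia_table)
        assert t.loc[0, "n"] == 576
        assert t.loc[0, "pct_contains_A"] == 3.5
        assert t.loc[0, "pct_contains_M"] == 5.4
        assert t.loc[0, "pct_contains_A_or_M"] == 5.9

    def test_sub_percent_values_two_decimals(self):
        t = tabulate(make_table({"M": 7, "C": 4143}))
        assert t.loc[0, "n"] == 4150
        assert t.loc[0, "pct_only_M"] == 0.17

    def test_exact_pattern_frequencies_sum_to_one(self, small_survey):
        t = tabulate(small_survey, ["year"])
        props = t[[f"prop_{p}" for p in PATTERNS]].astype(float).sum(axis=1)
        assert np.allclose(props, 1.0, atol=1e-12)

    def test_contains_counts_dominate_only_counts(self, small_survey):
        t = tabulate(small_survey, ["macro_region"])
        for l in "ACM":
            assert (t[f"n_contains_{l}"] >= t[f"n_only_{l}"]).all()
        # every sample contains at least one lineage
        total_contains = t[["n_contains_A", "n_contains_C", "n_contains_M"]].sum(axis=1)
        assert (total_contains >= t["n"]).all()

    def test_group_totals_sum_to_input(self, small_survey):
        for keys in (["year"], ["macro_region"], ["year", "region"]):
            t = tabulate(small_survey, keys)
            assert int(t["n"].sum()) == len(small_survey)
            assert (t["n"] > 0).all()  # zero groups omitted

    def test_unknown_key_and_empty_input_rejected(self, small_survey):
        with pytest.raises(ValueError, match="grouping key"):
            tabulate(small_survey, ["flavour"])
        with pytest.raises(ValueError, match="empty"):
            tabulate(small_survey.iloc[0:0])


class TestRounding:
    @pytest.mark.parametrize(
        "value,decimals,expected",
        [(3.45, 1, 3.5), (3.44999, 1, 3.4), (0.165, 2, 0.17), (2.455, 2, 2.46)],
    )
    def test_half_up(self, value, decimals, expected):
        assert round_half_up(value, decimals) == expected

    def test_format_percent_convention(self):
        assert format_percent(20, 576) == 3.5
        assert format_percent(7, 4150) == 0.17  # sub-1% at two decimals
        assert format_percent(576, 576) == 100.0


class TestTimeWindows:
    @pytest.mark.parametrize(
        "year,label",
        [(1986, "1986-1999"), (1999, "1986-1999"), (2000, "2000-2009"),
         (2009, "2000-2009"), (2010, "2010-2017"), (2017, "2010-2017"),
         (2018, "2018"), (2021, "2021"), (2023, "2023")],
    )
    def test_window_bounds(self, year, label):
        assert assign_time_window(year) == label

    @pytest.mark.parametrize("year", [1985, 2024])
    def test_out_of_range_rejected(self, year):
        with pytest.raises(ValueError):
            assign_time_window(year)


class TestIO:
    def test_roundtrip_identity(self, small_survey, tmp_path):
        for name in ("t.csv", "t.tsv"):
            path = tmp_path / name
            write_samples(small_survey, path)
            back = read_samples(path)
            pd.testing.assert_frame_equal(
                back.reset_index(drop=True), small_survey.reset_index(drop=True)
            )

    def test_macro_region_derived_from_italian_regions(self, tmp_path):
        df = make_table({"C": 2}, region="Emilia-Romagna").drop(columns=["macro_region"])
        path = tmp_path / "x.csv"
        df.to_csv(path, index=False)
        back = read_samples(path)
        assert (back["macro_region"] == "North").all()

    def test_unknown_region_without_macro_fails(self, tmp_path):
        df = make_table({"C": 1}, region="Atlantis").drop(columns=["macro_region"])
        path = tmp_path / "x.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="Atlantis"):
            read_samples(path)

    def test_coordinate_window_soft_warning(self, tmp_path):
        df = make_table({"C": 1}, lat=55.0)
        path = tmp_path / "x.csv"
        df.to_csv(path, index=False)
        with pytest.warns(UserWarning, match="coordinate window"):
            read_samples(path)

    def test_region_map_is_a_function_over_20_regions(self):
        mapping = load_region_map()
        assert len(mapping) == 20
        assert set(mapping.values()) == set(samples.MACRO_REGIONS)


def test_grid_density_counts(small_survey):
    g = grid_density(small_survey, coding="contains-A", cell=0.25)
    assert int(g["n"].sum()) == len(small_survey)
    n_a = small_survey["pattern"].str.contains("A").sum()
    assert int(g["n_coding"].sum()) == n_a
    assert (g["n_coding"] <= g["n"]).all()
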