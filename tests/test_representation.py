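import numpy as np
import pandas as pd
import pytest

from aoh_gapscan.overlap_engine import InputError
from aoh_gapscan.representation import (ConfigurationError, build_summary, classify,
                                        classify_series, compare_groups, count_below,
                                        pa_crosscheck, rollup_species)


def summary_frame(rows):
    """Minimal per-map summary table from (map_id, species_id, season, pct) plus extras."""
    df = pd.DataFrame(rows, columns=["map_id", "species_id", "season", "pct_in_union"])
    df["threatened"] = False
    df["redlist"] = "LC"
    df["class"] = classify_series(df["pct_in_union"])
    return df


class TestClassify:
    @pytest.mark.parametrize("pct,expected", [
        (0.0, "no_overlap"),
        (4.99, "very_under"),
        (5.0, "under"),          # strict <5 boundary
        (7.99, "under"),
        (8.0, "adequate"),       # strict <8 boundary
        (100.0, "adequate"),
        (0.0001, "very_under"),
    ])
    def test_boundary_semantics(self, pct, expected):
        assert classify(pct) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            classify(-0.1)
        with pytest.raises(InputError):
            classify(100.1)

    def test_zero_percent_counts_under_both_thresholds(self):
        df = summary_frame([("m1", "s1", "resident", 0.0)])
        assert count_below(df, 5.0) == 1
        assert count_below(df, 8.0) == 1

    def test_class_counts_nest(self):
        rng = np.random.default_rng(3)
        pcts = np.concatenate([np.zeros(5), rng.uniform(0, 100, 200)])
        df = summary_frame([(f"m{i}", f"s{i}", "resident", p)
                            for i, p in enumerate(pcts)])
        n0 = (df["class"] == "no_overlap").sum()
        n5 = count_below(df, 5.0)
        n8 = count_below(df, 8.0)
        assert n0 <= n5 <= n8
        assert n0 == 5
        assert n5 == (pcts < 5).sum()
        assert n8 == (pcts < 8).sum()

    def test_series_matches_scalar(self):
        pcts = pd.Series([0.0, 3.2, 5.0, 7.5, 8.0, 99.0])
        assert list(classify_series(pcts)) == [classify(p) for p in pcts]


class TestRollup:
    def test_resident_below_threshold(self):
        df = summary_frame([("m1", "s1", "resident", 3.0)])
        out = rollup_species(df, threshold=5.0)
        row = out.iloc[0]
        assert row["under_any_season"] and row["pattern"] == "resident"

    def test_breeding_only_under(self):
        df = summary_frame([("m1", "s1", "breeding", 2.0),
                            ("m2", "s1", "nonbreeding", 15.0)])
        assert rollup_species(df, 5.0).iloc[0]["pattern"] == "breeding-only-under"

    def test_both_seasons_under(self):
        df = summary_frame([("m1", "s1", "breeding", 4.0),
                            ("m2", "s1", "nonbreeding", 4.0)])
        assert rollup_species(df, 5.0).iloc[0]["pattern"] == "both-seasons-under"

    def test_nonbreeding_only_under(self):
        df = summary_frame([("m1", "s1", "breeding", 50.0),
                            ("m2", "s1", "nonbreeding", 1.0)])
        assert rollup_species(df, 5.0).iloc[0]["pattern"] == "nonbreeding-only-under"

    def test_duplicate_species_season_rejected(self):
        df = summary_frame([("m1", "s1", "resident", 3.0),
                            ("m2", "s1", "resident", 4.0)])
        with pytest.raises(InputError):
            rollup_species(df)

    def test_pattern_codes_partition_flagged_species(self):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(120):
            if i % 3 == 0:
                rows.append((f"m{i}", f"s{i}", "resident", rng.uniform(0, 20)))
            else:
                rows.append((f"mb{i}", f"s{i}", "breeding", rng.uniform(0, 20)))
                rows.append((f"mn{i}", f"s{i}", "nonbreeding", rng.uniform(0, 20)))
        out = rollup_species(summary_frame(rows), 5.0)
        flagged = out[out["under_any_season"]]
        assert flagged["pattern"].notna().all()
        assert (~out["under_any_season"] == out["pattern"].isna()).all()
        assert flagged["pattern"].isin(["resident", "both-seasons-under",
                                        "breeding-only-under",
                                        "nonbreeding-only-under"]).all()


class TestCompareGroups:
    def test_mean_of_two_maps(self):
        df = summary_frame([("m1", "s1", "resident", 10.0),
                            ("m2", "s2", "resident", 30.0)])
        df["trigger"] = True
        out = compare_groups(df, "trigger")
        assert out.loc[0, "mean_pct"] == pytest.approx(20.0)

    def test_identical_groups_have_zero_difference(self):
        df = summary_frame([("m1", "s1", "resident", 10.0),
                            ("m2", "s2", "resident", 30.0),
                            ("m3", "s3", "resident", 10.0),
                            ("m4", "s4", "resident", 30.0)])
        df["trigger"] = [True, True, False, False]
        out = compare_groups(df, "trigger")
        assert out.attrs["difference"] == pytest.approx(0.0)

    def test_mean_is_unweighted_by_area_and_order_invariant(self):
        df = summary_frame([("m1", "s1", "resident", 10.0),
                            ("m2", "s2", "resident", 30.0)])
        df["trigger"] = True
        shuffled = df.iloc[::-1].reset_index(drop=True)
        a = compare_groups(df, "trigger").loc[0, "mean_pct"]
        b = compare_groups(shuffled, "trigger").loc[0, "mean_pct"]
        assert a == b


class TestPaCrosscheck:
    def test_zero_count_in_subset(self):
        df = summary_frame([(f"m{i}", f"s{i}", "resident", 0.0) for i in range(5)])
        df["pct_protected"] = [0.0, 0.0, 1.0, 2.0, 3.0]
        out = pa_crosscheck(df)
        assert out["subset_size"] == 5 and out["zero_pa_count"] == 2

    def test_empty_subset_gives_empty_table(self):
        df = summary_frame([("m1", "s1", "resident", 50.0)])
        df["pct_protected"] = 10.0
        out = pa_crosscheck(df)
        assert out["subset_size"] == 0 and len(out["gap_table"]) == 0

    def test_missing_pa_layer_is_configuration_error(self):
        df = summary_frame([("m1", "s1", "resident", 0.0)])
        with pytest.raises(ConfigurationError):
            pa_crosscheck(df)

    def test_pa_layer_equal_to_site_layer_forces_identical_percents(self):
        # when the protected-area layer IS the site layer, the zero-PA maps in
        # the subset are exactly the no-overlap maps
        rng = np.random.default_rng(9)
        pcts = np.concatenate([np.zeros(4), rng.uniform(0.1, 4.9, 6),
                               rng.uniform(10, 90, 10)])
        df = summary_frame([(f"m{i}", f"s{i}", "resident", p)
                            for i, p in enumerate(pcts)])
        df["threatened"] = [True] * 10 + [False] * 10
        df["pct_protected"] = df["pct_in_union"]
        out = pa_crosscheck(df, threshold=5.0)
        assert out["zero_pa_count"] == 4


def test_build_summary_joins_attributes(small_scenario):
    import shapely

    from aoh_gapscan.geometry_prep import repair_geometries
    from aoh_gapscan.overlap_engine import summarize_maps

    ss = repair_geometries(small_scenario.sites)
    core = summarize_maps(small_scenario.maps, ss.dissolve(), warn_unusable=False)
    out = build_summary(core, small_scenario.attributes)
    assert {"class", "trigger", "redlist", "order"} <= set(out.columns)
    assert len(out) == len(small_scenario.maps)
    assert (out["unit"] == "map").all()
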