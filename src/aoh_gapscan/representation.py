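"""Representation classes, seasonal rollups, group comparisons, PA cross-check.

A species map is *underrepresented* when strictly less than 8% of its
suitable habitat lies inside the dissolved site union, and *very
underrepresented* below 5%.  The 8% default anchors to the fraction of
Earth's land covered by the global Key Biodiversity Area network (8.01%):
under random placement of species and sites, ~8% of any map would fall in
sites, so falling well short of that marks a genuine gap.  Classes nest —
a map with 0% is also counted in the <5% and <8% tallies — so counts below
a threshold are cumulative.

Counts are reported at two granularities, maps and species, and every
output carries an explicit unit, because one species can contribute two
seasonal maps.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .overlap_engine import InputError

DEFAULT_THRESHOLDS = (5.0, 8.0)

CLASS_NO_OVERLAP = "no_overlap"
CLASS_VERY_UNDER = "very_under"
CLASS_UNDER = "under"
CLASS_ADEQUATE = "adequate"

PATTERN_RESIDENT = "resident"
PATTERN_BOTH = "both-seasons-under"
PATTERN_BREEDING = "breeding-only-under"
PATTERN_NONBREEDING = "nonbreeding-only-under"


class ConfigurationError(ValueError):
    """A required layer or column is missing for the requested analysis."""


def classify(percent: float, thresholds: tuple[float, float] = DEFAULT_THRESHOLDS) -> str:
    """Representation class of one percent-in-union value.

    Strict ``<`` semantics at both thresholds; exactly 0 is additionally
    flagged ``no_overlap`` (and still counts toward both threshold tallies).
    """
    low, high = sorted(thresholds)
    if not (0.0 <= percent <= 100.0) or np.isnan(percent):
        raise InputError(f"percent {percent!r} outside [0, 100]")
    if percent == 0.0:
        return CLASS_NO_OVERLAP
    if percent < low:
        return CLASS_VERY_UNDER
    if percent < high:
        return CLASS_UNDER
    return CLASS_ADEQUATE


def classify_series(percents: pd.Series,
                    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS) -> pd.Series:
    """Vectorized :func:`classify`; NaN percents (unusable maps) stay NaN."""
    low, high = sorted(thresholds)
    p = percents.astype(float)
    if ((p < 0) | (p > 100)).any():
        raise InputError("percents outside [0, 100]")
    out = pd.Series(np.select(
        [p == 0.0, p < low, p < high], [CLASS_NO_OVERLAP, CLASS_VERY_UNDER, CLASS_UNDER],
        default=CLASS_ADEQUATE), index=percents.index, dtype=object)
    out[p.isna()] = pd.NA
    return out


def count_below(summaries: pd.DataFrame, threshold: float,
                unit: str = "map") -> int:
    """Cumulative tally of maps (or species) with percent strictly below threshold."""
    usable = summaries[~summaries["pct_in_union"].isna()]
    below = usable[usable["pct_in_union"] < threshold]
    if unit == "map":
        return len(below)
    if unit == "species":
        return below["species_id"].nunique()
    raise InputError(f"unknown unit {unit!r}")


def build_summary(map_summaries: pd.DataFrame, attributes: pd.DataFrame,
                  thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
                  pa_percents: pd.Series | None = None) -> pd.DataFrame:
    """Join per-map percents with species attributes into the analysis table.

    One row per map (unit = map) with representation class, trigger flag,
    Red List category, order/family, the single-important-habitat code, and
    optionally the percent of the map inside protected areas.
    """
    df = map_summaries.merge(
        attributes[["species_id", "order", "family", "redlist", "threatened",
                    "trigger", "single_major_habitat", "migratory"]],
        on="species_id", how="left", validate="many_to_one")
    df["class"] = classify_series(df["pct_in_union"], thresholds)
    df["unit"] = "map"
    if pa_percents is not None:
        df["pct_protected"] = df["map_id"].map(pa_percents)
    return df


def rollup_species(summaries: pd.DataFrame, threshold: float = 5.0) -> pd.DataFrame:
    """Species-level rollup of per-season percents against one threshold.

    A species is flagged when *any* of its seasonal maps falls strictly below
    ``threshold``; flagged species get a migratory pattern code partitioning
    them into resident / both-seasons / breeding-only / nonbreeding-only.
    Unusable (NaN-percent) maps are ignored.
    """
    if summaries.duplicated(["species_id", "season"]).any():
        raise InputError("duplicate (species, season) map")
    usable = summaries[~summaries["pct_in_union"].isna()]
    rows = []
    for sid, grp in usable.groupby("species_id", sort=True):
        pct = dict(zip(grp["season"], grp["pct_in_union"]))
        under = {s: p < threshold for s, p in pct.items()}
        flagged = any(under.values())
        pattern = pd.NA
        if flagged:
            if "resident" in under and under["resident"]:
                pattern = PATTERN_RESIDENT
            else:
                b = under.get("breeding", False)
                nb = under.get("nonbreeding", False)
                if b and nb:
                    pattern = PATTERN_BOTH
                elif b:
                    pattern = PATTERN_BREEDING
                elif nb:
                    pattern = PATTERN_NONBREEDING
        rows.append({
            "species_id": sid,
            "pct_resident": pct.get("resident", np.nan),
            "pct_breeding": pct.get("breeding", np.nan),
            "pct_nonbreeding": pct.get("nonbreeding", np.nan),
            "under_any_season": flagged,
            "pattern": pattern,
            "unit": "species",
        })
    return pd.DataFrame(rows)


def compare_groups(summaries: pd.DataFrame, group_col: str = "trigger") -> pd.DataFrame:
    """Unweighted mean percent-in-union per group, with the pairwise difference.

    The mean is over maps (each map one observation, regardless of its area).
    Empty groups are reported with a missing mean.  For a boolean grouping the
    returned frame's ``.attrs['difference']`` holds mean(True) - mean(False).
    """
    usable = summaries[~summaries["pct_in_union"].isna()]
    out = (usable.groupby(group_col, dropna=False)["pct_in_union"]
           .agg(n_maps="size", mean_pct="mean").reset_index())
    if set(out[group_col]) >= {True, False}:
        m = dict(zip(out[group_col], out["mean_pct"]))
        out.attrs["difference"] = float(m[True] - m[False])
    return out


def pa_crosscheck(summaries: pd.DataFrame, threshold: float = 5.0) -> dict:
    """Protected-area gap table for the most exposed maps.

    Subset rule: maps with zero overlap with sites, plus maps of threatened
    species strictly below ``threshold``; within the subset, report maps with
    zero percent inside protected areas.  Requires ``pct_protected`` on the
    summary table (a configuration error otherwise).
    """
    if "pct_protected" not in summaries.columns or summaries["pct_protected"].isna().all():
        raise ConfigurationError("protected-area percents missing; compute them first")
    usable = summaries[~summaries["pct_in_union"].isna()]
    in_subset = (usable["pct_in_union"] == 0.0) | (
        usable["threatened"].fillna(False) & (usable["pct_in_union"] < threshold))
    subset = usable[in_subset]
    gaps = subset[subset["pct_protected"] == 0.0]
    return {
        "subset_size": len(subset),
        "zero_pa_count": len(gaps),
        "gap_table": gaps[["map_id", "species_id", "season", "pct_in_union",
                           "pct_protected", "redlist", "class"]].reset_index(drop=True),
    }
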