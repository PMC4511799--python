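"""Vessel-day effort construction, CPUE tabulation and fleet summaries.

The effort unit is the vessel-day: one vessel fishing on one calendar
date, measured from its 5-minute GPS fixes.  A day's effort is split
across latitude-band areas in proportion to fix counts (equivalently,
time at the fixed cadence).  Two allocation rules are supported:

* the GLM rule — keep only days with at least 85% of fixes in one area
  and assign the whole day to that dominant area (week-area cells whose
  days all have zero catch are then dropped, since all-zero cells make
  the count-GLM likelihood separate);
* proportional allocation — each day contributes fractional vessel-days
  to every area it visited, while each caught fish counts in the area of
  its capture coordinates.  This conserves total effort and is the rule
  behind the stock-specific CPUE tables.

Fish of unknown length are imputed fractional legal status from the
known legal/sub-legal ratio of their month-area stratum.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .strata import StrataConfig

log = logging.getLogger(__name__)

MIN_DOMINANT_FRACTION = 0.85


def build_vessel_days(
    fixes: pd.DataFrame,
    encounters: pd.DataFrame,
    strata: StrataConfig,
) -> pd.DataFrame:
    """One record per (vessel, date) with per-area fix fractions.

    Columns: vessel_id, date, fixes, area_fractions (dict), dominant_area,
    dominant_fraction, technique, legal_catch, sublegal_catch, week, month.
    Legal counts come from the encounter records (known lengths only;
    unknown lengths are resolved later by :func:`impute_legal`).
    Encounters whose vessel has no same-day fixes are kept, warned about,
    and located by their own coordinates.
    """
    fx = fixes.copy()
    fx["date"] = fx["timestamp"].dt.date
    fx["area"] = [strata.area_of(la) for la in fx["lat"].astype(float)]
    fx = fx[fx["area"].notna()]

    enc = encounters.copy()
    enc["date"] = enc["timestamp"].dt.date
    enc["area"] = [strata.area_of(la) for la in enc["lat"].astype(float)]

    have_fixes = set(zip(fx["vessel_id"], fx["date"]))
    orphan = [k not in have_fixes for k in zip(enc["vessel_id"], enc["date"])]
    if any(orphan):
        log.warning("%d encounter(s) have no same-day fixes for their vessel; "
                    "kept with area from capture coordinates", sum(orphan))

    records = []
    enc_by_day = dict(tuple(enc.groupby(["vessel_id", "date"], sort=False)))
    for (vessel, date), g in fx.groupby(["vessel_id", "date"], sort=False):
        counts = g["area"].value_counts()
        fractions = (counts / counts.sum()).to_dict()
        dom = counts.idxmax()
        eday = enc_by_day.get((vessel, date))
        technique = None
        if "technique" in g.columns and g["technique"].notna().any():
            technique = g["technique"].mode().iloc[0]
        legal = sublegal = unknown = 0
        if eday is not None:
            if technique is None and eday["technique"].notna().any():
                technique = eday["technique"].mode().iloc[0]
            if "legal" in eday.columns:
                legal = int((eday["legal"] == True).sum())  # noqa: E712
                sublegal = int((eday["legal"] == False).sum())  # noqa: E712
                unknown = int(eday["legal"].isna().sum())
            else:  # no length annotation: count every encounter as legal
                legal = len(eday)
        records.append({
            "vessel_id": vessel, "date": date, "fixes": int(counts.sum()),
            "area_fractions": fractions,
            "dominant_area": dom, "dominant_fraction": float(counts.max() / counts.sum()),
            "technique": technique, "legal_catch": legal,
            "sublegal_catch": sublegal, "unknown_length": unknown,
            "week": strata.week_of(date), "month": strata.month_of(date),
        })
    vd = pd.DataFrame.from_records(records)
    return vd.sort_values(["vessel_id", "date"]).reset_index(drop=True)


def annotate_legal(encounters: pd.DataFrame, legal_threshold_mm: float) -> pd.DataFrame:
    """Add a nullable-boolean ``legal`` column from measured length."""
    enc = encounters.copy()
    length = enc["length_mm"]
    enc["legal"] = pd.array(
        np.where(length.notna(), length >= legal_threshold_mm, None),
        dtype="boolean",
    )
    return enc


def glm_dataset(
    vessel_days: pd.DataFrame,
    min_fraction: float = MIN_DOMINANT_FRACTION,
    period: str = "week",
) -> tuple[pd.DataFrame, dict]:
    """Filter vessel-days for count-GLM fitting.

    Keeps days whose dominant area holds at least ``min_fraction`` of the
    day's fixes, assigns the whole day to that area, then drops every
    (period, area) cell whose days are all zero-catch (quasi-complete
    separation guard).  Returns the filtered table and step-wise drop
    counts.
    """
    if period not in ("week", "month"):
        raise ValueError("period must be 'week' or 'month'")
    kept = vessel_days[vessel_days["dominant_fraction"] >= min_fraction].copy()
    n_spread = len(vessel_days) - len(kept)
    kept["area"] = kept["dominant_area"]

    cell_max = kept.groupby([period, "area"])["legal_catch"].transform("max")
    zero_cell = cell_max == 0
    out = kept[~zero_cell].reset_index(drop=True)
    report = {
        "dropped_multi_area_days": int(n_spread),
        "dropped_zero_cell_days": int(zero_cell.sum()),
        "n_zero_cells": int(kept.loc[zero_cell, [period, "area"]]
                            .drop_duplicates().shape[0]),
        "retained_days": len(out),
    }
    return out, report


def proportional_effort(
    vessel_days: pd.DataFrame, period: str = "month"
) -> pd.DataFrame:
    """Fractional vessel-day effort per (period, area).

    Each day contributes its area fix-fractions; total effort is
    conserved to within floating-point error.
    """
    rows = []
    for _, day in vessel_days.iterrows():
        for area, frac in day["area_fractions"].items():
            rows.append({period: day[period], "area": area,
                         "technique": day["technique"], "vessel_days": frac})
    eff = (pd.DataFrame(rows)
           .groupby([period, "area"], as_index=False, dropna=False)["vessel_days"]
           .sum())
    return eff


def catch_by_capture_area(
    encounters: pd.DataFrame, strata: StrataConfig, period: str = "month"
) -> pd.DataFrame:
    """Legal (fractional, post-imputation) catch per (period, area), with
    each fish allocated to the area of its capture coordinates."""
    enc = encounters.copy()
    enc["date"] = enc["timestamp"].dt.date
    enc["area"] = [strata.area_of(la) for la in enc["lat"].astype(float)]
    enc[period] = [getattr(strata, f"{period}_of")(d) for d in enc["date"]]
    col = "legal_weight" if "legal_weight" in enc.columns else "legal"
    enc["_legal"] = enc[col].astype(float)
    return (enc.groupby([period, "area"], as_index=False)["_legal"]
            .sum().rename(columns={"_legal": "legal_encounters"}))


def impute_legal(
    encounters: pd.DataFrame, strata: StrataConfig
) -> tuple[pd.DataFrame, dict]:
    """Resolve unknown-length fish to fractional legal weights.

    Each unknown-length fish in a month-area stratum contributes a legal
    weight equal to the stratum's known-legal / known-total ratio; a
    stratum with no length-known fish falls back to the season-wide ratio
    for its area (logged).  Adds a ``legal_weight`` column; known fish
    get weight 0/1.  Total fish count is conserved.
    """
    enc = encounters.copy()
    enc["date"] = enc["timestamp"].dt.date
    enc["area"] = [strata.area_of(la) for la in enc["lat"].astype(float)]
    enc["month"] = [strata.month_of(d) for d in enc["date"]]

    known = enc[enc["legal"].notna()]
    ratio = known.groupby(["month", "area"])["legal"].mean()
    area_ratio = known.groupby("area")["legal"].mean()
    global_ratio = float(known["legal"].mean()) if len(known) else 0.0

    weights = np.empty(len(enc))
    fallback_strata = set()
    for i, row in enumerate(enc.itertuples(index=False)):
        if row.legal is not None and not pd.isna(row.legal):
            weights[i] = float(row.legal)
            continue
        key = (row.month, row.area)
        if key in ratio.index:
            weights[i] = float(ratio.loc[key])
        elif row.area in area_ratio.index:
            weights[i] = float(area_ratio.loc[row.area])
            fallback_strata.add(key)
        else:
            weights[i] = global_ratio
            fallback_strata.add(key)
    if fallback_strata:
        log.info("legal imputation fell back to season-area pool for %s",
                 sorted(fallback_strata))
    enc["legal_weight"] = weights
    report = {
        "n_unknown": int(enc["legal"].isna().sum()),
        "fallback_strata": sorted(fallback_strata),
    }
    return enc, report


def stratum_cpue(
    effort: pd.DataFrame,
    legal: pd.DataFrame,
    period: str = "month",
) -> pd.DataFrame:
    """CPUE per (period, area): legal encounters / vessel-days.

    ``effort`` needs columns [period, area, vessel_days]; ``legal`` needs
    [period, area, legal_encounters] (aliases 'legal' accepted).  Strata
    with zero effort get NaN CPUE.  Values are kept at full precision;
    round only for display.
    """
    legal = legal.rename(columns={"legal": "legal_encounters"})
    eff = effort.groupby([period, "area"], as_index=False)["vessel_days"].sum()
    cat = legal.groupby([period, "area"], as_index=False)["legal_encounters"].sum()
    tab = eff.merge(cat, on=[period, "area"], how="outer")
    tab["vessel_days"] = tab["vessel_days"].fillna(0.0)
    tab["legal_encounters"] = tab["legal_encounters"].fillna(0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tab["cpue"] = np.where(
            tab["vessel_days"] > 0,
            tab["legal_encounters"] / tab["vessel_days"],
            np.nan,
        )
    return tab.reset_index(drop=True)


def summarize_strata(
    cells: pd.DataFrame,
    value: str,
    merge_rule: str = "merge_shared_month_area",
) -> dict:
    """Descriptive summary (min/max/mean/median) over month-area strata.

    ``cells`` has columns [area, month, technique, <value>].  Under the
    default merge rule, retention and non-retention cells of the same
    month-area are combined into one stratum (they represent one fishery
    sampled both ways within the month); "none" keeps them separate.
    Returns the summary plus the merged stratum list for audit.
    """
    if merge_rule == "merge_shared_month_area":
        merged = cells.groupby(["area", "month"], as_index=False)[value].sum()
    elif merge_rule == "none":
        merged = cells.copy()
    else:
        raise ValueError(f"unknown merge_rule {merge_rule!r}")
    merged = merged[merged[value] > 0].reset_index(drop=True)
    vals = merged[value].to_numpy(float)
    return {
        "n_strata": len(vals),
        "min": float(vals.min()),
        "max": float(vals.max()),
        "mean": float(vals.mean()),
        "median": float(np.median(vals)),
        "total": float(vals.sum()),
        "strata": merged,
    }


def fleet_comparison(project: dict, external: dict) -> pd.DataFrame:
    """Compare project totals against an external (full-fleet) fishery.

    Shared keys become rows with percentage = project/external x 100
    (NaN for zero denominators).  CPUE rows are added from landed fish
    over vessel effort, with and without zero-catch days when the
    project's non-zero-catch day count is supplied.
    """
    rows = []
    for key in project:
        if key in external:
            ext = external[key]
            pct = 100.0 * project[key] / ext if ext else np.nan
            rows.append({"quantity": key, "project": project[key],
                         "external": ext, "percent": pct})
    landed = project.get("landed_fish_total")
    effort = project.get("vessel_effort_total")
    if landed is not None and effort:
        rows.append({"quantity": "cpue", "project": landed / effort,
                     "external": (external.get("landed_fish_total", np.nan)
                                  / external.get("vessel_effort_total", np.nan)),
                     "percent": np.nan})
    nz = project.get("vessel_days_nonzero_catch")
    if landed is not None and nz:
        rows.append({"quantity": "cpue_excluding_zero_catch_days",
                     "project": landed / nz, "external": np.nan,
                     "percent": 100.0 * nz / external.get("vessel_effort_total", np.nan)
                     if external.get("vessel_effort_total") else np.nan})
    return pd.DataFrame(rows)
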