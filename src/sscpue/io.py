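"""Readers and writers for the pipeline's external text formats.

All formats are plain CSV (genotypes, GPS track logs, encounter records)
or YAML (strata configuration).  Genotype CSVs use two columns per locus,
``<locus>_1`` / ``<locus>_2``; a missing genotype is coded as an empty
field or ``"0"`` on read and written back as empty.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, CoordinateRangeError, MalformedGenotypeError, TimestampError
from .genotypes import META_COLUMNS, GenotypeTable
from .strata import Area, StrataConfig

MISSING_ALLELE_CODES = ("", "0")


def _locus_names(columns) -> list[str]:
    """Locus list from paired ``<locus>_1`` / ``<locus>_2`` headers."""
    loci = []
    for c in columns:
        if c.endswith("_1") and c[:-2] + "_2" in columns and c[:-2] not in META_COLUMNS:
            loci.append(c[:-2])
    return loci


def read_genotypes(path, marker_type: str) -> GenotypeTable:
    """Read a genotype CSV into a :class:`GenotypeTable`.

    Both alleles empty/"0" means the locus is missing for that fish; a
    half-typed locus raises :class:`MalformedGenotypeError`.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    loci = _locus_names(list(df.columns))
    for locus in loci:
        for suffix in ("_1", "_2"):
            col = locus + suffix
            df[col] = df[col].str.strip()
            df.loc[df[col].isin(MISSING_ALLELE_CODES), col] = pd.NA
    for col in META_COLUMNS:
        if col in df.columns:
            df.loc[df[col] == "", col] = pd.NA
    for col in ("lat", "lon", "length_mm"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if "date" in df.columns:
        df["date"] = pd.to_datetime(df["date"], errors="coerce").dt.date
    try:
        return GenotypeTable(marker_type, loci, df)
    except MalformedGenotypeError as e:
        raise MalformedGenotypeError(f"{path}: {e}") from None


def write_genotypes(table: GenotypeTable, path) -> None:
    cols = META_COLUMNS + [f"{l}_{i}" for l in table.loci for i in (1, 2)]
    table.data[cols].to_csv(path, index=False)


def read_track_log(path) -> pd.DataFrame:
    """Read GPS effort fixes (vessel_id, timestamp, lat, lon).

    Output is sorted by (vessel_id, timestamp); exact duplicate timestamps
    within a vessel keep the first fix.  Coordinates outside +/-90 / +/-180
    raise :class:`CoordinateRangeError`.
    """
    df = pd.read_csv(path, dtype={"vessel_id": str})
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    if ts.isna().any():
        bad = df.loc[ts.isna(), "timestamp"].iloc[0]
        raise TimestampError(f"{path}: unparseable timestamp {bad!r}")
    df["timestamp"] = ts
    _check_coords(df, path)
    df = df.sort_values(["vessel_id", "timestamp"], kind="stable")
    df = df.drop_duplicates(subset=["vessel_id", "timestamp"], keep="first")
    return df.reset_index(drop=True)


def read_encounters(path) -> pd.DataFrame:
    """Read fish encounter records.

    Columns: fish_id, vessel_id, timestamp, lat, lon, length_mm (may be
    empty), technique (retention | nonretention).
    """
    df = pd.read_csv(path, dtype={"fish_id": str, "vessel_id": str})
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    if ts.isna().any():
        bad = df.loc[ts.isna(), "timestamp"].iloc[0]
        raise TimestampError(f"{path}: unparseable timestamp {bad!r}")
    df["timestamp"] = ts
    df["length_mm"] = pd.to_numeric(df.get("length_mm"), errors="coerce")
    _check_coords(df, path)
    return df.reset_index(drop=True)


def _check_coords(df: pd.DataFrame, path) -> None:
    lat = df["lat"].to_numpy(float)
    lon = df["lon"].to_numpy(float)
    bad = (np.abs(lat) > 90) | (np.abs(lon) > 180) | ~np.isfinite(lat) | ~np.isfinite(lon)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise CoordinateRangeError(
            f"{path}: coordinate out of range at row {i}: "
            f"lat={lat[i]}, lon={lon[i]}"
        )


def read_strata_config(path) -> StrataConfig:
    """Read a YAML strata configuration.

    Layout::

        areas:
          - {code: NO, lat_min: 44.015, lat_max: 45.767}
          ...
        season_start: 2010-05-01
        season_end: 2010-09-30
        week_rule: iso_monday        # or custom_anchor
        week_anchor: 2010-05-03      # required for custom_anchor
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        areas = [Area(str(a["code"]), float(a["lat_min"]), float(a["lat_max"]))
                 for a in raw["areas"]]
        cfg = StrataConfig(
            areas=areas,
            season_start=_as_date(raw["season_start"]),
            season_end=_as_date(raw["season_end"]),
            week_rule=raw.get("week_rule", "iso_monday"),
            week_anchor=_as_date(raw["week_anchor"]) if raw.get("week_anchor") else None,
            month_labels=raw.get("month_labels", []),
        )
    except (KeyError, TypeError, ValueError) as e:
        raise ConfigError(f"{path}: invalid strata config ({e})") from None
    return cfg


def write_strata_config(cfg: StrataConfig, path) -> None:
    doc = {
        "areas": [{"code": a.code, "lat_min": a.lat_min, "lat_max": a.lat_max}
                  for a in cfg.areas],
        "season_start": cfg.season_start.isoformat(),
        "season_end": cfg.season_end.isoformat(),
        "week_rule": cfg.week_rule,
        "month_labels": cfg.month_labels,
    }
    if cfg.week_anchor is not None:
        doc["week_anchor"] = cfg.week_anchor.isoformat()
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _as_date(v) -> dt.date:
    if isinstance(v, dt.datetime):
        return v.date()
    if isinstance(v, dt.date):
        return v
    return dt.date.fromisoformat(str(v))
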