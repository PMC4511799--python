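"""Published tabulations from the 2010 West Coast at-sea troll survey.

These are the printed month x area effort and encounter tables from the
2010 cooperative Chinook salmon sampling program (Cape Falcon, Oregon to
the Mexican border), kept here as arithmetic fixtures and worked-example
inputs: stratum CPUE, stratum summaries, and the comparison against the
2010 commercial fishery are all recomputable from them.

Areas north to south: NO (North Oregon Coast), CO (Central Oregon Coast),
KO (Oregon Klamath Zone), KC-n (California Klamath Zone north), FB (Fort
Bragg), SF-n / SF-s (San Francisco north / south), MO-n / MO-s (Monterey
north / south).  No sampling occurred in KO or KC-n during May.
"""

from __future__ import annotations

import datetime as dt

import pandas as pd

from .strata import Area, StrataConfig

AREA_BANDS = [
    ("NO", 44.015, 45.767),
    ("CO", 42.667, 44.015),
    ("KO", 42.000, 42.667),
    ("KC-n", 40.765, 42.000),
    # KC-s (40.083-40.765) was closed to sampling; the band is omitted.
    ("FB", 38.958, 40.083),
    ("SF-n", 37.996, 38.958),
    ("SF-s", 37.183, 37.996),
    ("MO-n", 36.300, 37.183),
    ("MO-s", 32.584, 36.300),
]

AREAS = [code for code, _, _ in AREA_BANDS]
MONTHS = ["May", "June", "July", "August", "September"]

#: commercial retention size limits, total length in inches
LEGAL_LIMIT_INCHES = {"OR": 28.0, "CA": 27.0}
#: default legal threshold used by the synthetic generator, mm (~27 in)
LEGAL_LIMIT_MM = 686.0


def strata_config() -> StrataConfig:
    """The survey's nine latitude bands and May-September 2010 season."""
    return StrataConfig(
        areas=[Area(c, lo, hi) for c, lo, hi in AREA_BANDS],
        season_start=dt.date(2010, 5, 1),
        season_end=dt.date(2010, 9, 30),
    )


# -- vessel-days of effort per (area, month, technique) ---------------------
# Fractional values arise from proportional allocation of boundary-crossing
# days.  July cells south of Fort Bragg have both retention (open July 1-4,
# 8-11) and non-retention components.
VESSEL_DAYS = [
    # area, month, technique, vessel_days
    ("NO", "May", "retention", 75.29),
    ("NO", "June", "retention", 176.96),
    ("NO", "July", "retention", 73.86),
    ("NO", "August", "retention", 181.35),
    ("NO", "September", "nonretention", 33.00),
    ("CO", "May", "retention", 108.71),
    ("CO", "June", "retention", 166.08),
    ("CO", "July", "retention", 34.14),
    ("CO", "August", "retention", 204.65),
    ("CO", "September", "nonretention", 30.07),
    ("KO", "June", "nonretention", 34.96),
    ("KO", "July", "retention", 7.00),
    ("KO", "August", "retention", 27.00),
    ("KO", "September", "nonretention", 20.93),
    ("KC-n", "June", "nonretention", 37.00),
    ("KC-n", "July", "nonretention", 55.00),
    ("KC-n", "August", "nonretention", 60.00),
    ("KC-n", "September", "nonretention", 60.00),
    ("FB", "May", "nonretention", 9.00),
    ("FB", "June", "nonretention", 47.00),
    ("FB", "July", "retention", 91.57),
    ("FB", "August", "retention", 120.00),
    ("FB", "September", "nonretention", 70.00),
    ("SF-n", "May", "nonretention", 24.00),
    ("SF-n", "June", "nonretention", 59.00),
    ("SF-n", "July", "nonretention", 32.00),
    ("SF-n", "July", "retention", 60.20),
    ("SF-n", "August", "nonretention", 60.00),
    ("SF-n", "September", "nonretention", 59.73),
    ("SF-s", "May", "nonretention", 52.00),
    ("SF-s", "June", "nonretention", 60.00),
    ("SF-s", "July", "nonretention", 38.00),
    ("SF-s", "July", "retention", 48.19),
    ("SF-s", "August", "nonretention", 58.00),
    ("SF-s", "September", "nonretention", 67.27),
    ("MO-n", "May", "nonretention", 35.69),
    ("MO-n", "June", "nonretention", 42.11),
    ("MO-n", "July", "nonretention", 22.00),
    ("MO-n", "July", "retention", 60.04),
    ("MO-n", "August", "nonretention", 40.00),
    ("MO-n", "September", "nonretention", 28.00),
    ("MO-s", "May", "nonretention", 8.31),
    ("MO-s", "June", "nonretention", 14.89),
    ("MO-s", "July", "nonretention", 11.00),
    ("MO-s", "July", "retention", 18.00),
    ("MO-s", "August", "nonretention", 17.00),
    ("MO-s", "September", "nonretention", 12.00),
]

# -- Chinook encounters per (area, month): sub-legal and legal counts -------
# Technique: "retention", "nonretention", or "mixed" (July cells sampled
# under both regimes; counts were published already combined).
ENCOUNTERS = [
    # area, month, technique, sublegal, legal
    ("NO", "May", "retention", 0, 404),
    ("NO", "June", "retention", 0, 1102),
    ("NO", "July", "retention", 0, 403),
    ("NO", "August", "retention", 0, 532),
    ("NO", "September", "nonretention", 7, 23),
    ("CO", "May", "retention", 0, 453),
    ("CO", "June", "retention", 0, 616),
    ("CO", "July", "retention", 0, 75),
    ("CO", "August", "retention", 0, 601),
    ("CO", "September", "nonretention", 31, 64),
    ("KO", "June", "nonretention", 0, 44),
    ("KO", "July", "retention", 0, 10),
    ("KO", "August", "retention", 0, 69),
    ("KO", "September", "nonretention", 49, 86),
    ("KC-n", "June", "nonretention", 6, 64),
    ("KC-n", "July", "nonretention", 7, 127),
    ("KC-n", "August", "nonretention", 88, 382),
    ("KC-n", "September", "nonretention", 121, 247),
    ("FB", "May", "nonretention", 6, 91),
    ("FB", "June", "nonretention", 10, 159),
    ("FB", "July", "retention", 2, 483),
    ("FB", "August", "retention", 8, 533),
    ("FB", "September", "nonretention", 49, 441),
    ("SF-n", "May", "nonretention", 10, 37),
    ("SF-n", "June", "nonretention", 23, 87),
    ("SF-n", "July", "mixed", 9, 395),
    ("SF-n", "August", "nonretention", 22, 138),
    ("SF-n", "September", "nonretention", 13, 37),
    ("SF-s", "May", "nonretention", 27, 86),
    ("SF-s", "June", "nonretention", 78, 198),
    ("SF-s", "July", "mixed", 17, 99),
    ("SF-s", "August", "nonretention", 5, 114),
    ("SF-s", "September", "nonretention", 11, 70),
    ("MO-n", "May", "nonretention", 6, 11),
    ("MO-n", "June", "nonretention", 3, 17),
    ("MO-n", "July", "mixed", 16, 377),
    ("MO-n", "August", "nonretention", 34, 114),
    ("MO-n", "September", "nonretention", 42, 50),
    ("MO-s", "May", "nonretention", 0, 2),
    ("MO-s", "June", "nonretention", 0, 5),
    ("MO-s", "July", "mixed", 0, 13),
    ("MO-s", "August", "nonretention", 0, 9),
    ("MO-s", "September", "nonretention", 0, 16),
]

#: encounters excluded from CPUE calculations: eight NO/August fish were
#: collected by vessels whose effort logs were not part of this survey.
CPUE_EXCLUDED = {("NO", "August"): 8}


def vessel_days_table() -> pd.DataFrame:
    return pd.DataFrame(
        VESSEL_DAYS, columns=["area", "month", "technique", "vessel_days"]
    )


def encounters_table() -> pd.DataFrame:
    return pd.DataFrame(
        ENCOUNTERS, columns=["area", "month", "technique", "sublegal", "legal"]
    )


def legal_for_cpue() -> pd.DataFrame:
    """Legal encounter counts per (area, month) with the CPUE exclusions
    applied, merged across techniques."""
    df = encounters_table().groupby(["area", "month"], as_index=False)["legal"].sum()
    for (area, month), n in CPUE_EXCLUDED.items():
        sel = (df["area"] == area) & (df["month"] == month)
        df.loc[sel, "legal"] -= n
    return df


# -- 2010 commercial-fishery comparison totals ------------------------------
AT_SEA_TOTALS = {
    "landed_fish_or": 4482,
    "landed_fish_ca": 4402,
    "landed_fish_total": 8884,
    "vessel_effort_or": 1055,
    "vessel_effort_ca": 398,
    "vessel_effort_total": 1453,
    "vessel_days_nonzero_catch": 1113,
    "vessels_or": 78,
    "vessels_ca": 63,
    "vessels_total": 141,
}

COMMERCIAL_TOTALS = {
    "landed_fish_or": 26454,
    "landed_fish_ca": 15088,
    "landed_fish_total": 41542,
    "vessel_effort_or": 3428,
    "vessel_effort_ca": 1975,
    "vessel_effort_total": 5403,
    "vessels_or": 370,
    "vessels_ca": 215,
    "vessels_total": 585,
}

#: CWT validation worked example: of the tagged fish meeting the >=0.90
#: posterior criterion, 35 of 38 genetic assignments matched the tag.
CWT_EXAMPLE = {"compared": 38, "matching": 35}
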