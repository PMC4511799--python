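import datetime as dt

import numpy as np
import pandas as pd
import pytest

from sscpue.genotypes import GenotypeTable
from sscpue.simulate import SimulationConfig, simulate_study
from sscpue.strata import Area, StrataConfig


def make_genotype_table(genotypes, marker_type="microsat", meta=None, loci=None):
    """Build a GenotypeTable from {fish_id: {locus: (a, b) | None}}.

    ``meta`` optionally maps fish_id -> dict of metadata columns.
    """
    if loci is None:
        loci = sorted({l for g in genotypes.values() for l in g})
    rows = []
    for fid, g in genotypes.items():
        row = {"fish_id": fid}
        if meta and fid in meta:
            row.update(meta[fid])
        for locus in loci:
            pair = g.get(locus)
            row[f"{locus}_1"] = pair[0] if pair else pd.NA
            row[f"{locus}_2"] = pair[1] if pair else pd.NA
        rows.append(row)
    columns = ["fish_id"] + [f"{l}_{i}" for l in loci for i in (1, 2)]
    df = pd.DataFrame(rows) if rows else pd.DataFrame(columns=columns)
    return GenotypeTable(marker_type, loci, df)


@pytest.fixture
def two_band_strata():
    return StrataConfig(
        areas=[Area("N", 44.0, 46.0), Area("S", 42.0, 44.0)],
        season_start=dt.date(2010, 5, 1),
        season_end=dt.date(2010, 6, 30),
    )


def small_config(seed=0, **kwargs):
    """Two-area, two-month configuration for fast end-to-end tests."""
    strata = StrataConfig(
        areas=[Area("N", 44.0, 46.0), Area("S", 42.0, 44.0)],
        season_start=dt.date(2010, 5, 1),
        season_end=dt.date(2010, 6, 30),
    )
    defaults = dict(
        n_populations=4,
        n_loci=12,
        baseline_n_per_pop=120,
        strata=strata,
        months=["May", "June"],
        true_pi={
            ("May", "N"): np.array([0.5, 0.3, 0.15, 0.05]),
            ("May", "S"): np.array([0.1, 0.2, 0.3, 0.4]),
            ("June", "N"): np.array([0.4, 0.4, 0.1, 0.1]),
            ("June", "S"): np.array([0.05, 0.15, 0.3, 0.5]),
        },
        catch_intensity={("May", "N"): 5.0, ("May", "S"): 2.0,
                         ("June", "N"): 4.0, ("June", "S"): 3.0},
        effort_schedule={
            ("May", "N", "retention"): 15,
            ("May", "S", "nonretention"): 12,
            ("June", "N", "retention"): 15,
            ("June", "S", "nonretention"): 12,
        },
        seed=seed,
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_study():
    return simulate_study(small_config(seed=11))
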