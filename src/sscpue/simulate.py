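"""Synthetic baseline, mixture and fishery-effort data with ground truth.

The generator emulates the statistical structure the analysis assumes:

* baseline populations differentiated under the Balding-Nichols model —
  per-locus ancestral allele frequencies are drawn uniformly on the
  simplex and each population's frequencies from a Dirichlet centred on
  the ancestral vector with concentration (1-F)/F, so a single parameter
  F (an F_ST analogue) tunes how hard stock identification is;
* genotypes drawn under Hardy-Weinberg equilibrium with per-locus
  missingness, plus injected duplicate records (same fish re-entered
  under a new id) to exercise the dedupe filter;
* mixture fish drawn per month-area stratum from exogenous stock
  proportions that drift along the coast through the season;
* overdispersed daily catches — legal catch per vessel-day is negative
  binomial with mean set by the stratum's catch intensity and NB2
  dispersion theta (variance mu + mu^2/theta);
* GPS tracks as bounded random walks at the 5-minute fix cadence inside
  the day's latitude band, with a small fraction of days crossing into a
  neighbouring band to exercise the effort-allocation rules;
* sub-legal fish (non-retention days only) via a length distribution
  around a configurable legal threshold, and missing lengths on a
  fraction of non-retention fish to exercise legal-status imputation.

Default conditions mirror the 2010 survey: its nine latitude bands and
May-September season, its per-stratum vessel-day schedule, and its
observed per-stratum catch rates as the intensity surface.

Everything is deterministic given the configuration seed.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import survey2010
from .errors import ConfigError
from .genotypes import GenotypeTable
from .strata import MONTH_NAMES, StrataConfig

#: sub-legal encounters as a fraction of legal intensity on non-retention
#: days (retention fisheries record essentially none)
SUBLEGAL_RATIO = 0.25


def _default_reporting_groups(n_pops: int) -> dict[str, str]:
    """Two populations per reporting group, north-to-south order."""
    return {f"P{i+1:02d}": f"RG{i // 2 + 1}" for i in range(n_pops)}


def _default_true_pi(
    strata: StrataConfig, months: list[str], n_pops: int
) -> dict[tuple[str, str], np.ndarray]:
    """Latitudinal mixture gradient with slow seasonal drift.

    Population p is centred on area index h_p (spread north to south);
    its proportion in an area falls off as a Gaussian in area index, and
    the centres drift southward by 0.3 areas per month.
    """
    areas = strata.area_codes
    A = len(areas)
    homes = np.linspace(0, A - 1, n_pops)
    out = {}
    for mi, month in enumerate(months):
        for ai, area in enumerate(areas):
            w = np.exp(-0.5 * ((ai - homes - 0.3 * mi) / 1.5) ** 2) + 0.02
            out[(month, area)] = w / w.sum()
    return out


@dataclass
class SimulationConfig:
    n_populations: int = 10
    reporting_group_map: dict[str, str] = None
    n_loci: int = 20
    marker_type: str = "microsat"
    alleles_per_locus: int = 8
    differentiation: float = 0.1
    baseline_n_per_pop: int = 200
    strata: StrataConfig = None
    months: list[str] = None
    true_pi: dict = None                 # (month, area) -> prob vector
    catch_intensity: dict = None         # (month, area) -> mean legal catch/day
    dispersion: float = 1.0              # NB2 theta
    effort_schedule: dict = None         # (month, area, technique) -> vessel-days
    missing_locus_rate: float = 0.02
    missing_length_rate: float = 0.30
    duplicate_rate: float = 0.005
    near_duplicates: bool = False
    sublegal_ratio: float = SUBLEGAL_RATIO
    legal_threshold_mm: float = survey2010.LEGAL_LIMIT_MM
    fixes_per_day: int = 96
    cross_area_fraction: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if self.strata is None:
            self.strata = survey2010.strata_config()
        if self.months is None:
            self.months = list(self.strata.month_labels)
        if self.reporting_group_map is None:
            self.reporting_group_map = _default_reporting_groups(self.n_populations)
        if self.true_pi is None:
            self.true_pi = _default_true_pi(self.strata, self.months,
                                            self.n_populations)
        if self.effort_schedule is None:
            self.effort_schedule = {
                (month, area, tech): int(round(days))
                for area, month, tech, days in survey2010.VESSEL_DAYS
                if month in self.months and area in self.strata.area_codes
            }
        if self.catch_intensity is None:
            eff = {}
            cat = {}
            for area, month, _, days in survey2010.VESSEL_DAYS:
                eff[(month, area)] = eff.get((month, area), 0.0) + days
            legal = survey2010.legal_for_cpue()
            for row in legal.itertuples(index=False):
                cat[(row.month, row.area)] = row.legal
            self.catch_intensity = {
                k: cat.get(k, 0.0) / v for k, v in eff.items() if v > 0
                and k[0] in self.months and k[1] in self.strata.area_codes
            }
        self._validate()

    def _validate(self):
        if self.alleles_per_locus < 2:
            raise ConfigError("alleles_per_locus must be >= 2")
        if self.marker_type == "snp" and self.alleles_per_locus != 2:
            raise ConfigError("snp panels are biallelic")
        if not 0 < self.differentiation < 1:
            raise ConfigError("differentiation F must be in (0, 1)")
        if self.dispersion <= 0:
            raise ConfigError("dispersion theta must be > 0")
        for name in ("missing_locus_rate", "missing_length_rate", "duplicate_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1]")
        for key, pi in self.true_pi.items():
            pi = np.asarray(pi, float)
            if pi.shape != (self.n_populations,):
                raise ConfigError(f"true_pi[{key}] has wrong length")
            if abs(pi.sum() - 1.0) > 1e-12:
                raise ConfigError(f"true_pi[{key}] does not sum to 1")

    @property
    def populations(self) -> list[str]:
        return [f"P{i+1:02d}" for i in range(self.n_populations)]

    @property
    def loci(self) -> list[str]:
        return [f"L{j+1:02d}" for j in range(self.n_loci)]

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class TruthRecord:
    """Ground truth for recovery tests."""

    fish: pd.DataFrame         # fish_id, population, group, legal, month, area, ...
    strata: pd.DataFrame       # month, area, intensity + one pi column per pop
    vessel_days: pd.DataFrame  # vessel_id, date, month, area, technique, counts
    duplicates: dict           # injected duplicate id -> original fish_id

    def pi(self, month: str, area: str) -> np.ndarray:
        row = self.strata[(self.strata["month"] == month)
                          & (self.strata["area"] == area)].iloc[0]
        return row.filter(like="pi_").to_numpy(float)


# ---------------------------------------------------------------------------
# baseline

def simulate_baseline(config: SimulationConfig):
    """Baseline genotypes plus the generating allele frequencies.

    Returns ``(table, ancestral, pop_freqs)`` where ``ancestral`` maps
    locus -> ancestral frequency vector and ``pop_freqs`` maps locus ->
    (n_pops, n_alleles) per-population frequencies.
    """
    rng = config.rng(1)
    A = config.alleles_per_locus
    F = config.differentiation
    conc = (1.0 - F) / F
    ancestral, pop_freqs = {}, {}
    for locus in config.loci:
        anc = rng.dirichlet(np.ones(A))
        pop_freqs[locus] = rng.dirichlet(np.maximum(anc * conc, 1e-12),
                                         size=config.n_populations)
        ancestral[locus] = anc

    rows = []
    for pi_, pop in enumerate(config.populations):
        n = config.baseline_n_per_pop
        rec = {
            "fish_id": [f"B-{pop}-{k:04d}" for k in range(n)],
            "origin_label": pop,
            "reporting_group": config.reporting_group_map[pop],
        }
        for locus in config.loci:
            p = pop_freqs[locus][pi_]
            g = rng.choice(A, size=(n, 2), p=p / p.sum())
            rec[f"{locus}_1"] = [f"{a+1:03d}" for a in g[:, 0]]
            rec[f"{locus}_2"] = [f"{a+1:03d}" for a in g[:, 1]]
        rows.append(pd.DataFrame(rec))
    table = GenotypeTable(config.marker_type, config.loci,
                          pd.concat(rows, ignore_index=True))
    return table, ancestral, pop_freqs


# ---------------------------------------------------------------------------
# mixture season

def _month_dates(strata: StrataConfig, month: str) -> list[dt.date]:
    m = MONTH_NAMES.index(month)
    return [d for d in strata.season_dates() if d.month == m]


def _draw_genotypes(rng, pop_freqs, loci, pops_drawn, populations, A):
    """Vectorised Hardy-Weinberg genotype draw for a vector of true pops."""
    n = len(pops_drawn)
    out = {}
    for locus in loci:
        a1 = np.empty(n, dtype=np.int64)
        a2 = np.empty(n, dtype=np.int64)
        for pi_, pop in enumerate(populations):
            sel = np.flatnonzero(pops_drawn == pi_)
            if len(sel) == 0:
                continue
            p = pop_freqs[locus][pi_]
            p = p / p.sum()
            a1[sel] = rng.choice(A, size=len(sel), p=p)
            a2[sel] = rng.choice(A, size=len(sel), p=p)
        out[f"{locus}_1"] = np.array([f"{a+1:03d}" for a in a1], dtype=object)
        out[f"{locus}_2"] = np.array([f"{a+1:03d}" for a in a2], dtype=object)
    return out


def simulate_mixture_season(config: SimulationConfig, pop_freqs):
    """Season of mixture fish with per-stratum truth.

    Vessel-days follow the effort schedule; each day's legal catch is
    negative binomial (mean = the stratum's catch intensity, dispersion
    theta), each fish's true population is drawn from the stratum's
    mixture proportions, and genotypes follow Hardy-Weinberg at the true
    population's frequencies.  Returns ``(mixture_table, truth)``.
    """
    rng = config.rng(2)
    strata = config.strata
    theta = config.dispersion
    A = config.alleles_per_locus
    band = {a.code: a for a in strata.areas}

    vd_rows, fish_rows = [], []
    strat_seen = set()
    strat_rows = []
    fid = 0
    for (month, area, tech), n_days in sorted(config.effort_schedule.items()):
        if n_days <= 0:
            continue
        key = (month, area)
        if key not in config.true_pi:
            raise ConfigError(f"stratum {key} has no true_pi")
        pi = np.asarray(config.true_pi[key], float)
        mu = float(config.catch_intensity.get(key, 0.0))
        if key not in strat_seen:
            strat_seen.add(key)
            strat_rows.append({"month": month, "area": area, "intensity": mu,
                               **{f"pi_{p}": pi[i]
                                  for i, p in enumerate(config.populations)}})
        dates = _month_dates(strata, month)
        n_vessels = max(2, int(np.ceil(n_days / max(len(dates) - 2, 1))) + 1)
        slots = [(v, d) for v in range(n_vessels) for d in dates]
        pick = rng.choice(len(slots), size=n_days, replace=False)
        crossing = rng.random(n_days) < config.cross_area_fraction

        if mu > 0:
            legal_counts = rng.negative_binomial(theta, theta / (theta + mu),
                                                 size=n_days)
        else:
            legal_counts = np.zeros(n_days, dtype=int)
        if tech == "nonretention" and mu > 0:
            mus = config.sublegal_ratio * mu
            sub_counts = rng.negative_binomial(theta, theta / (theta + mus),
                                               size=n_days)
        else:
            sub_counts = np.zeros(n_days, dtype=int)

        for k, slot in enumerate(pick):
            v, date = slots[slot]
            vessel = f"V-{area}-{tech[:1]}{v:02d}"
            vd_rows.append({
                "vessel_id": vessel, "date": date, "month": month,
                "area": area, "technique": tech, "crossing": bool(crossing[k]),
                "n_legal": int(legal_counts[k]), "n_sublegal": int(sub_counts[k]),
            })
            n_fish = int(legal_counts[k] + sub_counts[k])
            if n_fish == 0:
                continue
            legal_flags = np.r_[np.ones(legal_counts[k], bool),
                                np.zeros(sub_counts[k], bool)]
            pops = rng.choice(config.n_populations, size=n_fish, p=pi)
            b = band[area]
            lats = rng.uniform(b.lat_min, b.lat_max, size=n_fish)
            lons = rng.uniform(-124.9, -121.2, size=n_fish)
            minutes = rng.integers(0, config.fixes_per_day * 5, size=n_fish)
            thr = config.legal_threshold_mm
            lengths = np.where(
                legal_flags,
                thr + np.abs(rng.normal(65.0, 55.0, n_fish)),
                thr - 5 - np.abs(rng.normal(55.0, 45.0, n_fish)),
            ).round(0)
            miss_len = (tech == "nonretention") & \
                (rng.random(n_fish) < config.missing_length_rate)
            for i in range(n_fish):
                fish_rows.append({
                    "fish_id": f"F{fid:06d}",
                    "population": config.populations[pops[i]],
                    "group": config.reporting_group_map[config.populations[pops[i]]],
                    "legal": bool(legal_flags[i]),
                    "length_mm": float(lengths[i]),
                    "length_missing": bool(miss_len[i]),
                    "month": month, "area": area, "date": date,
                    "time_min": int(minutes[i]),
                    "lat": float(lats[i]), "lon": float(lons[i]),
                    "vessel_id": vessel, "technique": tech,
                    "pop_index": int(pops[i]),
                })
                fid += 1

    fish_columns = [
        "fish_id", "population", "group", "legal", "length_mm",
        "length_missing", "month", "area", "date", "time_min",
        "lat", "lon", "vessel_id", "technique", "pop_index",
    ]
    fish = pd.DataFrame(fish_rows, columns=fish_columns)
    truth = TruthRecord(
        fish=fish,
        strata=pd.DataFrame(strat_rows),
        vessel_days=pd.DataFrame(vd_rows),
        duplicates={},
    )

    # genotypes for every real fish
    geno = _draw_genotypes(rng, pop_freqs, config.loci,
                           fish["pop_index"].to_numpy(), config.populations, A)
    data = {
        "fish_id": fish["fish_id"].to_numpy(),
        "date": fish["date"].to_numpy(),
        "lat": fish["lat"].to_numpy(),
        "lon": fish["lon"].to_numpy(),
        "vessel_id": fish["vessel_id"].to_numpy(),
        "length_mm": np.where(fish["length_missing"], np.nan,
                              fish["length_mm"].to_numpy()),
        "technique": fish["technique"].to_numpy(),
    }
    data.update(geno)
    df = pd.DataFrame(data)

    # per-locus missingness (both alleles dropped together)
    if config.missing_locus_rate > 0 and len(df):
        mask = rng.random((len(df), config.n_loci)) < config.missing_locus_rate
        for j, locus in enumerate(config.loci):
            df.loc[mask[:, j], [f"{locus}_1", f"{locus}_2"]] = pd.NA

    # inject duplicates: same genotypes under a fresh id
    n_dup = int(round(config.duplicate_rate * len(df)))
    if n_dup > 0:
        src = rng.choice(len(df), size=n_dup, replace=False)
        dups = df.iloc[src].copy()
        dup_ids = [f"D{fid + k:06d}" for k in range(n_dup)]
        truth.duplicates = dict(zip(dup_ids, dups["fish_id"]))
        dups["fish_id"] = dup_ids
        if config.near_duplicates:
            # perturb one typed locus so similarity is high but < 1
            for r in range(len(dups)):
                for locus in config.loci:
                    if pd.notna(dups.iloc[r][f"{locus}_1"]):
                        dups.iloc[r, dups.columns.get_loc(f"{locus}_1")] = "999"
                        dups.iloc[r, dups.columns.get_loc(f"{locus}_2")] = "999"
                        break
        df = pd.concat([df, dups], ignore_index=True)

    mixture = GenotypeTable(config.marker_type, config.loci, df)
    return mixture, truth


# ---------------------------------------------------------------------------
# effort and catch records

def _walk(rng, n, lo, hi, start=None, step=0.004):
    """Bounded 1-D random walk with reflection at [lo, hi]."""
    x = np.empty(n)
    x[0] = rng.uniform(lo, hi) if start is None else start
    steps = rng.normal(0.0, step, size=n - 1) if n > 1 else []
    for i, s in enumerate(steps):
        v = x[i] + s
        if v < lo:
            v = lo + (lo - v)
        if v > hi:
            v = hi - (v - hi)
        x[i + 1] = min(max(v, lo), hi)
    return x


def simulate_effort_catch(config: SimulationConfig, truth: TruthRecord):
    """GPS track logs and encounter records for the simulated season.

    Each vessel-day emits 5-minute fixes from a bounded random walk in
    its latitude band; crossing days split their fixes between the band
    and a neighbouring band (never reaching 85% in either).  Encounter
    records are exactly the fish in ``truth`` (injected genotype
    duplicates are lab artefacts, not extra encounters).
    """
    rng = config.rng(3)
    strata = config.strata
    areas = strata.areas
    idx = {a.code: i for i, a in enumerate(areas)}
    nfix = config.fixes_per_day

    fix_frames = []
    for day in truth.vessel_days.itertuples(index=False):
        b = areas[idx[day.area]]
        t0 = dt.datetime.combine(day.date, dt.time(6, 0))
        times = [t0 + dt.timedelta(minutes=5 * i) for i in range(nfix)]
        if day.crossing and len(areas) > 1:
            nb = areas[idx[day.area] - 1] if idx[day.area] > 0 else areas[1]
            n_out = int(round(rng.uniform(0.25, 0.75) * nfix))
            lat_out = _walk(rng, n_out, nb.lat_min, nb.lat_max)
            lat_in = _walk(rng, nfix - n_out, b.lat_min, b.lat_max)
            lat = np.r_[lat_out, lat_in]
        else:
            lat = _walk(rng, nfix, b.lat_min, b.lat_max)
        lon = _walk(rng, nfix, -124.9, -121.2)
        fix_frames.append(pd.DataFrame({
            "vessel_id": day.vessel_id, "timestamp": times,
            "lat": lat, "lon": lon, "technique": day.technique,
        }))
    fixes = (pd.concat(fix_frames, ignore_index=True)
             .sort_values(["vessel_id", "timestamp"], kind="stable")
             .reset_index(drop=True))

    f = truth.fish
    ts = [dt.datetime.combine(d, dt.time(6, 0)) + dt.timedelta(minutes=int(m))
          for d, m in zip(f["date"], f["time_min"])]
    encounters = pd.DataFrame({
        "fish_id": f["fish_id"],
        "vessel_id": f["vessel_id"],
        "timestamp": ts,
        "lat": f["lat"], "lon": f["lon"],
        "length_mm": np.where(f["length_missing"], np.nan, f["length_mm"]),
        "technique": f["technique"],
    })
    return fixes, encounters


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    baseline: GenotypeTable
    ancestral: dict
    pop_freqs: dict
    mixture: GenotypeTable
    truth: TruthRecord
    fixes: pd.DataFrame
    encounters: pd.DataFrame


def simulate_study(config: SimulationConfig | None = None, **kwargs) -> SimulatedStudy:
    """Run the whole generator: baseline, mixture season, tracks, catches."""
    if config is None:
        config = SimulationConfig(**kwargs)
    baseline, ancestral, pop_freqs = simulate_baseline(config)
    mixture, truth = simulate_mixture_season(config, pop_freqs)
    fixes, encounters = simulate_effort_catch(config, truth)
    return SimulatedStudy(config, baseline, ancestral, pop_freqs,
                          mixture, truth, fixes, encounters)
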