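"""End-to-end orchestration of the analysis stages.

Each stage function takes in-memory objects and returns DataFrames; the
``run_*`` wrappers also write the stage's standard output files.  The
CLI is a thin layer over these functions, and ``run_all`` chains them:

    simulate -> qc -> gsi -> effort -> cpue -> sscpue -> report
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import effort as eff
from . import glm as cpue_glm
from . import gsi as gsi_mod
from . import qc as qc_mod
from . import stats as sstats
from .genotypes import GenotypeTable
from .io import write_genotypes, write_strata_config
from .simulate import SimulatedStudy, SimulationConfig, simulate_study
from .strata import StrataConfig

log = logging.getLogger(__name__)


def _to_csv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def run_simulate(config: SimulationConfig, out_dir: Path) -> SimulatedStudy:
    study = simulate_study(config)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_genotypes(study.baseline, out_dir / "baseline.csv")
    write_genotypes(study.mixture, out_dir / "mixture.csv")
    _to_csv(study.fixes.drop(columns=["technique"]), out_dir / "tracks.csv")
    _to_csv(study.encounters, out_dir / "encounters.csv")
    _to_csv(study.truth.fish, out_dir / "truth.csv")
    write_strata_config(config.strata, out_dir / "strata.yaml")
    return study


def run_qc(mixture: GenotypeTable, out_dir: Path, **kwargs):
    filtered, report = qc_mod.run_qc(mixture, **kwargs)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_genotypes(filtered, out_dir / "mixture_filtered.csv")
    _to_csv(report.table, out_dir / "qc_report.csv")
    return filtered, report


def run_gsi(
    baseline: GenotypeTable,
    mixture: GenotypeTable,
    strata: StrataConfig,
    out_dir: Path,
    min_window_n: int = 5,
    oob_n_sim: int = 0,
    seed: int | None = None,
):
    bf = gsi_mod.estimate_frequencies(baseline, mixture)
    assignments = gsi_mod.sliding_window_run(
        mixture, bf, strata, min_window_n=min_window_n,
        oob_n_sim=oob_n_sim, seed=seed)
    composition = gsi_mod.collate_monthly_composition(assignments)
    out_dir.mkdir(parents=True, exist_ok=True)
    _to_csv(assignments, out_dir / "assignments.csv")
    _to_csv(composition, out_dir / "composition_month_area.csv")
    return assignments, composition


def run_effort(
    fixes: pd.DataFrame,
    encounters: pd.DataFrame,
    strata: StrataConfig,
    out_dir: Path,
    legal_threshold_mm: float = 686.0,
):
    enc = eff.annotate_legal(encounters, legal_threshold_mm)
    vessel_days = eff.build_vessel_days(fixes, enc, strata)
    enc_imputed, _ = eff.impute_legal(enc, strata)

    glm_week, rep_week = eff.glm_dataset(vessel_days, period="week")
    tables = {"vessel_days": vessel_days, "glm_dataset": glm_week}
    cpue = {}
    for period in ("week", "month"):
        effort_frac = eff.proportional_effort(vessel_days, period=period)
        catch = eff.catch_by_capture_area(enc_imputed, strata, period=period)
        cpue[period] = eff.stratum_cpue(effort_frac, catch, period=period)
    out_dir.mkdir(parents=True, exist_ok=True)
    vd_out = vessel_days.copy()
    vd_out["area_fractions"] = vd_out["area_fractions"].map(json.dumps)
    _to_csv(vd_out, out_dir / "vessel_days.csv")
    glm_out = glm_week.copy()
    glm_out["area_fractions"] = glm_out["area_fractions"].map(json.dumps)
    _to_csv(glm_out, out_dir / "glm_dataset.csv")
    _to_csv(cpue["week"], out_dir / "stratum_cpue_week.csv")
    _to_csv(cpue["month"], out_dir / "stratum_cpue_month.csv")
    return vessel_days, glm_week, cpue


def run_cpue_models(glm_data: pd.DataFrame, out_dir: Path) -> dict:
    """Count-GLM stage: family selection tests, term tests, cell means."""
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {}
    for period in ("month", "week"):
        seq = [(), (period,), (period, "area"), (period, "area", f"{period}:area")]
        try:
            fits = cpue_glm.fit_nested_sequence(glm_data, seq, family="negbin")
        except cpue_glm.SeparationError as e:
            log.warning("%s x area model skipped: %s", period, e)
            continue
        full = fits[-1]
        pois = cpue_glm.fit_count_glm(glm_data, terms=full.terms, family="poisson",
                                      compute_delta_aic=False)
        lrt = cpue_glm.overdispersion_lrt(pois, full)
        vuong = cpue_glm.vuong_test(pois, full)
        anova = cpue_glm.anova_terms(fits)
        cells = full.data[[period, "area"]].drop_duplicates().reset_index(drop=True)
        means = full.predict_mean(cells)
        mean_table = pd.concat([cells, means.reset_index(drop=True)], axis=1)
        _to_csv(mean_table, out_dir / f"mean_cpue_{period}.csv")
        summary[f"{period}_x_area"] = {
            "family": "negbin",
            "theta": full.theta,
            "aic": full.aic,
            "delta_aic_vs_null": full.aic - fits[0].aic,
            "null_aic": fits[0].aic,
            "deviance": full.deviance,
            "df_resid": full.df_resid,
            "overdispersion_lrt": {"statistic": lrt.statistic,
                                   "p_halved": lrt.p_value,
                                   "p_raw": lrt.extra["p_raw"]},
            "vuong_poisson_vs_negbin": {"statistic": vuong.statistic,
                                        "p": vuong.p_value,
                                        "direction": vuong.direction},
            "anova": [{"term": t.name, "deviance_decrease": t.statistic,
                       "df": t.df, "p": t.p_value} for t in anova],
        }
    with open(out_dir / "model_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary


def run_sscpue(
    composition: pd.DataFrame,
    cpue_month: pd.DataFrame,
    out_dir: Path,
    area_order=None,
    month_order=None,
) -> dict:
    table = sstats.sscpue_table(composition, cpue_month)
    richness = sstats.stock_richness(composition)
    kendall = sstats.correlation_report(table)
    out_dir.mkdir(parents=True, exist_ok=True)
    _to_csv(table, out_dir / "sscpue_month_area.csv")
    _to_csv(richness, out_dir / "richness.csv")
    _to_csv(kendall, out_dir / "kendall_results.csv")
    grid_dir = out_dir / "log_grids"
    grid_dir.mkdir(exist_ok=True)
    all_cpue = table.drop_duplicates(["month", "area"])[["month", "area", "cpue"]]
    g = sstats.log_grid(all_cpue, value="cpue",
                        period_order=month_order, area_order=area_order)
    g.to_csv(grid_dir / "all_stocks.csv")
    for group, sub in table.groupby("group"):
        if not sub["displayed"].any():
            continue
        g = sstats.log_grid(sub, value="sscpue",
                            period_order=month_order, area_order=area_order)
        g.to_csv(grid_dir / f"{group}.csv")
    return {"table": table, "richness": richness, "kendall": kendall}


def run_all(config: SimulationConfig, out_dir: Path,
            oob_n_sim: int = 0) -> dict:
    """Full synthetic pipeline; returns the main in-memory results."""
    out_dir = Path(out_dir)
    study = run_simulate(config, out_dir)
    strata = config.strata

    # composition uses legal-sized fish: drop known sub-legal before GSI
    known_sub = study.mixture.data["length_mm"].notna() & \
        (study.mixture.data["length_mm"] < config.legal_threshold_mm)
    mixture_legal = study.mixture.subset(~known_sub.to_numpy())
    filtered, qc_report = run_qc(mixture_legal, out_dir)
    assignments, composition = run_gsi(
        study.baseline, filtered, strata, out_dir,
        oob_n_sim=oob_n_sim, seed=config.seed)
    vessel_days, glm_data, cpue = run_effort(
        study.fixes, study.encounters, strata, out_dir,
        legal_threshold_mm=config.legal_threshold_mm)
    models = run_cpue_models(glm_data, out_dir)
    ss = run_sscpue(composition, cpue["month"], out_dir,
                    area_order=strata.area_codes,
                    month_order=config.months)

    report = {
        "n_baseline_fish": study.baseline.n_fish,
        "n_mixture_fish": study.mixture.n_fish,
        "n_after_qc": filtered.n_fish,
        "n_removed_qc": qc_report.n_removed,
        "n_vessel_days": len(vessel_days),
        "n_encounters": len(study.encounters),
        "mean_cpue": float(np.nanmean(cpue["month"]["cpue"])),
        "n_strata": int(len(cpue["month"])),
        "mean_richness": float(ss["richness"]["richness"].mean()),
    }
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return {"study": study, "filtered": filtered, "assignments": assignments,
            "composition": composition, "vessel_days": vessel_days,
            "glm_dataset": glm_data, "cpue": cpue, "models": models,
            "sscpue": ss, "report": report}
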