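"""Stock-specific CPUE, richness, log-grids and rank-correlation scans.

The headline statistic is stock-specific catch per unit effort:

    SSCPUE_{i,j} = composition_{i,j} x CPUE_j

for stock (reporting group) i in month-area stratum j, where the
composition is the stock's estimated proportion of the stratum's sample
and CPUE is legal encounters per vessel-day.  SSCPUE partitions the
stratum's catch rate across stocks, so it sums back to the stratum CPUE
and — unlike composition — is unaffected by how abundant the *other*
stocks are, making it comparable across strata.

Composition and SSCPUE are compared with Kendall's tau-b rank
correlation, first on all non-zero pairs, then under an increasing
stock-composition threshold to find the point where the correlation
loses significance (locally rare stocks, always jointly low-ranked on
both axes, otherwise inflate tau).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


def sscpue_table(
    composition: pd.DataFrame,
    cpue: pd.DataFrame,
    period: str = "month",
    min_strata_displayed: int = 4,
) -> pd.DataFrame:
    """Join composition and stratum CPUE into the SSCPUE table.

    ``composition`` has [period, area, group, proportion]; ``cpue`` has
    [period, area, cpue].  Output adds ``sscpue = proportion * cpue`` and
    a ``displayed`` flag that is False for groups contributing to fewer
    than ``min_strata_displayed`` strata (rare groups are hidden from
    display output but retained in the table).  Raises KeyError if a
    composition stratum lacks a CPUE value.
    """
    tab = composition.merge(cpue[[period, "area", "cpue"]],
                            on=[period, "area"], how="left")
    if tab["cpue"].isna().any():
        missing = tab.loc[tab["cpue"].isna(), [period, "area"]].drop_duplicates()
        raise KeyError(f"composition strata without CPUE: {missing.to_dict('records')}")
    tab["sscpue"] = tab["proportion"] * tab["cpue"]
    strata_per_group = (tab[tab["proportion"] > 0]
                        .groupby("group")[[period, "area"]]
                        .apply(lambda g: g.drop_duplicates().shape[0]))
    tab["displayed"] = tab["group"].map(
        lambda g: bool(strata_per_group.get(g, 0) >= min_strata_displayed))
    return tab


def stock_richness(composition: pd.DataFrame, period: str = "month") -> pd.DataFrame:
    """Number of reporting groups with non-zero composition per stratum."""
    nz = composition[composition["proportion"] > 0]
    rich = (nz.groupby([period, "area"]).size()
            .rename("richness").reset_index())
    return rich


def log_grid(
    values: pd.DataFrame,
    period: str = "month",
    value: str = "sscpue",
    period_order=None,
    area_order=None,
    mask_missing: bool = True,
) -> pd.DataFrame:
    """Month x area grid of natural-log values for contour export.

    Rows are areas north to south, columns the ordered periods.  Zero and
    missing cells become NaN when ``mask_missing`` (otherwise zeros raise,
    since log 0 is not exportable, and missing cells are left for the
    plotting layer to interpolate).  Negative values always raise.
    """
    v = values[[period, "area", value]].copy()
    if (v[value] < 0).any():
        raise ValueError("negative value in log grid input")
    grid = v.pivot_table(index="area", columns=period, values=value,
                         aggfunc="sum")
    if area_order is not None:
        grid = grid.reindex(area_order)
    if period_order is not None:
        grid = grid.reindex(columns=period_order)
    arr = grid.to_numpy(float)
    if mask_missing:
        arr = np.where(arr > 0, arr, np.nan)
    elif (arr == 0).any():
        raise ValueError("zero cell with masking disabled")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = pd.DataFrame(np.log(arr), index=grid.index, columns=grid.columns)
    out.index.name = "area"
    out.columns.name = period
    return out


@dataclass
class KendallResult:
    tau: float
    p_value: float
    n_pairs: int
    threshold: float | None = None
    stock: str = "all"
    tau_a: float | None = None

    def significant(self, alpha: float = 0.05) -> bool:
        return bool(self.p_value <= alpha)


def kendall_tau(x, y, stock: str = "all") -> KendallResult:
    """Kendall's tau-b with a two-sided p-value.

    Tie-adjusted tau-b (ties are certain with composition data); the
    p-value is exact for small untied samples and uses the tie-corrected
    normal approximation otherwise.  An all-tied axis yields NaN.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2:
        raise ValueError("need at least two pairs")
    if len(set(x)) < 2 or len(set(y)) < 2:
        return KendallResult(np.nan, np.nan, len(x), stock=stock)
    res = sps.kendalltau(x, y)
    n = len(x)
    conc = 0
    for i in range(n):
        conc += int(np.sum(np.sign(x[i+1:] - x[i]) * np.sign(y[i+1:] - y[i])))
    tau_a = conc / (n * (n - 1) / 2)
    return KendallResult(float(res.statistic), float(res.pvalue), n,
                         stock=stock, tau_a=float(tau_a))


@dataclass
class ThresholdScan:
    result: KendallResult | None      # first non-significant threshold, or None
    trace: pd.DataFrame               # threshold, tau, p_value, n_pairs


def threshold_scan(
    composition,
    sscpue,
    alpha: float = 0.05,
    min_pairs: int = 5,
    stock: str = "all",
) -> ThresholdScan:
    """Find the composition threshold where tau loses significance.

    Input pairs should already be the "full data set" (non-zero on both
    axes).  Candidate thresholds are the sorted distinct composition
    values; at each, pairs with composition >= threshold are retained and
    tau-b recomputed.  The reported result is the smallest threshold with
    p > alpha; the full trace is returned either way.  If no threshold
    turns non-significant before fewer than ``min_pairs`` pairs remain,
    ``result`` is None (undefined).

    ``min_pairs`` defaults to 5 because below that the exact test cannot
    reach p <= 0.05 even for a perfect ordering (n = 4 fully concordant
    pairs give p = 1/12), so smaller tails measure power loss rather
    than decoupling.
    """
    comp = np.asarray(composition, float)
    ss = np.asarray(sscpue, float)
    rows = []
    hit = None
    for thr in np.unique(comp):
        keep = comp >= thr
        if keep.sum() < min_pairs:
            break
        r = kendall_tau(comp[keep], ss[keep], stock=stock)
        r.threshold = float(thr)
        rows.append({"threshold": float(thr), "tau": r.tau,
                     "tau_a": r.tau_a, "p_value": r.p_value,
                     "n_pairs": r.n_pairs})
        if hit is None and not np.isnan(r.p_value) and r.p_value > alpha:
            hit = r
    trace = pd.DataFrame(rows, columns=["threshold", "tau", "tau_a",
                                        "p_value", "n_pairs"])
    return ThresholdScan(result=hit, trace=trace)


def composition_sscpue_pairs(
    table: pd.DataFrame, stock: str | None = None, period: str = "month"
) -> pd.DataFrame:
    """Non-zero (composition, SSCPUE) pairs from an SSCPUE table, for all
    stocks pooled or one stock."""
    t = table if stock is None else table[table["group"] == stock]
    t = t[(t["proportion"] > 0) & (t["sscpue"] > 0)]
    return t[[period, "area", "group", "proportion", "sscpue"]].reset_index(drop=True)


def correlation_report(
    table: pd.DataFrame,
    stocks=None,
    alpha: float = 0.05,
    period: str = "month",
) -> pd.DataFrame:
    """Full-set and threshold-set tau for all stocks pooled and per stock.

    One row per analysis: full tau/p, tau/p at the first non-significant
    threshold, and the minimum retained composition (as a percentage),
    mirroring the standard composition-vs-SSCPUE comparison layout.
    """
    analyses = [("all", None)]
    if stocks is None:
        stocks = sorted(table.loc[table["displayed"], "group"].unique()) \
            if "displayed" in table else sorted(table["group"].unique())
    analyses += [(s, s) for s in stocks]
    rows = []
    for label, stock in analyses:
        pairs = composition_sscpue_pairs(table, stock, period)
        if len(pairs) < 3:
            continue
        full = kendall_tau(pairs["proportion"], pairs["sscpue"], stock=label)
        scan = threshold_scan(pairs["proportion"], pairs["sscpue"],
                              alpha=alpha, stock=label)
        hit = scan.result
        rows.append({
            "stock": label,
            "tau_full": full.tau, "p_full": full.p_value,
            "n_full": full.n_pairs,
            "tau_threshold": hit.tau if hit else np.nan,
            "p_threshold": hit.p_value if hit else np.nan,
            "min_pct_composition": 100 * hit.threshold if hit else np.nan,
            "n_threshold": hit.n_pairs if hit else np.nan,
        })
    return pd.DataFrame(rows)
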