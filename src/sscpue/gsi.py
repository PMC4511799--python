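"""Conditional mixture-model genetic stock identification.

The mixture of fishery-caught fish is modelled as draws from baseline
populations: fish i carries multilocus genotype y_i, population j has
posterior-mean allele frequencies f_j, and the sampling proportions pi
are unknown.  Under Hardy-Weinberg equilibrium within populations and
independence across loci,

    L_ij = P(y_i | pop j) = prod_l f_j(a)^2  (homozygote a/a)
                                or 2 f_j(a) f_j(b)  (heterozygote a/b),

and the observed-data log-likelihood sum_i log sum_j pi_j L_ij is
maximised over pi by EM.  Individual fish are then assigned by the
posterior Z_ij = pi_j L_ij / sum_k pi_k L_ik, aggregated to reporting
groups (management-level clusters of genetically similar populations).

Baseline allele frequencies use the posterior mean under a symmetric
Dirichlet prior of total mass 1 spread over the allele registry
(1/A per allele), so alleles observed only in the mixture still have
positive likelihood in every population.

The season is analysed with a sliding weekly window: the mixture
proportions fitted to each area's fish from the focal week plus its two
neighbouring weeks act as the prior for the focal week's individual
posteriors, letting assignments track week-scale shifts in stock
composition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GSIError
from .genotypes import GenotypeTable
from .strata import StrataConfig

log = logging.getLogger(__name__)

LOG2 = np.log(2.0)


@dataclass
class BaselineFrequencies:
    """Posterior allele frequencies per population and locus."""

    loci: list[str]
    registry: dict[str, list[str]]          # locus -> ordered allele labels
    populations: list[str]
    freqs: dict[str, np.ndarray]            # locus -> (n_pops, n_alleles)
    gene_counts: dict[str, np.ndarray]      # locus -> typed gene copies per pop
    reporting_groups: dict[str, str]        # population -> group

    @property
    def n_pops(self) -> int:
        return len(self.populations)

    @property
    def group_names(self) -> list[str]:
        seen = []
        for p in self.populations:
            g = self.reporting_groups.get(p, p)
            if g not in seen:
                seen.append(g)
        return seen

    def group_matrix(self) -> np.ndarray:
        """(n_pops, n_groups) 0/1 membership matrix."""
        groups = self.group_names
        gi = {g: k for k, g in enumerate(groups)}
        M = np.zeros((self.n_pops, len(groups)))
        for i, p in enumerate(self.populations):
            M[i, gi[self.reporting_groups.get(p, p)]] = 1.0
        return M


def estimate_frequencies(
    baseline: GenotypeTable,
    mixture: GenotypeTable | None = None,
    reporting_groups: dict[str, str] | None = None,
) -> BaselineFrequencies:
    """Posterior-mean allele frequencies from a baseline table.

    For population p, locus l with allele registry of size A:

        f(a) = (count of allele a in p at l + 1/A) / (n typed copies + 1)

    The registry is the union of alleles seen in the baseline and, when
    given, the mixture, so mixture-only alleles carry prior mass only.
    """
    registry = baseline.allele_registry()
    if mixture is not None:
        if mixture.loci != baseline.loci:
            raise ValueError("mixture and baseline locus lists differ")
        mreg = mixture.allele_registry()
        registry = {l: sorted(set(registry[l]) | set(mreg[l])) for l in baseline.loci}
    for locus, alleles in registry.items():
        if not alleles:
            raise ValueError(f"locus {locus!r}: empty allele registry")

    pops = list(dict.fromkeys(baseline.data["origin_label"].dropna()))
    if not pops:
        raise ValueError("baseline has no origin labels")
    pop_index = {p: i for i, p in enumerate(pops)}
    rows = baseline.data["origin_label"].map(pop_index).to_numpy()

    c1, c2 = baseline.coded(registry)
    freqs, counts = {}, {}
    for j, locus in enumerate(baseline.loci):
        A = len(registry[locus])
        tab = np.zeros((len(pops), A))
        typed = c1[:, j] >= 0
        np.add.at(tab, (rows[typed], c1[typed, j]), 1.0)
        np.add.at(tab, (rows[typed], c2[typed, j]), 1.0)
        n = tab.sum(axis=1)
        freqs[locus] = (tab + 1.0 / A) / (n + 1.0)[:, None]
        counts[locus] = n

    if reporting_groups is None:
        rg = baseline.data.groupby("origin_label")["reporting_group"].first()
        reporting_groups = {
            p: (rg.get(p) if pd.notna(rg.get(p)) else p) for p in pops
        }
    return BaselineFrequencies(
        loci=list(baseline.loci), registry=registry, populations=pops,
        freqs=freqs, gene_counts=counts, reporting_groups=reporting_groups,
    )


def genotype_loglik(
    genotype: dict[str, tuple | None],
    pop_freqs: dict[str, np.ndarray],
    registry: dict[str, list[str]],
) -> float:
    """Hardy-Weinberg log-likelihood of one fish under one population.

    ``genotype`` maps locus -> (allele, allele) or None for missing;
    missing loci contribute zero.
    """
    ll = 0.0
    for locus, pair in genotype.items():
        if pair is None:
            continue
        labels = registry[locus]
        try:
            ia, ib = labels.index(pair[0]), labels.index(pair[1])
        except ValueError as e:
            raise KeyError(f"allele not in registry at {locus!r}: {e}") from None
        f = pop_freqs[locus]
        if ia == ib:
            ll += 2.0 * np.log(f[ia])
        else:
            ll += np.log(2.0) + np.log(f[ia]) + np.log(f[ib])
    return float(ll)


def loglik_matrix(mixture: GenotypeTable, bf: BaselineFrequencies) -> np.ndarray:
    """(n_fish, n_pops) genotype log-likelihood matrix."""
    c1, c2 = mixture.coded(bf.registry)
    n, P = mixture.n_fish, bf.n_pops
    LL = np.zeros((n, P))
    for j, locus in enumerate(bf.loci):
        logf = np.log(bf.freqs[locus])          # (P, A)
        typed = c1[:, j] >= 0
        if not typed.any():
            continue
        a, b = c1[typed, j], c2[typed, j]
        contrib = logf[:, a] + logf[:, b]       # (P, n_typed)
        contrib[:, a != b] += LOG2
        LL[typed] += contrib.T
    return LL


@dataclass
class MixtureEstimate:
    populations: list[str]
    pi: np.ndarray                    # (n_pops,)
    posteriors: np.ndarray            # (n_fish, n_pops)
    group_posteriors: pd.DataFrame    # n_fish x groups
    loglik_trace: np.ndarray
    converged: bool
    n_iterations: int


def fit_mixture_em(
    loglik: np.ndarray,
    populations: list[str] | None = None,
    group_matrix: np.ndarray | None = None,
    group_names: list[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 10000,
) -> MixtureEstimate:
    """Maximum-likelihood mixture proportions by EM.

    Starts from uniform pi.  E-step: Z_ij proportional to pi_j exp(LL_ij),
    row-normalised via log-sum-exp; M-step: pi_j = mean_i Z_ij.  Stops
    when max |delta pi| < tol.
    """
    LL = np.asarray(loglik, dtype=float)
    if LL.ndim != 2 or LL.size == 0:
        raise ValueError("loglik must be a non-empty 2-D array")
    n, P = LL.shape
    dead = np.all(np.isneginf(LL), axis=1)
    if dead.any():
        i = int(np.flatnonzero(dead)[0])
        raise GSIError(f"fish at row {i} has -inf likelihood under every population")
    if populations is None:
        populations = [f"pop{j}" for j in range(P)]

    pi = np.full(P, 1.0 / P)
    trace = []
    converged = False
    it = 0
    Z = np.empty_like(LL)
    for it in range(1, max_iter + 1):
        logw = LL + np.log(pi)
        m = logw.max(axis=1, keepdims=True)
        w = np.exp(logw - m)
        s = w.sum(axis=1, keepdims=True)
        Z = w / s
        trace.append(float((m[:, 0] + np.log(s[:, 0])).sum()))
        new_pi = Z.mean(axis=0)
        if np.max(np.abs(new_pi - pi)) < tol:
            pi = new_pi
            converged = True
            break
        pi = new_pi
    # posteriors under the final pi
    logw = LL + np.log(pi)
    m = logw.max(axis=1, keepdims=True)
    w = np.exp(logw - m)
    Z = w / w.sum(axis=1, keepdims=True)

    if group_matrix is None:
        group_matrix = np.eye(P)
        group_names = list(populations)
    gp = pd.DataFrame(Z @ group_matrix, columns=group_names)
    return MixtureEstimate(
        populations=list(populations), pi=pi, posteriors=Z,
        group_posteriors=gp, loglik_trace=np.array(trace),
        converged=converged, n_iterations=it,
    )


def posteriors_under_pi(loglik: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Individual posteriors for fixed mixture proportions."""
    logw = np.asarray(loglik) + np.log(np.asarray(pi))
    m = logw.max(axis=1, keepdims=True)
    w = np.exp(logw - m)
    return w / w.sum(axis=1, keepdims=True)


def sliding_window_run(
    mixture: GenotypeTable,
    bf: BaselineFrequencies,
    strata: StrataConfig,
    min_window_n: int = 5,
    oob_n_sim: int = 0,
    seed: int | None = None,
    tol: float = 1e-8,
) -> pd.DataFrame:
    """Sliding-window GSI over the season, one fit per (area, focal week).

    Each area's fish from weeks {w-1, w, w+1} (truncated at the season
    edges) are pooled and the mixture proportions fitted by EM; the
    fitted pi then serves as the prior for the focal week's individual
    posteriors.  Windows holding fewer than ``min_window_n`` fish are
    widened symmetrically one week at a time.  Optionally scores each
    fish's fit to its best population against ``oob_n_sim`` simulated
    genotypes (out-of-baseline screen).

    Returns one row per fish: fish_id, week, month, area, assigned group,
    max group posterior, and the out-of-baseline percentile (NaN when the
    screen is off).  Argmax ties break toward the earlier-listed group.
    """
    meta = mixture.data
    dates = pd.to_datetime(meta["date"]).dt.date
    weeks = np.array([strata.week_of(d) for d in dates])
    months = np.array([strata.month_of(d) for d in dates])
    areas = np.array([strata.area_of(la) for la in meta["lat"].astype(float)],
                     dtype=object)
    if any(a is None for a in areas):
        raise ValueError("mixture contains fish outside all area bands")

    LL = loglik_matrix(mixture, bf)
    GM = bf.group_matrix()
    gnames = bf.group_names
    rng = np.random.default_rng(seed)

    records = []
    for area in pd.unique(areas):
        in_area = areas == area
        area_weeks = np.unique(weeks[in_area])
        wmin, wmax = area_weeks.min(), area_weeks.max()
        for w in area_weeks:
            focal = in_area & (weeks == w)
            half = 1
            while True:
                lo = max(w - half, wmin)
                hi = min(w + half, wmax)
                window = in_area & (weeks >= lo) & (weeks <= hi)
                if window.sum() >= min_window_n or (lo == wmin and hi == wmax):
                    break
                half += 1
                log.info("area %s week %s: widened window to +/-%d weeks",
                         area, w, half)
            est = fit_mixture_em(LL[window], bf.populations, tol=tol)
            Z = posteriors_under_pi(LL[focal], est.pi)
            G = Z @ GM
            best = np.argmax(G, axis=1)  # ties -> earlier (more northern) group
            idx = np.flatnonzero(focal)
            for k, row in enumerate(idx):
                oob = np.nan
                if oob_n_sim > 0:
                    best_pop = int(np.argmax(LL[row]))
                    oob = out_of_baseline_score(
                        mixture, int(row), bf, best_pop, oob_n_sim, rng)
                records.append({
                    "fish_id": meta["fish_id"].iloc[row],
                    "week": int(w),
                    "month": months[row],
                    "area": area,
                    "group": gnames[best[k]],
                    "posterior": float(G[k, best[k]]),
                    "oob_percentile": oob,
                })
    return pd.DataFrame.from_records(records)


def collate_monthly_composition(assignments: pd.DataFrame) -> pd.DataFrame:
    """Hard-assignment stock composition per (month, area).

    proportion = assigned fish in group / total assigned fish in the
    stratum; strata with zero fish are absent.
    """
    counts = (assignments.groupby(["month", "area", "group"])
              .size().rename("n").reset_index())
    totals = counts.groupby(["month", "area"])["n"].transform("sum")
    counts["proportion"] = counts["n"] / totals
    return counts


def out_of_baseline_score(
    mixture: GenotypeTable,
    row: int,
    bf: BaselineFrequencies,
    best_pop: int,
    n_sim: int,
    rng: np.random.Generator,
) -> float:
    """Percentile of a fish's log-likelihood among genotypes simulated
    from its best-fitting population.

    ``n_sim`` genotypes are drawn under Hardy-Weinberg from the best
    population's frequencies at the fish's typed loci; the score is the
    fraction of simulated log-likelihoods strictly below the observed
    one.  Scores near zero flag fish whose genotypes fit the baseline
    poorly and may come from an unrepresented stock.
    """
    if n_sim <= 0:
        raise ValueError("n_sim must be positive")
    c1, c2 = mixture.coded(bf.registry)
    obs = 0.0
    sim = np.zeros(n_sim)
    for j, locus in enumerate(bf.loci):
        if c1[row, j] < 0:
            continue
        logf = np.log(bf.freqs[locus][best_pop])
        a, b = c1[row, j], c2[row, j]
        obs += logf[a] + logf[b] + (LOG2 if a != b else 0.0)
        f = bf.freqs[locus][best_pop]
        p = f / f.sum()
        g1 = rng.choice(len(p), size=n_sim, p=p)
        g2 = rng.choice(len(p), size=n_sim, p=p)
        sim += logf[g1] + logf[g2] + np.where(g1 != g2, LOG2, 0.0)
    return float(np.mean(sim < obs))


def cwt_concordance(
    assignments: pd.DataFrame,
    cwt_labels: dict[str, str],
    posterior_min: float = 0.90,
) -> dict:
    """Concordance between genetic assignments and coded-wire-tag origins.

    Restricts to fish with a tag label and assignment posterior >=
    ``posterior_min``; concordance = matches / compared.  Returns the
    overall proportion plus a per-group breakdown; ``proportion`` is NaN
    when no fish survive the filter.
    """
    sub = assignments[assignments["fish_id"].isin(cwt_labels)]
    sub = sub[sub["posterior"] >= posterior_min]
    compared = len(sub)
    if compared == 0:
        return {"compared": 0, "matching": 0, "proportion": float("nan"),
                "by_group": pd.DataFrame(columns=["group", "compared", "matching"])}
    truth = sub["fish_id"].map(cwt_labels)
    match = (sub["group"].to_numpy() == truth.to_numpy())
    by_group = (pd.DataFrame({"group": truth, "match": match})
                .groupby("group")
                .agg(compared=("match", "size"), matching=("match", "sum"))
                .reset_index())
    return {
        "compared": compared,
        "matching": int(match.sum()),
        "proportion": float(match.mean()),
        "by_group": by_group,
    }
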