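"""Sample-quality filters for genotype tables.

Three filters are applied, in a fixed order, before stock identification:

1. species exclusion (fish flagged as the wrong species by the baseline,
   e.g. coho genotypes in a Chinook panel, handled as an id list);
2. duplicate-genotype removal — pairs of fish whose multilocus genotypes
   match at more than 90% of co-typed loci are collapsed to one fish,
   since re-sampling the same individual would bias composition;
3. per-fish data-quality thresholds — a minimum number of typed loci
   (microsatellite panels), or a missing-loci cap plus observed
   heterozygosity bounds guarding against allelic dropout and
   contamination (SNP panels).

Similarity is genotype matching over co-typed loci only, so it does not
depend on how much data either fish is missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeTable

#: default thresholds, expressed at the panel sizes they were defined for
MICROSAT_MIN_TYPED = 7      # of 13 loci
MICROSAT_PANEL = 13
SNP_MAX_MISSING = 20        # of 96 loci
SNP_PANEL = 96
HET_LOW = 0.16
HET_HIGH = 0.56
SIMILARITY_THRESHOLD = 0.90

REMOVAL_REASONS = (
    "duplicate", "too_few_loci", "low_het", "high_het", "species_excluded", "none",
)


@dataclass
class QCReport:
    """Per-fish retention decisions with reasons."""

    table: pd.DataFrame
    # columns: fish_id, retained, removal_reason, similarity_partner, observed_het

    @property
    def n_removed(self) -> int:
        return int((~self.table["retained"]).sum())

    def removed(self, reason: str | None = None) -> pd.DataFrame:
        out = self.table[~self.table["retained"]]
        if reason is not None:
            out = out[out["removal_reason"] == reason]
        return out


def genotype_similarity(table: GenotypeTable, i: int, j: int) -> tuple[float, int]:
    """Fraction of co-typed loci with identical unordered allele pairs.

    Returns ``(similarity, n_cotyped)``; similarity is NaN when the two
    fish share no typed loci.
    """
    sim, cot = _pairwise_similarity(table, [i], [j])
    return float(sim[0, 0]), int(cot[0, 0])


def _encode(table: GenotypeTable) -> tuple[np.ndarray, np.ndarray]:
    """Hash each unordered genotype into one int per (fish, locus).

    -1 marks a missing locus.  Equal hashes <=> equal unordered pairs
    because the pair is canonicalised before hashing.
    """
    reg = table.allele_registry()
    c1, c2 = table.coded(reg)
    width = max((len(v) for v in reg.values()), default=1) + 1
    code = c1.astype(np.int64) * width + c2
    code[c1 < 0] = -1
    return code, c1 >= 0


def _pairwise_similarity(table, rows, cols):
    code, typed = _encode(table)
    a, ta = code[rows], typed[rows]
    b, tb = code[cols], typed[cols]
    both = ta[:, None, :] & tb[None, :, :]
    match = (a[:, None, :] == b[None, :, :]) & both
    cot = both.sum(axis=2)
    with np.errstate(invalid="ignore"):
        sim = np.where(cot > 0, match.sum(axis=2) / np.maximum(cot, 1), np.nan)
    return sim, cot


def duplicate_pairs(
    table: GenotypeTable,
    threshold: float = SIMILARITY_THRESHOLD,
    min_cotyped: int = 1,
    block: int = 512,
) -> list[tuple[int, int]]:
    """Row-index pairs (i < j) with similarity strictly above ``threshold``
    and at least ``min_cotyped`` co-typed loci."""
    code, typed = _encode(table)
    n = table.n_fish
    pairs = []
    for start in range(0, n, block):
        stop = min(start + block, n)
        a, ta = code[start:stop], typed[start:stop]
        both = ta[:, None, :] & typed[None, :, :]
        match = (a[:, None, :] == code[None, :, :]) & both
        cot = both.sum(axis=2)
        nmatch = match.sum(axis=2)
        ok = (cot >= min_cotyped) & (nmatch > threshold * cot) & (cot > 0)
        ii, jj = np.nonzero(ok)
        for i, j in zip(ii + start, jj):
            if i < j:
                pairs.append((int(i), int(j)))
    return pairs


def deduplicate(
    table: GenotypeTable,
    threshold: float = SIMILARITY_THRESHOLD,
    min_cotyped: int = 1,
) -> tuple[GenotypeTable, QCReport]:
    """Collapse clusters of (near-)identical genotypes to one fish each.

    Pairs above the similarity threshold are clustered transitively; in
    each cluster the fish with the most typed loci is retained (ties go
    to the lexicographically earliest fish_id).  Idempotent.
    """
    pairs = duplicate_pairs(table, threshold, min_cotyped)
    parent = list(range(table.n_fish))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in pairs:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    clusters: dict[int, list[int]] = {}
    for i in range(table.n_fish):
        clusters.setdefault(find(i), []).append(i)

    n_typed = table.n_typed()
    ids = table.fish_ids
    removed: dict[int, int] = {}  # row -> kept partner row
    for members in clusters.values():
        if len(members) < 2:
            continue
        keep = min(members, key=lambda r: (-n_typed[r], ids.iloc[r]))
        for r in members:
            if r != keep:
                removed[r] = keep

    report = pd.DataFrame({
        "fish_id": ids.to_numpy(),
        "retained": [r not in removed for r in range(table.n_fish)],
        "removal_reason": ["duplicate" if r in removed else "none"
                           for r in range(table.n_fish)],
        "similarity_partner": [ids.iloc[removed[r]] if r in removed else ""
                               for r in range(table.n_fish)],
        "observed_het": table.het_fraction(),
    })
    keep_mask = report["retained"].to_numpy()
    return table.subset(keep_mask), QCReport(report)


def microsat_min_typed(n_loci: int) -> int:
    """Minimum typed-locus count, scaled from 7-of-13."""
    return math.ceil(MICROSAT_MIN_TYPED / MICROSAT_PANEL * n_loci)


def snp_max_missing(n_loci: int) -> int:
    """Maximum tolerated missing loci, scaled from 20-of-96."""
    return math.floor(SNP_MAX_MISSING / SNP_PANEL * n_loci)


def qc_filter(
    table: GenotypeTable,
    marker_type: str | None = None,
    min_typed: int | None = None,
    max_missing: int | None = None,
    het_low: float = HET_LOW,
    het_high: float = HET_HIGH,
) -> tuple[GenotypeTable, QCReport]:
    """Apply per-fish data-quality thresholds.

    microsat: retain fish typed at >= ``min_typed`` loci (default scales
    the 7-of-13 rule to the panel size).  snp: remove fish missing more
    than ``max_missing`` loci (default scales 20-of-96) or with observed
    heterozygosity strictly below ``het_low`` or strictly above
    ``het_high``.
    """
    marker_type = marker_type or table.marker_type
    L = len(table.loci)
    n_typed = table.n_typed()
    het = table.het_fraction()
    reasons = np.array(["none"] * table.n_fish, dtype=object)

    if marker_type == "microsat":
        lim = microsat_min_typed(L) if min_typed is None else min_typed
        reasons[n_typed < lim] = "too_few_loci"
    else:
        cap = snp_max_missing(L) if max_missing is None else max_missing
        with np.errstate(invalid="ignore"):
            reasons[np.nan_to_num(het, nan=het_high) > het_high] = "high_het"
            reasons[np.nan_to_num(het, nan=het_low) < het_low] = "low_het"
        # missing-loci rule takes precedence: a mostly-untyped fish is
        # reported as data-poor, not as a het outlier
        reasons[(L - n_typed) > cap] = "too_few_loci"

    report = pd.DataFrame({
        "fish_id": table.fish_ids.to_numpy(),
        "retained": reasons == "none",
        "removal_reason": reasons,
        "similarity_partner": "",
        "observed_het": het,
    })
    return table.subset(report["retained"].to_numpy()), QCReport(report)


def exclude_species(
    table: GenotypeTable, excluded_ids
) -> tuple[GenotypeTable, QCReport]:
    """Drop fish identified as a different species (e.g. coho genotypes
    flagged against the Chinook baseline)."""
    excluded = set(excluded_ids)
    mask = ~table.fish_ids.isin(excluded).to_numpy()
    report = pd.DataFrame({
        "fish_id": table.fish_ids.to_numpy(),
        "retained": mask,
        "removal_reason": np.where(mask, "none", "species_excluded"),
        "similarity_partner": "",
        "observed_het": table.het_fraction(),
    })
    return table.subset(mask), QCReport(report)


def run_qc(
    table: GenotypeTable,
    marker_type: str | None = None,
    species_excluded_ids=(),
    threshold: float = SIMILARITY_THRESHOLD,
    min_cotyped: int = 1,
    **filter_kwargs,
) -> tuple[GenotypeTable, QCReport]:
    """Full QC chain: species exclusion -> dedupe -> missing/het filter.

    The combined report records one removal reason per removed fish.
    """
    t1, r1 = exclude_species(table, species_excluded_ids)
    t2, r2 = deduplicate(t1, threshold=threshold, min_cotyped=min_cotyped)
    t3, r3 = qc_filter(t2, marker_type, **filter_kwargs)

    combined = r1.table.set_index("fish_id")
    for rep in (r2, r3):
        sub = rep.table.set_index("fish_id")
        rm = sub[~sub["retained"]]
        combined.loc[rm.index, ["retained", "removal_reason", "similarity_partner"]] = \
            rm[["retained", "removal_reason", "similarity_partner"]]
        combined.loc[sub.index, "observed_het"] = sub["observed_het"]
    return t3, QCReport(combined.reset_index())
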