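# Methods

This note documents the models behind `sscpue`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions a maintainer should know about.

## Spatial and temporal strata

Areas are latitude bands only — the fishery this design targets is a
coastal troll fleet whose management zones are bounded by parallels, so
no polygon support is needed.  Bands must not overlap but may leave
gaps (closed zones).  A point exactly on a shared boundary belongs to
the band whose top edge it touches (intervals are half-open
`[lat_min, lat_max)`, the northernmost band closed at its top); this is
a determinism convention, not a claim about any particular survey's
practice.  Weeks are ISO weeks (Monday start) by default; a custom
anchor date is available because "week" is otherwise ambiguous across
agencies.  Coordinates are decimal degrees, WGS84 assumed, west
longitudes negative.

## Genotype quality control

Three filters run in a fixed order: species exclusion (an id list from
the caller — e.g. coho genotypes flagged against a Chinook baseline),
duplicate-genotype removal, then per-fish data-quality thresholds.
Order matters: a wrong-species record must not shadow a legitimate fish
out of the data set through the duplicate rule.

Similarity between two fish is the fraction of *co-typed* loci whose
unordered allele pairs are identical.  Restricting the denominator to
co-typed loci makes the measure independent of missingness; this is a
design choice, since legacy toolkit implementations of the ">90%
similarity" rule do not document their treatment of missing data.
Pairs strictly above the threshold (default 0.90) are clustered
transitively; each cluster keeps the member with the most typed loci
(ties: lexicographically earliest id) — deterministic and
data-retaining.  Deduplication is idempotent by construction.

Data-quality thresholds generalise the conventional panel rules by
scale: microsatellite panels keep fish typed at ≥ ⌈7/13·L⌉ loci; SNP
panels drop fish missing > ⌊20/96·L⌋ loci or with observed
heterozygosity strictly below 0.16 (allelic dropout) or strictly above
0.56 (contamination).  At L = 13 and L = 96 these reduce exactly to the
field's customary 7-of-13 and 20-of-96 / 0.16 / 0.56 rules.  All
boundary comparisons are strict where the rule is worded strictly; the
tests pin each boundary.

## Conditional mixture-model GSI

Baseline allele frequencies are posterior means under a symmetric
Dirichlet prior with total mass 1 spread over the allele registry
(1/A per allele, Rannala–Mountain style):

    f_pl(a) = (n_pl(a) + 1/A_l) / (n_pl + 1).

The registry is the union of baseline and mixture alleles, so an allele
seen only in the mixture has positive frequency in every population and
no fish acquires a −∞ likelihood.  Genotype likelihoods assume
Hardy–Weinberg within populations and linkage equilibrium across loci;
missing loci contribute nothing.

Mixture proportions are maximum-likelihood via EM from a uniform start
(E-step in log space with log-sum-exp; M-step π_j = mean_i Z_ij;
stop at max|Δπ| < 1e−8 or 10,000 iterations).  EM was preferred over a
Gibbs sampler because the downstream products are point compositions;
it is deterministic, monotone in the observed-data log-likelihood
(property-tested), and testable against exhaustive simplex grid search
on small instances.  A fish with −∞ likelihood under every population
(impossible with the prior above unless loci mismatch) raises an error
naming the row.

The season runs in sliding windows per area: the fish of weeks
{w−1, w, w+1} (truncated at the season edges) are pooled, π is fitted
on the pool, and the focal week's individuals get posteriors under that
π — the window π is the "prior" through which week-scale composition
shifts inform individual assignment.  Windows with fewer than 5 fish
(configurable) widen symmetrically one week at a time; this avoids
degenerate fits in sparsely sampled weeks and is logged.  Assignment is
hard argmax over reporting-group posteriors (groups = sums of member
population posteriors, computed after the population-level fit, never
by pooling baseline populations before fitting); ties break toward the
earlier-listed (more northern) group, a determinism convention.
Monthly compositions are assigned-fish counts over the stratum total.

**Out-of-baseline screen.**  Whether a fish plausibly originates from a
stock absent from the baseline is scored by parametric simulation: n_sim
genotypes are drawn from the best-fitting population's frequencies at
the fish's typed loci, and the score is the fraction of simulated
log-likelihoods below the observed one.  For baseline-origin fish the
score is approximately uniform; scores below ~0.01 flag candidates.
This is a self-contained percentile construction, simpler than
published likelihood-based out-of-baseline statistics, and is labelled
as such wherever it surfaces.

## Effort, catch and CPUE tables

The effort unit is the vessel-day (one vessel, one local calendar
date).  A day's spatial allocation comes from its GPS fixes; with the
fixed 5-minute cadence, fix counts and time-in-area are equivalent.
Two allocation rules coexist deliberately:

* **GLM rule** — days with ≥ 85% of fixes in one band are assigned
  wholly to that band, others dropped; then any (week, area) cell whose
  days are all zero-catch is removed, because an all-zero factor cell
  makes the count-GLM maximum-likelihood estimate diverge
  (quasi-complete separation).
* **Proportional rule** — every day contributes fractional vessel-days
  by fix share, and each fish counts in the band of its capture
  coordinates.  Effort is conserved exactly; this rule feeds the
  SSCPUE tables.

The two routes agree exactly when every day is single-area
(property-tested).  Fish of unknown length receive fractional legal
status equal to their month-area stratum's known-legal share, falling
back to the season-area pool when a stratum has no measured fish
(logged).  Legal-size thresholds default to 686 mm (~27 in total
length) in the generator and are configurable per jurisdiction (28 in
Oregon / 27 in California are the relevant commercial limits).
Stratum CPUE is Σ legal encounters / Σ vessel-days, kept at full
precision and rounded only for display.

In stratum summaries, retention and non-retention cells of the same
month-area merge by default (they sample one fishery two ways within
the month); the merge is a configurable rule, not hard-coded.

## Count models

NB2 parameterisation throughout (variance μ + μ²/θ), θ estimated by
maximum likelihood unless fixed; with θ fixed at 1e7 the fit reproduces
Poisson coefficients to 1e−4 (invariant-tested).  Factor reference
levels follow first appearance in the data and are therefore arbitrary
but reproducible.  Model fitting is delegated to statsmodels; this
package owns the separation checks, shared-dispersion nesting (θ from
the largest model held fixed along the nested sequence so the
analysis-of-deviance decomposition is coherent, as in the standard R
workflow), and the test statistics:

* overdispersion LRT: 2(ℓ_NB − ℓ_Poisson) on χ²₁; because θ sits on the
  boundary under the null the halved (mixture) p-value is primary and
  the raw one co-reported;
* Vuong: mean of per-observation log-likelihood differences times √n
  over their (population) SD, two-sided normal; negative favours the
  second model — the sign convention is stated in the result;
* 2×2 successful-day χ²: Yates-corrected by default (the correction can
  only lower the statistic; both variants reported);
* per-fisherman z-tests against the reference level carry an explicit
  multiple-testing caveat — at α = 0.05, ~5% of comparisons are
  expected significant under the null.

## SSCPUE and the correlation threshold scan

SSCPUE = composition × stratum CPUE.  It inherits composition's
sampling error and CPUE's effort normalisation, sums to the stratum
CPUE across stocks (identity-tested at 1e−9), and is invariant to other
stocks' abundance — the property that makes it comparable across
strata, verified end-to-end on synthetic data.  Stock richness is the
count of groups with non-zero composition.  Log grids use the natural
log (configurable; the base is recorded in the axis metadata), with
zero/missing cells masked rather than exported as −∞.

Composition–SSCPUE association uses Kendall's τ-b (ties are certain
with compositions; τ-a is co-reported in scan traces), exact p-values
for small untied samples and the tie-corrected normal approximation
otherwise.  The threshold scan restricts candidate thresholds to the
observed composition values — reported break points are data values,
not interpolated midpoints — and reports the smallest threshold whose
p exceeds α.  The scan stops once fewer than 5 pairs remain: below
n = 5 the exact test cannot reach p ≤ 0.05 even for a perfectly
concordant ordering (n = 4 gives p = 1/12), so smaller tails measure
power loss, not decoupling.

## Synthetic data

The generator's defaults are the study conditions of a real 2010
coast-wide season: the nine latitude bands and May–September calendar,
the published per-stratum vessel-day schedule (2,651 days), and the
published per-stratum catch rates as the intensity surface.  On top of
that frame it draws:

* baselines under the Balding–Nichols model — one parameter F (an
  F_ST analogue, default 0.1, a realistic inter-stock differentiation
  for salmon reporting groups) controls GSI difficulty; 10 populations
  in 5 reporting groups, 200 fish per population;
* a default marker panel of 20 microsatellite-like loci with 8 alleles
  each.  A 20-locus *biallelic* panel would make the >90%-similarity
  duplicate rule fire on unrelated fish (chance genotype identity is
  high at 20 SNPs), which is why real SNP panels use ~96 loci; the
  multi-allelic default keeps the panel small and the dedupe rule
  meaningful.  Biallelic panels of any size remain fully supported;
* mixture proportions per stratum from an exogenous latitudinal
  gradient with slow seasonal drift (π is specified, not emergent —
  there is no migration model);
* daily legal catches NB2(μ = stratum intensity, θ = 1).  θ = 1 is a
  strongly overdispersed regime consistent with the clumped catches
  the count-model stage is designed to detect; sub-legal encounters on
  non-retention days at 0.25 of legal intensity (the ratio observed in
  non-retention sampling), with lengths from truncated normals around
  the 686 mm legal threshold;
* 5-minute GPS fixes from bounded random walks inside the day's band;
  3% of days cross into a neighbouring band (never reaching 85%
  dominance) to exercise both effort-allocation rules.  Path realism is
  irrelevant downstream — only fix-share per band matters;
* 2% per-locus missingness, 30% missing lengths on non-retention fish,
  0.5% injected duplicate records (same genotypes, fresh id; a
  near-duplicate mode perturbs one locus to exercise the sub-unity
  similarity branch).

Everything is deterministic given the seed (byte-identical outputs,
tested).  What the generator does **not** emulate: genotyping error,
linkage between loci, departures from Hardy–Weinberg within
populations, within-week abundance trends, vessel-level catchability
differences correlated with space, and environmental covariates.
Passing recovery tests therefore demonstrate the estimators' internal
correctness under the stated model, not robustness to those real-data
features.

## Problem sizes and numerical conventions

The default end-to-end run (2,651 vessel-days, ~10,000 fish, 20 loci)
completes in well under a minute on a single core; test-suite
simulations use two-area/two-month scenes of a few hundred fish, and
calibration checks (type-I error of the deviance and technique tests)
use 200 replicates at n = 100–160 per replicate — sizes chosen to make
the binomial error bands on the checked rates informative.  EM
tolerance is 1e−8 on max|Δπ|; the NB dispersion is clipped at
α ≥ 1e−10; the overdispersion LRT clamps small negative statistics
(boundary refit noise up to 1e−3) to zero.  Empty tables, zero-effort
strata and undefined statistics (all-tied τ axes, empty χ² margins)
return flagged NaNs rather than raising, except where the input is
structurally invalid.

## Known limitations

* The out-of-baseline screen is a simulation percentile, not a formal
  likelihood-ratio statistic; its null distribution is exact only
  conditional on the best-population choice.
* Sliding-window fits do not use leave-one-out baseline frequencies;
  with small baselines and a fish's own population underrepresented the
  posteriors are mildly optimistic.
* Monthly composition is argmax-count (hard assignment), which
  underweights assignment uncertainty relative to posterior-mean
  composition; the per-fish posteriors are retained in the outputs for
  anyone needing the soft version.
* No zero-inflated or hurdle count models, and no random-effects
  (GLMM) CPUE variants.
* No confidence intervals on individual SSCPUE values; stratum-level
  sampling error is available through the count-model stage instead.
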