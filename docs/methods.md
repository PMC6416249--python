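# Methods

## Model and procedure

The pipeline treats post-transcriptional regulation as a gene-set
over/under-representation problem. Inputs are (i) an RBP–mRNA network —
either binary edges built from genomic peak intervals, or a scored
interaction-propensity matrix binarised at a cutoff — and (ii) a
compendium of functional units (gene sets with a source tag: complex,
module, pathway). All counting happens over a fixed statistical
background: the genes of the tested universe that are annotated in at
least one unit. A configuration switch (`use_full_universe`) swaps in the
whole tested universe for sensitivity analysis.

For each (RBP, unit) pair the 2×2 table (in-unit/out-of-unit ×
interacting/non-interacting) is tested with the conditional exact test:
the two-sided p-value is the total hypergeometric probability of all
tables with the observed margins whose point probability does not exceed
the observed one (relative slack 1 + 1e-7 against floating-point ties,
the same convention scipy and R use). The effect size is the log2 ratio
of in-unit vs out-of-unit interacting fractions; zero cells yield signed
infinities (no pseudocounts — significance comes from the exact test, so
the sentinel only affects reporting) and 0/0 is NaN. Benjamini–Hochberg
correction is applied per family; a pair is *enriched* when the adjusted
p is below α with positive ratio, *depleted* when negative.

### Multiple-testing family

Whether correction should pool all RBP×unit tests or treat each RBP's
unit scan as its own family is genuinely open. The default is **per
RBP**, matching the per-RBP framing of the promiscuity control ("for
each RBP with significant results"); `family="global"` is available, and
outputs record which family produced them.

### Promiscuity control

RBPs binding a large fraction of the transcriptome can accumulate
significant calls for trivial reasons. The control shuffles gene
identities over the background with a single global permutation applied
to every unit simultaneously — preserving unit sizes and their overlap
structure — recomputes the full BH-corrected landscape, and counts
significant enrichments/depletions per RBP. After S shuffles the
empirical p per direction is (1 + #{null count ≥ observed}) / (1 + S)
(add-one rule, so p is never zero at finite S). An RBP is kept when
either direction beats α = 0.05. RBPs with no observed significant call
are marked *untestable* and not kept; no shuffles are spent on them. A
per-unit independent resampling variant (overlaps not preserved) is
available behind `per_unit_resampling=True`.

### Threshold-free confirmation

To decouple conclusions from the binarisation cutoff, each RBP's
background genes are ranked by interaction propensity (descending; ties
broken by gene id for determinism) and each unit is scored with the
weighted Kolmogorov–Smirnov running sum: hits add |score|^w normalised
by the total hit weight, misses subtract 1/(N − n_hits); the enrichment
score (ES) is the extremum of largest magnitude. The weight exponent is
fixed at w = 1, the standard choice. Null ES distributions come from
gene-set permutation — member sets of identical size resampled without
replacement from the background — shared across units of equal size
within an RBP. NES divides ES by the mean |permuted ES| of the matching
sign; the FDR is the signed ratio-of-tails estimate over the pooled
permutation NES, clipped to [0, 1].

One numerical subtlety: with all-positive scores the hit weights are all
positive, and for large sets the permutation null is strongly biased
toward positive ES — a random set's heavy top-of-ranking weights push
the running sum up early. A strongly avoided unit can then produce an
observed ES more negative than *every* permutation, leaving the
matching-sign side empty. Declaring NES undefined there would discard
precisely the strongest depletion evidence, so the normaliser falls back
to the opposite side's mean magnitude (sign preserved); NES is NaN only
when every permuted ES is exactly zero.

### Classification and summaries

Entities are partitioned by their significant calls: E (≥1 enrichment,
0 depletions), M (both), D (0 enrichments, ≥1 depletion), none. RBPs
failing the permutation control are reported as `none` with reason code
`failed control` rather than dropped, so both the tested and the
post-control denominators remain reconstructable. Summaries report group
counts, per-group mean and median burdens (lower-median convention on
even counts, for determinism), group-to-group link tallies whose sums
equal the significant-record totals, and the fraction of tested entities
with at least one significant call. The shared-RBP network links two
units when at least one RBP has both enriched, weighted by the count of
such RBPs.

### Feature statistics

Group comparisons use the nonparametric batteries standard in this
setting: one-sided Mann-Whitney U for burden comparisons (exact
enumeration when the combined sample is ≤ 20 without ties, tie-corrected
normal approximation otherwise), tie-corrected Kruskal-Wallis with
chi-square reference, Dunn's post-hoc z with the pooled-tie variance
term and two-sided normal p BH-corrected across pairs, two-sample
Kolmogorov-Smirnov with asymptotic p, and one-sided Fisher tests for
category composition (odds ratio ad/bc with infinity sentinel). PTM
density is sites per residue (sites past the recorded sequence length
are kept with a warning — database/sequence version drift is tolerated).
Disorder calls use a strict > 0.4 per-residue probability cutoff;
disorder predictors and low-complexity maskers are consumed as
per-residue tracks, never reimplemented, and each predictor's track is
summarised separately rather than merged by any consensus rule.
Expression breadth is the fraction of the 58 surveyed tissues where the
protein level is at least "low" with reliability in
{approved, enhanced, supported} (configurable).

## Sequence-selection filters

Peak-to-gene mapping uses 0-based half-open (BED) coordinates; an edge
requires ≥ 1 shared base between any peak of the RBP and any transcript
of the gene, and replicate peaks or isoforms collapse to one edge.
Overlap is strand-blind by default with a `stranded` option, since
peak-transcript intersection conventions vary; unmapped peaks are logged,
never fatal. Representative transcripts are chosen per gene after
discarding lengths outside [50, 1200] nt: the longest survivor wins,
ties broken by lexicographically smallest transcript id. Proteins are
kept at lengths within [50, 750] aa, bounds inclusive. Scored pairs
binarise at propensity ≥ 50. Units are size-filtered to [5, 500] members
*after* intersection with the universe.

## Synthetic data: what it emulates, and what it does not

The generator produces the statistical structure the analysis assumes:
a sparse interaction layer with planted regulons (elevated in-unit
binding probability), planted avoidance units (suppressed probability),
promiscuous RBPs (globally elevated rate), and group-biased feature
tables with a ground-truth ledger. Scores are anchored to the production
threshold: a pair with target post-threshold probability p gets score
`50 + 10·(Z + Φ⁻¹(p))`, Z ~ N(0,1), so binarising at 50 realises p
exactly and the background (p ≈ 0.023 at the nominal mean-30/sd-10
scale) shifts smoothly with p.

Default strong-effect conditions: 2000 genes, 36 units, 50 RBPs — 6
enrichment-only (intended E), 6 mixed (M), 6 avoidance-only (D), 3
promiscuous (rate 0.6), 29 unstructured — background probability 0.2,
in-unit 0.8 for enrichment plants and 0.02 for avoidance plants, one
planted unit per mode per RBP. Enrichment-planted and filler units have
30 genes. **Avoidance-planted units have 100 genes**: a depletion signal
is bounded by the unit size (the in-unit count cannot fall below zero),
and at these rates a 30-gene unit's best achievable raw p (~2×10⁻³ at
zero in-unit targets) cannot survive multiple-testing correction, while
avoided units in real compendia are typically large pathways. Units are
carved disjointly from a global shuffle of the gene pool
(`overlap_fraction` > 0 shares members between designated pairs), so the
background is the union of unit members (1920 genes at defaults).

What the generator does **not** emulate: real catRAPID score marginals
(heavy tails, RBP-specific baselines), peak-shape statistics, pathway
topology or the correlated membership structure of real compendia, and
correlations between features beyond group-level rate shifts. Passing
recovery tests therefore demonstrates the statistical machinery is
correct and calibrated under the stated model — not that real networks
meet the model's independence assumptions.

## Numerical choices and degenerate inputs

* Fisher p-values come from a margin-cached vectorised hypergeometric
  routine (cache key: background size, unit size, target count), which
  makes landscape and permutation passes cheap; tests pin it to
  scipy.stats.fisher_exact and to exact integer enumeration.
* Units whose background intersection falls below the minimum size are
  excluded from testing with a logged warning, not failed.
* α = 0 is accepted and silences all calls (useful for smoke tests).
* A unit equal to the whole background gives c = d = 0: the ratio is a
  sentinel and the test degenerates to p = 1.
* All stochastic steps take an explicit seed; the CLI defaults to a
  fixed, printed seed.

## Problem sizes used in the automated checks

The exact-test sweep covers every 2×2 table with total ≤ 60 (~6.4×10⁵
tables). Null calibration uses 200 structure-free networks of 20 RBPs ×
500 genes × 40 ten-gene units with 200-shuffle controls. Recovery pools
five strong-effect instances with 1000-shuffle controls and
1000-permutation GSEA. These sizes were chosen to give Monte-Carlo
standard errors comfortably below the decision margins they feed.

## Known limitations

* The global BH family inside the permutation control is approximated
  within the testable-RBP subset (identical when all RBPs are testable);
  the default per-RBP family is exact.
* GSEA significance uses plain tail counting; no adaptive refinement of
  very small FDRs, and no leading-edge reporting.
* The Dunn test uses the normal approximation regardless of sample size.
* Classification accuracy on synthetic data is intrinsically capped by
  the BH false-discovery level: ~4–5% of single-mode regulators acquire
  one wrong-direction call and migrate to M.
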