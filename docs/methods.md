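# Methods

## Study design the pipeline encodes

The package analyzes targeted bisulfite methylomes from three patient
arms — SSRI-treated GAD/MDD (n = 10), untreated GAD/MDD (n = 4) and
matched controls (n = 10) — through two contrasts: the treatment effect
(treated vs untreated) and the disease effect (untreated vs control).
The first-listed group of a contrast is the "case"; all methylation
differences are case minus control in percentage points (pp).  Input is
one Bismark coverage table per sample; alignment, base calling and
strand collapsing are upstream of this pipeline, and input rows are
treated as already strand-merged CpG sites.

## Per-CpG test

At each site the methylated/unmethylated counts are modeled as binomial
with a group-specific methylation level, i.e. a logistic regression of
counts on group membership — the default behaviour of the standard
per-site DMR toolkits for multi-sample groups.  With a group-only
covariate the MLE of each group's level is its pooled methylated
fraction, so the likelihood-ratio statistic

&nbsp;&nbsp;G = 2·[ℓ(p̂_case) + ℓ(p̂_ctrl) − ℓ(p̂_pooled)] ~ χ²(1)

is evaluated in closed form; the test suite verifies it against direct
numerical maximization of the binomial likelihood.  No overdispersion
correction is applied (the variance inflation the generator plants is a
property of the data, not of the test; this mirrors the default of the
tooling the design follows).  When both groups have exactly one sample
the model is saturated and the comparison falls back to two-sided
Fisher's exact on the 2×2 table.

Sites untestable in a group (zero pooled coverage) are excluded before
multiple-testing correction, so the BH n equals the number of tested
sites.  BH is the standard step-up, q_(i) = min_{j≥i} p_(j)·n/j capped at
1, NaN-aware.

**DMS rule** (strict inequalities): |MD| > 25 pp and q < 0.01, with MD
the pooled case percent minus pooled control percent.

## Coverage filter

Per sample, sites with total depth < 10 are removed, as are sites above
that sample's 99.9th depth percentile (PCR-duplicate guard); both values
follow the defaults of the cited tooling, since the underlying study does
not state its filters, and are exposed in the config.  Only sites
surviving in every sample of the contrast are kept (complete cases), so
every test sees all samples.

## DMR rule

Per chromosome and per direction, DMSs sorted by position are chained
greedily left to right: the chain absorbs the next same-direction DMS
while (last − first) ≤ 1,000 bp, then closes.  A closed chain is a DMR
when it has ≥ 3 members and |mean MD| > 25 pp.  Chains never share a DMS;
non-significant CpGs and opposite-direction DMSs inside the span do not
break a chain (the rule counts significant CpGs only).  The "within a
1,000 bp interval" constraint is read as region span, consistent with the
printed sizes of such tables (all ≤ 991 bp).  Greedy non-overlapping
chaining was chosen over sliding windows that could emit overlapping
candidates; it is deterministic with positional tie-breaking, and the
suite proves it equivalent to exhaustive enumeration of maximal
left-to-right same-direction runs.  Region size is end − start of the
first/last constituent positions (1-based), matching the printed
arithmetic (e.g. 134464977 − 134464025 = 952).  Max MD is reported
signed (the constituent of largest magnitude).

## Annotation

Islands come from a user BED (or the generator).  Shores are the ± 2 kb
island flanks minus island bases — the island-flank convention of the
standard annotation packages; the width is configurable because the
underlying study names the tool, not the width.  Context classification
is a partition with precedence island > shore > other.

Genic annotation is multi-label: promoter = [TSS − 1 kb, TSS),
1–5 kb = [TSS − 5 kb, TSS − 1 kb), both strand-oriented, plus exon,
intron and (only when a user supplies an enhancer BED — no default track
is bundled, since the provenance of published enhancer labels is
unstated) enhancer; "intergenic" is the fallback.  Reports join labels
with " & ".  Proportion tables reduce each site to its primary label by
the fixed precedence so strata are true partitions and percentages (one
decimal) sum to 100.  Region annotation is the union over constituent
sites.  The coding/non-coding split is computed over unique features with
a TSS within ± 5 kb of any DMS, not over DMSs.

## Enrichment

Published analyses of this design used a web service's proprietary
multiple-testing scheme and ranked-GSEA vocabulary; this package instead
implements the fully specifiable equivalent for unranked lists:
upper-tail hypergeometric over-representation with BH across sets.  The
universe is restricted to genes appearing in ≥ 1 gene set and (in the
pipeline) annotatable to ≥ 1 tested CpG.  Sets with < 5 universe genes or
q > 0.05 are excluded from reporting.  Leading-edge analysis is replaced
by a driver-gene tabulation: overlap genes ranked by the number of
surviving sets containing them, ties alphabetical.

## qPCR validation

ΔCt = Ct_target − Ct_reference per sample; ΔΔCt is the difference of
group-mean ΔCt (case − control); fold change = 2^(−ΔΔCt).  Per-sample ΔCt
distributions are available alongside the group estimate.  Direction
consistency against a region's methylation state uses a fold-change
tolerance τ = 0.2: hypo + fold ≥ 1.2 or hyper + fold ≤ 0.8 is concordant,
|fold − 1| ≤ τ is no-change, anything else discordant.  Amplification-
efficiency correction and significance testing of fold changes are out of
scope (direction is the validated quantity).

## Synthetic cohort generator

The generator emulates a methyl-capture experiment with known truth:

| parameter | default | meaning |
|---|---|---|
| `n_per_group` | 10 / 4 / 10 | treated / untreated / control samples, the study arms |
| `n_targets` | 80 | capture targets, cycled over chr1–chr22 |
| `cpgs_per_target` | 5–12 | clustered CpGs per target |
| `target_span_bp` | 300–1,000 | target width |
| `baseline_meth` | 0.30 | beta mean π₀, clamped to [0.01, 0.99] |
| `dispersion` | 0.05 | beta-binomial intraclass correlation ρ |
| `coverage_mean` / `coverage_size` | 30 / 30 | negative-binomial depth per site/sample |
| `island_fraction` | 0.30 | targets coinciding with a CpG island |

Counts are beta-binomial with α = π(1−ρ)/ρ, β = (1−π)(1−ρ)/ρ, so ρ is
directly the intraclass correlation and ρ → 0 recovers the binomial
exactly (verified by a χ² goodness-of-fit in the suite).  ρ = 0.05 is a
moderate biological overdispersion for matched bisulfite cohorts.  Depth
is drawn independently per site and sample; the size parameter 30 gives a
coefficient of variation ≈ 0.26, typical of deduplicated on-target
capture coverage and consistent with a panel sequenced so that targeted
CpGs clear the 10× analysis filter — at substantially higher depth
dispersion the complete-case filter would discard an unrealistically
large share of sites.  Planted regions shift π additively by δ/100 for
the affected group only, clamped to [0.01, 0.99] (matching the
percentage-point language of the DMS rule), and are anchored on
`n_cpgs ≥ 3` consecutive simulated CpGs so they are callable by
construction.  Gene models are two-exon genes placed around targets in a
rotation (promoter / 1–5 kb / exonic / intronic / none) so that every
genic class occurs; gene sets are drawn over the simulated symbols with
an optional spike-in of truth-region genes.

What the generator does **not** model: correlated depth along a fragment,
bisulfite conversion error, strand-level reads, realistic CpG spacing or
hg38 coordinates, and methylation correlation between neighboring sites
beyond the planted shift.  Passing tests therefore demonstrate the
correctness and calibration of the pipeline's inference and bookkeeping
under the stated noise model — not performance on real capture data,
where neighbor correlation and coverage structure can change power.

## Numerical and reproducibility choices

* All randomness flows from a single integer seed through one
  `numpy.random.Generator`; identical config + seed gives byte-identical
  outputs (gzip members are written with a pinned zero mtime).
* Result writers pin formatting: two decimals for percentages and
  methylation differences, one for proportion percentages, six
  significant digits scientific for p/q; tables sort by natural
  chromosome order then position.  Round-tripping a written table and
  rewriting it is byte-stable.
* Coordinates are 0-based half-open internally (BED convention); CpG
  sites keep their 1-based Bismark coordinate and overlap checks subtract
  one at the boundary.  Chromosome names are never normalized — a
  naming mismatch between inputs fails loudly rather than producing
  silently empty intersections.
* Degenerate inputs: empty DMS lists yield empty DMR/proportion outputs;
  an empty enrichment query or universe raises; a filter that removes
  every site raises rather than returning an empty frame; ties in p are
  left to BH, and the max-MD tie (equal magnitudes) keeps the leftmost
  constituent.
* Opposite-direction matching across contrasts anchors on the identical
  (chromosome, start) coordinate, reproducing how published shared-region
  tables pair rows without inventing an overlap threshold.
* The markdown report prints the top 30 DMRs per contrast by ascending
  q-value (N configurable).

## Problem sizes used in checks

The calibration suite uses 5,000 null sites (ρ = 0, 10 vs 10, ~30×) for
the type-I band and three replicate cohorts of 10 planted ± 40 pp regions
(10 vs 4) for recovery; determinism is checked on the full default cohort
(80 targets, 24 samples).  These sizes give stable Monte-Carlo estimates
(binomial 99% half-width ≈ 0.8 pp at 5,000 sites) while keeping the whole
suite fast.
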