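# Methods

This note documents the statistical model behind `gliakit`, the defaults
and why they were chosen, what the simulator does and does not emulate, and
the numerical decisions a maintainer should know about.

## Normalization model

Sequencing depth is corrected with a single median-of-ratios size factor
per sample: for reference genes (those with nonzero counts in every
sample), `s_j = median_g ( k_gj / geomean_g )`, where `geomean_g` is the
gene's geometric mean count across samples. The median is taken on the
ratio scale (for an even number of reference genes this differs from a
log-scale median, which would average the two central ratios
geometrically). Factors are rescaled so their geometric mean is exactly 1,
which makes the single-sample case return `s = 1` and gives adjusted
totals a well-defined scale.

"Adjusted total reads" re-expresses the size factor on the scale of total
uniquely aligned reads: `M̃_j = s_j · C`. Any positive `C` preserves the
defining property (nRPKM proportional to `k/s` per gene); we fix
`C = ΣM / Σs` so that the sum of adjusted totals equals the sum of
observed totals and the project-level read scale is conserved. Totals `M`
are always taken from the sample sheet, never recomputed from exonic
counts: library protocols with heavy intronic content make `M` larger than
the column sums, and that excess is exactly what the statistic is meant to
carry.

Zero counts yield zero expression with no pseudocount; pseudocounts enter
only at explicit log-transform points downstream (`log2(x+1)` in the
differential test and variable-gene selection). Gene length is the union
of merged exon intervals (1-based inclusive GTF coordinates; overlapping
and duplicated exons merged before summing; strand ignored).

## Differential expression

The default engine is a Welch two-sample t on `log2(k/s + 1)`. This is a
deliberate simplification: a negative-binomial Wald model is the field
standard for counts, but the attribution machinery downstream consumes
only (log2 fold change, adjusted p) per gene, and the TSV interface
accepts differential tables from any external engine. The in-repo test
keeps the pipeline self-contained and calibrated (type-I error ≈ 5% at
p ≤ 0.05 on simulated null NB data; the suite checks this over 20 seeds).

Pre-filter conventions: genes lacking ≥10 counts in ≥3 samples (pooled
over conditions) receive p = 1 and log2 fold change 0, and are excluded
from the BH family — the correction denominator counts passing genes only.
Their adjusted p is missing (`NA` in TSV), never 1, so downstream
consumers cannot mistake "not tested" for "tested and null".

## Cell-type attribution

The reference profile is the per-gene arithmetic mean nRPKM within each of
exactly three sorted cell types. Profile column order is recorded
metadata: the simplex projection maps the first, second and third type to
the corners (−1,0), (1,0) and (0,√3) respectively, row-by-row with the
matrix `[[−1,1,0],[0,0,√3]]`. Genes with an all-zero profile cannot be
placed and are excluded with their ids recorded (`.attrs["excluded"]`).

Markers are genes whose pseudocounted reference expression is ≥20-fold
that of *both* other types (pseudocount 0.1 nRPKM guards zero
denominators). Attribution assigns a significant bulk gene to the type
holding the largest composition fraction when that fraction reaches 0.5,
else "mixed". Because fractions are proportional to absolute reference
expression, a gene induced in two cell types is attributed to the one
expressing it more highly — the behavior wanted for genes like Gfap that
rise in several types but are dominated by one. The 0.5 share cutoff makes
a visual judgement reproducible; it is configurable.

Change-mode classification needs one piece of information the expression
data cannot supply: whether the assigned type's *abundance* differs
between conditions (a composition prior). Callers supply it per cell type
— from stereology, flow counts, or simulation truth. Rules, given a
significant bulk change assigned to type c:

- significant same-direction sorted change in c, no prior → **regulation**;
- significant same-direction sorted change in c, prior set → **both**;
- no sorted change, prior set → **composition**;
- anything else (including mixed/unassigned attribution, opposite-direction
  sorted changes, missing sorted tables) → **unassigned**.

The marker-shift diagnostic compares the bulk log2 fold-change
distribution of each marker set against all non-marker genes (two-sided
Wilcoxon rank-sum; location summarized by median difference). For a pure
marker of a type whose proportion goes from π0 to π1, mixture arithmetic
puts the expected bulk shift at log2(π1/π0).

Display utilities follow fixed conventions: heat-map values are log2,
floored at −4 (zeros included), Z-scored per gene *within each dataset
label* using the population (n) denominator with zero-variance rows set to
Z = 0, and capped at Z = 4; variable-gene selection takes the top
⌈2.5%⌉ by SD with ties broken by lexicographic gene id; probe-level
matrices collapse to the probe with the highest IQR (linear-interpolation
quartiles, ties to the lexicographically smallest probe id); four-way
comparisons set fold change to 1 for genes below 1 mean nRPKM in both
conditions of a comparison (a conservative floor near background — the
threshold is otherwise arbitrary and configurable).

## Splicing

Variant counts are the sum of 5′ and 3′ feature counts, or the single
unique value when both measure the same features (unequal values in that
case are a contract violation and raise). vFreq is the variant's share of
its event total per sample, undefined when the total is zero.

The testability cascade is order-dependent and idempotent:

1. drop variants without ≥5 counts in ≥3 samples (any condition);
2. drop events left with ≤1 variant (effectively constitutive);
3. drop retained-intron events;
4. mark each surviving event's first variant (input order — the event
   table format preserves discovery order, and the first variant is
   generally the skipping isoform) as excluded from testing.

BH correction runs across the variants actually tested, i.e. after step 4;
discarding first variants before the correction is the reading that
"limits the number of tests".

Differential usage is a Welch t on logit(vFreq) with vFreq clamped to
[0.01, 0.99]. The clamp bounds the logit for fully-skipped/included
samples; the test is monotone in the same signal as a count-level GLM and
agrees with an exhaustive label-permutation test in rank order (checked on
random events in the suite). Samples with undefined vFreq are dropped per
variant; a variant with fewer than two defined values in either condition
is skipped with a warning.

## qPCR

Technical replicates average over passing wells only. A (sample, assay)
pair failing all replicates is imputed at Ct^max+1, where Ct^max is the
highest *passing* Ct that assay reached in any sample (across conditions);
imputed values are flagged and propagate the flag through −ΔCt and ΔΔCt.
−ΔCt subtracts the mean of a configurable housekeeping set (default
`{Actb}` for splicing assays; `{Gapdh, Rpl37a}` for gene-level treatment
analyses). Splicing ΔΔCt = (−ΔCt^inclusion) − (−ΔCt^skip); lower values
mean more skipping. Treatment ΔΔCt is the group-mean difference of −ΔCt
(treated minus control). Per-cell-type testing uses the classical
equal-variance two-sample t (Welch available via `equal_var=False`),
imputed values included, BH-corrected across events within each cell type.
Amplification efficiency is taken as exactly 2 throughout; it affects
interpretation (ΔΔCt of 1 ≈ two-fold), not the arithmetic.

## Simulator

The generator emulates a sorted-cell + bulk design: three cell types from
n = 5 animals per condition, bulk samples as proportion-weighted mixtures.
Per-gene true abundances θ_gc are log-normal — non-marker genes share a
base draw (ln-mean 1.5, ln-sd 1.5) with mild per-type jitter (ln-sd 0.3,
so spurious ≥20-fold specificity is vanishingly rare); marker genes
(200 per type by default) draw a well-expressed target (ln-mean 3.0,
ln-sd 1.0) and are floored at target/1000 in the other types, making them
effectively exclusive as canonical markers are. Counts are negative
binomial with Var = μ + φμ², φ = 0.1 (typical between-animal biological
CV² at moderate expression), mean = library size × relative abundance.
Library sizes are log-uniform in [5×10⁵, 2×10⁶] to exercise the
size-factor machinery, and reported totals exceed exonic sums by a random
factor in [1.3, 1.7] to mimic intronic read excess.

Two default scenarios mirror the analysis's headline contrast. The
**composition** scenario doubles the microglial fraction (0.10 → 0.20)
with neurons 0.60 → 0.50 and astrocytes constant, and regulates nothing.
The **regulation** scenario fixes proportions and induces 100 genes
4-fold in microglia; regulation targets are drawn from the microglial
marker set, since a fold change confined to one cell type is visible in
bulk only for genes that type dominates — the situation the classifier
exists for. Mixing proportions are fixed per condition (no per-animal
Dirichlet jitter); biological spread enters through the NB noise.

Splicing events are two-variant cassettes: inclusion reads are binomial
(depth 60, baseline vFreq uniform in [0.2, 0.8]); treatment shifts the
inclusion frequency on the logit scale; the skipping variant is emitted
first so the filter cascade's first-variant rule applies as in real event
tables; totals split deterministically into 5′/3′ halves. qPCR plates
measure Ct = a − log2(abundance) + N(0, σ) per technical replicate
(a = 20, σ = 0.15, 3 replicates) with wells beyond Ct 35 (or undetectable
abundance) flagged failed.

Randomness uses numpy's seeded `default_rng` with independent child
streams per data product, so outputs are bit-reproducible for a given seed
and adding one product never perturbs another.

**What the simulator does not model:** amplification bias, batch effects,
sample contamination, per-animal proportion variability, correlated
gene-gene structure, more than three cell types, events with >2 variants,
and qPCR efficiency ≠ 2. Passing recovery tests therefore demonstrates
correctness of the pipeline's arithmetic and calibration under the stated
generative model, not robustness to these real-data complications.

## Validation sizes and expectations

The suite and `scripts/acceptance.py` use 20 replicate simulated studies
of 2,000 genes (600 markers), 5 animals per condition — sizes chosen so a
full validation runs in seconds while leaving dozens of attributed genes
pooled across replicates. Under the composition scenario ≥90% of
microglia-attributed bulk-significant genes classify as composition and
the microglial marker shift has median ≈ 1 log2 unit (±0.15, mixture
arithmetic); under the regulation scenario ≥80% of bulk-detected targets
classify regulation/both and off-target marker shifts center at 0.
Splicing power at logit shift 2 (depth 60, 5v5) exceeds 80% at
adj p ≤ 0.05 with near-nominal type-I at shift 0. These are the quantities
the acceptance script recomputes; the script's JSON output is the
authoritative record of a given run.

## Known limitations

- The Welch-t differential engine is less powerful than an NB GLM at very
  low counts; plug in an external differential table for real analyses
  where that matters.
- Attribution uses reference profiles from control sorted samples only;
  genes whose cell-type specificity itself changes with condition (e.g.,
  astrocyte-enriched genes invading reactive microglia) can be
  mis-attributed — the classifier surfaces them as "both"/"unassigned"
  rather than resolving them.
- No contamination score for sorted samples is implemented; callers must
  exclude contaminated samples upstream.
- The composition prior is an input, not an inference; the package does
  not estimate cell fractions from bulk data (no deconvolution).
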