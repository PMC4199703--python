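# Methods

tetramap builds haplotype-resolved genetic linkage maps for an
autotetraploid F1 cross from genotyping-by-sequencing (GBS) allele
read depths, following the two-way pseudo-testcross strategy, and
validates every stage against a tetrasomic-meiosis simulator with
known truth. This note records the models, the defaults and why they
were chosen, and what the simulation-based tests do and do not show.

## Genotype model and calling rules

For a biallelic SNP (alleles A/B) in a tetrasomic individual with true
genotype G ∈ {AAAA, AAAB, AABB, ABBB, BBBB} and total depth N, the
A-read count is modelled as binomial,

    X_A | G ~ Binomial(N, p_G),   p_G = 1−α, 3/4, 1/2, 1/4, α,

with α the per-read sequencing error rate. Note the asymmetry: only
the homozygote classes involve α; the heterozygote classes use their
exact dosage fractions. `genotype_model.genotype_likelihood`
implements exactly these five probabilities.

Calling is rule-based, not posterior-based, because the dominant risk
at GBS depths is miscalling a triplex heterozygote (AAAB) that by
chance shows only A reads. P(X_A = N | AAAB) = (3/4)^N drops below
0.05 first at N = 11, which fixes the homozygote depth floor:

* only one allele observed → homozygote if N ≥ 11, else missing;
* both alleles observed → heterozygote if the minor allele has ≥ 2
  reads and minor-allele frequency > 0.10 (both strict), else missing;
* N = 0 → missing.

Heterozygote dosage (AAAB vs AABB vs ABBB) is never emitted: separating
those classes reliably needs ≳60× depth. Downstream analyses use only
presence/absence of the single-dose allele, so the collapse is lossless
for mapping.

A structural consequence of the single-allele rule worth knowing: a
true homozygote showing even one error read is no longer a
"single-allele" observation and, failing the heterozygote thresholds,
becomes missing. Absence calls are therefore censored relative to
presence calls, increasingly so at high depth (P(no error read) =
(1−α)^N). Two design choices below follow from this.

### Parent replicates

Parents enter the libraries as replicate columns (defaults 5 and 7).
`merge_parent_replicates` pools replicates by summing depths — the
right choice for shallow replicates, where 3+4+4 reads of one allele
legitimately become an 11-read homozygote. The pipeline default,
however, is `consensus_parent_calls`: each replicate is called at its
own depth and the parent gets the majority state among non-missing
replicate calls (ties → missing). Pooling 5–7 replicates of ~30×
depth yields 150–210 reads, at which point a homozygous parent almost
surely shows an error read and the pooled call collapses to missing;
per-replicate consensus keeps those markers usable.

### Missingness tiers

`filter_by_missingness` retains markers at or below a missing-fraction
cutoff and `missingness_tier_report` tabulates marker counts and mean
missingness for cutoffs 10%…90%, the standard way to choose a working
marker set for GBS data.

## Single-dose-allele screen

Pseudo-testcross mapping uses markers heterozygous in exactly one
parent (AB × AA or AA × AB, from the merged parent calls). A
single-dose (simplex) allele segregates 1:1 presence:absence in the
progeny; a double-dose (duplex) allele segregates 5:1 under random
chromosome segregation. The χ² goodness-of-fit statistics against the
two expectations coincide at presence fraction
x = (1 + √5)/(2 + 6/√5), i.e. at a presence:absence ratio of
√5 ≈ 2.236 (printed 2.24) — this is scale-free, so it holds at any
sample size (`equal_evidence_ratio`, verified against an independent
root-finder in the tests). The screen therefore keeps markers with
observed ratio < 2:1 and missingness < 50% (both strict). There is no
lower ratio bound: presence deficits stay in the marker set and are
flagged by the distortion test. An alternative "equal evidence" point
via binomial-likelihood equality instead of χ²-statistic equality
gives ≈ 2.15 and is deliberately not the default.

Per-marker distortion is χ² = (n_present − n_absent)²/n against 1:1
(1 df, no continuity correction; immaterial at n ≈ 384, noticeable
below n ≈ 50).

## Linkage mapping

Presence/absence of one parent's SDA markers behaves like a backcross:
with R mismatches among n pairwise-complete progeny, rf = R/n and
LOD = R·log10(rf) + (n−R)·log10(1−rf) + n·log10 2. Mismatch fractions
above 0.5 (repulsion-like pairs — markers on different homologs) are
truncated to rf = 0.5, LOD = 0. In an autotetraploid, repulsion
linkage is weak, so ignoring it is what makes each linkage group at a
high LOD threshold correspond to a single homolog. Pairwise-complete
estimation is unbiased when missingness is independent of genotype;
the simulator's depth model satisfies this at the locus level (see
limitations for the caller-induced exception).

Grouping is single linkage: connected components of the graph with
edges LOD ≥ 14. Ordering minimises the sum of adjacent recombination
fractions (SARF) per group, using only pairs with LOD ≥ 1.0 and
rf ≤ 0.35; an adjacency with no qualifying estimate contributes a flat
0.5 penalty (pure exclusion would reward placing unlinked markers side
by side). The seriation is deterministic: seed with the farthest
qualifying pair, insert remaining markers nearest-first at the
SARF-optimal position, polish with best-improvement 2-opt reversals,
and normalise orientation so the first marker id sorts before the
last; all ties break on marker id, making the output invariant to
input order. Positions accumulate Kosambi distances
d = 25·ln((1+2r)/(1−2r)) over adjacent pairs; an unusable adjacent
estimate falls back to the shortest spanning pair with a usable one.
Within a chromosome, homologs are named A–D by descending marker
count (ties by smallest marker id; >4 groups are flagged and lettered
onward).

## Segregation-distortion scan

Per-marker −log10(p) values are LOESS-smoothed along each linkage
group (tricube weights, degree 1, one pass, span 0.3 of the group's
markers) and a region is a maximal stretch where the smoothed curve
exceeds 3 (p < 0.001 on the smoothed scale) that contains at least
three consecutive markers individually at p < 0.001 with a shared skew
direction. The qualifying run is reported as the region core. The
span is not critical: the recovery tests hold across spans 0.25–0.5.
Direction constancy is required of the marker-level signs, not of the
smoothed curve. Smoothing is per linkage group, so homologs are
scanned independently.

## Synteny comparison

Marker tag sequences are assumed pre-aligned to a reference genome
(BLAST outfmt-6 tables are consumed, never produced). Per marker the
highest-bitscore hit under the e-value cutoff (default 1e−5, strict
alternative 1e−20) is kept, with ties broken by lower e-value then
lower subject position; "best hit = max bitscore" is a convention, the
alternatives differ only in contrived ties. Each linkage group is
assigned to the reference chromosome carrying the majority of its
markers' best hits (≥3 votes required; winning fraction < 0.5 or an
exact tie → ambiguous). The dotplot table pairs genetic (cM) against
physical (bp) positions; per-group Spearman |ρ| is the collinearity
score (the sign is meaningless because group orientation is
arbitrary). Inversions appear as contiguous rank-discordant blocks and
translocations as two-chromosome dot patterns / ambiguous assignments;
both are descriptive — no breakpoint model is fitted.

## The simulator: what it emulates, what it does not

`simulate` generates the latent truth and the observable data for an
autotetraploid F1 design: two parents with four phased homologs per
chromosome; simplex markers (A on one homolog of one parent) laid out
on an interleaved grid so each homolog's markers span the chromosome,
plus duplex decoys the screen should reject; tetrasomic meiosis with
uniformly random bivalent pairing (the three pairings of four
homologs), Haldane (no-interference Poisson) crossovers within each
bivalent, one product per bivalent per gamete, and no double
reduction — the gamete dosage distribution of a duplex parent is then
exactly (1/6, 2/3, 1/6) and simplex transmission is exactly 1/2, the
basis of the 1:1 and 5:1 expectations. Viability loci thin carriers at
conception by rejection sampling until the configured number of
progeny survives.

Read depths: each locus draws a mean-1 gamma factor (shape 1.2)
scaling the global mean depth (default 30), shared by progeny and
parents — this emulates the strongly unequal distribution of GBS reads
across restriction fragments and is what produces a broad per-marker
missingness spectrum. Given the locus mean, per-cell depth is
negative-binomial (size 2.0, zeros allowed) and X_A is binomial with
p = (d/4)(1−α) + (1−d/4)α for true dosage d. The default α is 0.001,
a standard figure for quality-filtered Illumina short reads.

Default study conditions: 384 progeny, 8 chromosomes of 70 cM, 25
simplex markers per homolog per parent, 4 duplex decoys per
chromosome, parent replicates 5 and 7. Under the calling rules these
defaults give a mean per-marker progeny missingness around 35–40%
(median ≈ 0.26, with a long tail of near-unusable shallow loci), and
roughly 70% of simplex markers survive parent classification plus the
SDA screen. At depth_mean = 4 the same model yields ≈ 85% missing
calls — the 11-read homozygote floor makes substantially lower
missingness unattainable at that depth for any dispersion.

Not emulated: sequence-level artefacts (no tags, no restriction-site
polymorphism, no barcode effects), per-individual library-size
variation, linked viability loci, double reduction (the config hook
exists but only 0 is implemented), and crossover interference.
Passing recovery tests therefore show the estimators are correct under
tetrasomic transmission with MCAR-at-locus-level missingness; they do
not certify behaviour under interference, segregation-dependent
missingness beyond the caller's own censoring, or reference-genome
artefacts.

## Known limitations

* **Dominant-scoring presence bias.** Because a homozygote call
  tolerates zero minor-allele reads, absence calls are censored
  relative to presence calls at both depth extremes (N < 11 and, via
  error reads, large N). At α = 0.005 this inflates observed
  presence:absence ratios by ~1.3× median and marks ~17% of null SDA
  markers "distorted" at p < 0.001 — all excess-presence — without any
  selection; at the default α = 0.001 the residual inflation is ~1.1×
  and the null distortion rate ~1%. The bias also attenuates genuine
  excess-absence distortion in read-level data, so end-to-end
  region detection is weaker than on perfectly typed data (the test
  suite measures both levels separately).
* **Single-linkage grouping** can chain two homologs through one
  miscalled bridge marker at low thresholds; at LOD 14 with n = 384
  this was never observed in the recovery tests, but smaller
  populations would warrant a robust grouping criterion.
* **SARF + 2-opt** is a local optimiser; with dense markers and
  n = 384 it recovers order to Spearman |ρ| ≈ 0.999, but adjacent
  markers a fraction of a centimorgan apart are ordered essentially at
  random (as with any method at this resolution).
* **Map-length bias.** Cumulative adjacent Kosambi distances slightly
  inflate lengths when marker density is high relative to n (binomial
  noise in each adjacent rf adds up); at the default conditions
  estimated homolog lengths fall within ~±15% of truth.

## Problem sizes used in the validation suite

Simulation-based tests run at the study conditions above (8×4×25
markers per parent, n = 384): 20 replicates for grouping/order
recovery, 20 + 20 replicates (selection and null) for the distortion
scan on perfectly typed data, 10,000 gametes for segregation
calibration, and ≥2,000 markers for type-I error control. The full
suite completes in about a minute on one CPU.
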