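# tetramap

Haplotype-resolved linkage mapping for autotetraploid F1 populations
genotyped by sequencing (GBS).

Autotetraploids (alfalfa being the motivating crop) inherit
tetrasomically: each locus has four homologous copies that pair and
segregate randomly at meiosis, so standard diploid mapping software
cannot consume the genotypes directly. tetramap implements the
two-way pseudo-testcross route around this: call genotypes from
per-allele read depths with a tetraploid-aware binomial model, keep
only *single-dose alleles* (SDAs — alleles on exactly one homolog of
one parent, which segregate 1:1 like a backcross), and build a
separate linkage map per parent in which every linkage group is a
single homolog. The toolkit adds a segregation-distortion-region scan
along the resulting maps and a synteny comparison against a reference
genome, and ships a tetrasomic-meiosis simulator that generates full
synthetic experiments with known truth for validation.

It is aimed at plant geneticists working with polyploid GBS data and
at method developers who need a tested, scriptable reference
implementation of the classical autotetraploid mapping workflow.

## The model in brief

* **Genotype calling.** For a biallelic SNP with true genotype
  G ∈ {AAAA, AAAB, AABB, ABBB, BBBB} and depth N, the A-read count is
  X_A ~ Binomial(N, p_G) with p_G = 1−α, 3/4, 1/2, 1/4, α. Since
  P(X_A = N | AAAB) = (3/4)^N < 0.05 first at N = 11, a homozygote is
  called only from ≥ 11 reads of a single allele; a heterozygote needs
  ≥ 2 reads per allele and minor-allele frequency > 0.10; everything
  else is missing.
* **SDA screen.** Simplex alleles segregate 1:1 presence:absence,
  duplex 5:1; the χ² evidence for the two balances at √5 ≈ 2.24:1, so
  markers with ratio < 2:1 and < 50% missing calls are kept.
  Distortion per marker: χ² = (n_present − n_absent)²/n against 1:1.
* **Mapping.** rf = mismatch fraction over pairwise-complete progeny
  (truncated at 0.5), LOD = R·log10 rf + (n−R)·log10(1−rf) + n·log10 2;
  single-linkage grouping at LOD ≥ 14; SARF seriation with 2-opt
  polish (pairs filtered at LOD ≥ 1.0, rf ≤ 0.35); Kosambi distances
  d = 25·ln((1+2r)/(1−2r)); homologs named A–D by marker count.
* **Distortion scan.** LOESS-smoothed −log10(p) along each group;
  a region is an above-3 stretch of the curve containing ≥ 3
  consecutive same-direction markers at p < 0.001.
* **Synteny.** Best BLAST hit per marker under an e-value cutoff,
  majority-vote chromosome assignment per group, cM-vs-bp dotplot
  tables with Spearman collinearity scores.

Details, defaults and limitations: `docs/methods.md`.

## Worked example

A complete synthetic experiment — 384 progeny, 8 chromosomes, 25
simplex markers per homolog per parent plus duplex decoys, 30× mean
depth — through the whole pipeline:

```
$ tetramap simulate --seed 42 --out-dir fixtures
wrote 1632 markers x 384 progeny to fixtures

$ tetramap call --reads fixtures/reads.tsv \
    --replicates fixtures/replicates.json --out calls.tsv --report tiers.tsv
called 1632 markers x 386 individuals

$ tetramap screen --calls calls.tsv --mother mother --father father --out sda.tsv
932 SDA markers of 1632 screened

$ tetramap map --sda sda.tsv --calls calls.tsv --out map.tsv
mapped 932 markers; linkage groups per parent: {'maternal': 32, 'paternal': 32}

$ tetramap distort --map map.tsv --sda sda.tsv --out regions.tsv
1 distortion region(s)
```

Reading the numbers: of 1632 simulated markers, 932 survive parental
classification and the SDA screen (the losses are duplex decoys,
markers whose parent calls are unusable, and shallow loci exceeding
the missingness cap — deliberately realistic for GBS). Grouping at
LOD 14 yields exactly 32 linkage groups per parent, i.e. 4 homologs ×
8 chromosomes, matching the simulated truth. No selection was
simulated here; the single reported region is a borderline false
positive of the kind the null-rate tests bound at ≈ 0.5 per genome
scan. The map table is tidy TSV:

```
parent	linkage_group	marker	position_cM
maternal	LG01	chr08_m2_001	0.0
maternal	LG01	chr08_m2_002	2.893398800866464
```

With a hit table against a reference genome (BLAST outfmt 6; the
simulator can fabricate a truth-linked one), linkage groups acquire
chromosome names and collinearity scores:

```
$ tetramap synteny --map map.tsv --hits hits.tsv --out-prefix syn
assigned 64/64 linkage groups

$ head -3 syn_collinearity.tsv
parent	linkage_group	chromosome	n_markers	spearman_rho	collinearity
maternal	LG01	chr08	19	1.0	1.0
maternal	LG02	chr02	18	1.0	1.0
```

The same stages are available as library functions
(`tetramap.simulate`, `genotype_model`, `sda_screen`, `linkage_map`,
`distortion_scan`, `synteny_compare`) operating on pandas objects.

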