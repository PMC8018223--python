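# Methods

## Scope and model

`oystermeth` implements the analysis of an environmentally induced phenotype
experiment in the black-lipped pearl oyster: three families each contribute a
control individual held at 8 m and a treatment individual moved
8 m → 30 m → 8 m at monthly intervals, with mantle sampled at each transfer
(times S1–S3). The pipeline starts from per-cytosine bisulfite counts
(Bismark cytosine-report or coverage dialects) and ends with effect-level DMC
tables, GO enrichment, and shell-colour test tables. Read QC, alignment and
deduplication are upstream of this package; gene→GO annotation is an input.

### Methylation calling

A cytosine is called when its total read count reaches `min_coverage`
(default 10). Contexts are assigned from the genome: CpG, CHG (C-H-G,
H ∈ {A,C,T}), CHH, and CN/CHN when a required base is N or beyond the
scaffold end. Coordinates are 1-based inclusive (BED output converted to
0-based half-open). CpG dyads are not destranded by default; a `destrand`
helper merges symmetric pairs by summing counts. No between-sample coverage
normalisation and no upper-percentile coverage filter are applied. For each
pairwise comparison, positions are intersected across all six samples
(methylKit-style unite), so every tested site is covered in every sample.

### Per-site differential methylation

With replicated groups, each site is tested by binomial logistic regression
of methylated proportion on the group indicator. Because the single
covariate is binary, the maximum-likelihood fit is closed-form — each group's
fitted proportion is its pooled proportion — so the 1-df likelihood-ratio
chi-square is computed directly and vectorised over sites (a test
cross-checks it against a statsmodels GLM fit). Complete separation (one
group entirely methylated, the other entirely unmethylated) falls back to
the two-sided Fisher exact test on pooled counts and is flagged; the Fisher
test is also the path for unreplicated groups. No overdispersion correction
is applied.

P values are adjusted by Benjamini–Hochberg within each comparison (the FDR
family is the sites of one comparison, not the nine comparisons jointly).
The methylation difference is the pooled, coverage-weighted percent
difference A − B (an unweighted mean-of-fractions alternative is available).
A DMC requires strictly |diff| > 25 percentage points and strictly q < 0.05.

### Effect disentangling

Nine 3-vs-3 comparisons form three families: time (controls across times),
depth+time (treatment across times) and depth+genotype (treatment vs control
per time). Family unions are non-redundant by (site, direction); a site
hyper in one comparison and hypo in another keeps both entries flagged
discordant. The depth-only set subtracts time-affected *positions*
(direction-agnostic — the conservative reading) from the depth+time union.
The depth+genotype family is reported but not used in the subtraction.

### Characterization

* Metagene: scale-regions profile with 3-kb flanks in 100-bp bins and the
  gene body scaled to 60 bins; minus-strand genes are reversed; per-bin site
  means are averaged within, then across genes.
* GBMR: per-gene unweighted mean of CpG site fractions over the full
  annotated span (bedtools `map -o mean` semantics); overlapping genes share
  sites; uncovered genes are missing.
* Classification: fractional midrank (rank − 0.5)/n with average ranks for
  ties; rank ≤ 0.2 → low, ≥ 0.5 → high, otherwise mid. The midrank
  convention makes a 10-gene strictly increasing series split 2/3/5.
  All-tied inputs classify as mid with a warning.
* Expression: RPKM = 10⁹·c/(L·N); methylation-by-expression curves report
  equal-count rank bins plus the fixed <100, 100–1000, >1000 RPKM bands.
  The moderate band is treated as 100–1000 RPKM ("lowly" < 100, "highly"
  > 1000), resolving an inverted inequality in the source description as a
  presumed typo.
* Clustering: Ward linkage on 1 − Pearson correlation of per-sample site
  fractions (scipy), exported as Newick with merge heights; constant
  profiles are rejected.

### Enrichment

DMCs outside all gene bodies are counted and discarded; inclusive,
strand-agnostic overlap assigns the rest (a DMC under two overlapping genes
counts for both, flagged). GO terms are tested one-sided (over-representation
only) by the hypergeometric upper tail of the 2×2 table, BH-adjusted within
each namespace (BP and MF separately). No ancestor propagation is performed
by default.

### Colour phenotyping

Darkness is defined operationally as 1 − mean HSV brightness (value channel)
over shell pixels; saturation is the arithmetic mean; hue is the circular
(unit-vector) mean in degrees. Groups (ten screenshots per sample by
default) are tested with Shapiro–Wilk (descriptive) and pairwise two-sided
Wilcoxon rank-sum tests: exact by enumeration when the pooled sample has at
most 25 tie-free values, otherwise the tie-corrected normal approximation.
With complete separation of two groups of ten the exact two-sided p is
2/C(20,10) ≈ 1.0825×10⁻⁵.

## Synthetic data generator

The generator defines the study conditions the tests run under:

* Genome: i.i.d. bases at GC fraction 0.35 (mollusc-like), default 2×50 kb.
* Genes: non-overlapping spans of 1–3 kb placed with 3-kb flanks inside
  scaffolds; default 30 genes.
* Mosaic methylome: genes are assigned to low/mid/high classes by exact
  quota (defaults 20 % / 30 % / 50 %, matching the rank bands the classifier
  uses — with i.i.d. draws the realised proportions fluctuate around the
  fixed rank cuts and label recovery is bounded away from 1 regardless of
  signal). Genic CpG levels are uniform in (0, 0.0019) for low, (0.005,
  0.05) for mid and (0.005, 0.4012) for high genes; per-gene mean levels are
  therefore bimodal with an empty band in (0.002, 0.005). Intergenic CpGs
  sit at 0.07; CHG/CHH/CN levels are jittered ±50 % around 0.009/0.010.
* Planted DMCs: +30-point shifts on CpGs of low-methylation gene bodies
  (hypermethylation gains, the scenario the design is powered for), applied
  to the treatment group at S2 and S3 only (a persistent response), with a
  truth table for recovery scoring; shifts leaving [0,1] are clipped and
  flagged.
* Counts: coverage ~ negative binomial (mean 30, size 20 — overdispersed
  enough that the minimum-coverage filter is active, ~0.15 % of sites per
  sample below 10 reads); methylated reads ~ binomial in the true fraction
  after a symmetric conversion error e = 0.005 (observed p = p(1−e)+(1−p)e).
  Zero-coverage sites remain present as 0/0 rows.
* Sample structure: per-site Gaussian offsets on CpG sites only, with
  treatment (sd 0.05, all times, individual-linked) > genotype (sd 0.02,
  shared by the control and treatment individual of a family) > time
  (sd 0.005), so correlation-distance Ward clustering splits first by
  treatment and then by genotype.
* Expression: with `coupling="hump"`, mid/high-methylation genes draw RPKM
  log-uniformly inside 100–1000 and low-methylation genes outside, creating
  the moderate-expression methylation peak; `"none"` draws log-normal RPKM
  independently of class.
* GO map: random term assignment (Poisson mean 3 terms/gene over 20 terms,
  alternating BP/MF) plus an optional planted term attached to a chosen gene
  list.
* Images: constant-HSV frames with Gaussian brightness noise and a darkness
  shift; 8-bit PNG by default, float RGB on request (8-bit quantisation
  produces exact ties in per-image mean darkness, which would force the
  rank-sum test off its exact path).

All randomness derives from one seed through a `SeedSequence` tree, so equal
configs give byte-identical outputs.

### What the generator does not emulate

Real WGBS features absent here: sequence-driven coverage bias and M-bias,
correlated methylation of neighbouring CpGs, partially methylated domains,
repeat content and mappability gaps, strand-asymmetric conversion failure,
and biological annotation structure in the GO map. Passing tests demonstrate
the correctness and calibration of the statistical machinery under the
stated generative model, not performance on real oyster data; the study's
own printed rates and DMC counts derive from its sequencing data and are not
reproduced at desk scale.

## Numerical choices and problem sizes

* Strict inequalities at both DMC thresholds; sites with zero pooled
  coverage in a group are skipped and logged.
* Fisher p uses the sum of hypergeometric probabilities ≤ the observed
  table's (scipy); degenerate margins give p = 1.
* The null calibration and recovery studies use 10,000 sites, 3 vs 3
  samples, coverage mean 30: the type-I rate of the LRT at p < 0.05 is
  ~5.1 %, and recovery of +30-point DMCs through the >25 %/q<0.05 filter is
  ~0.82 in expectation — the observed pooled difference exceeds the strict
  25-point cut with probability ~0.83–0.85 at ~90 pooled reads per group, so
  seed-to-seed values of 77–87 % are expected (binomial sd ≈ 2.7 points).
* The end-to-end run uses a 100-kb genome with 18 samples (~35,000 stranded
  cytosines), which keeps the whole pipeline under a minute while leaving
  every stage non-trivial (thousands of united CpG sites per comparison).
* Dendrogram leaf order is scipy's deterministic ordering; correlation
  distances are symmetrised and clipped at 0 before linkage.
* The worked GO example (10-of-100 study, term with 10 population genes, 4
  in the study) has upper-tail p = 8.2249×10⁻³ by exact enumeration.

## Known limitations

* q values are Benjamini–Hochberg, a deliberate substitution for methylKit's
  SLIM correction; DMC counts are therefore not expected to match a SLIM
  analysis exactly.
* No DMR (region-level) calling, no covariate adjustment, no overdispersion
  correction in the site test.
* GO enrichment does not propagate annotations to ancestor terms unless the
  caller supplies a propagated map.
* The darkness statistic is this package's operational definition
  (1 − mean V); other HSB summaries of the same images will differ.
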