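# Methods

`ailqtl` implements a genetical-genomics analysis for an advanced intercross
line (AIL) between two divergent, inbred-like founder lines: linkage mapping
of growth traits, liver-style expression QTL (eQTL) mapping, trans-hotspot
detection with conditional mediation, candidate-gene integration, and
selective-sweep overlap testing. A bundled simulator generates the whole
study design so every stage can be calibrated without external data.

## Cross model and genotype probabilities

Genotypes at SNP markers are coded on the intercross alphabet
{AA, AB, BB, not-AA, not-BB, missing}, where A denotes the wild-founder
allele and the partial codes represent dominant markers that cannot separate
one homozygote from the heterozygote. Multipoint genotype probabilities are
computed by a three-state hidden Markov model run along each chromosome with
forward–backward smoothing:

- transitions between adjacent positions use the standard F2 two-locus
  distribution with recombination fraction from the Haldane map function,
  r = (1 − e^(−2d/100))/2 for d in cM;
- emissions keep probability 1 − ε on states compatible with the observed
  code and spread ε uniformly over incompatible states
  (default ε = 0.001, configurable);
- pseudomarkers are inserted on a regular grid (default 1 cM in the
  pipeline; tests and calibration use 2 cM).

The AIL is analysed with F2 transition probabilities on the *observed*
(already expanded) map — the same approximation used when such a cross is
coded as an ordinary intercross. A generation-indexed AIL transition model
is deliberately out of scope. Scans run on autosomes only; no Z-chromosome
model is provided.

## Haley–Knott scans

Each trait is regressed at each grid position on the expected genotype
scores x_a = P(BB) − P(AA) and x_d = P(AB), with covariates: batch
(one-hot), sex (+1 male / −1 female), optionally dye for expression traits,
and trait-associated genotype principal components (the first ten PCs are
screened against the trait at p < 0.05 — a light-weight control for family
structure). LOD = (n/2)·log10(RSS0/RSS1) against the covariates-only null.
Sex is also an interactive covariate: a genotype-by-sex term is retained
when it improves the model LOD by more than 1, for traits and eQTL alike.

Computationally, the genotype columns are residualized against the
covariate basis once and per-position fits reduce to small batched QR
projections, so permutations and whole-array eQTL scans are matrix
operations rather than per-position model fits.

Significance is empirical: the trait vector is permuted over the scanned
individuals (covariates stay attached to the genotypes), the genome-wide
maximum LOD recorded per permutation, and thresholds taken at the 95%
(significant) and 80% (suggestive) quantiles. Support intervals use a
1.8-LOD drop, expanded one grid position outward past the drop and
converted to Mb by piecewise-linear interpolation of the dual-coordinate
map (clamped, floored at zero, at chromosome ends). Overlapping intervals
across traits are merged when counting distinct genomic regions.

Two-dimensional scans fit, for every pair of grid positions on a coarsened
(≥5 cM) grid, the full two-locus model (both loci plus the four
interaction products) and the additive model, reporting the five standard
statistics (full, full-vs-one, interaction, additive, additive-vs-one)
with default declaration thresholds 11/9/7/7/4. Multiple-QTL models are
built by forward inclusion in LOD order with drop-one LOD tests; variance
explained per term is 100·(RSS_reduced − RSS_full)/TSS, with TSS the total
sum of squares about the trait mean (so reported percentages are of total
phenotypic variance, sex dimorphism included).

Analytic power uses the noncentral χ² approximation: 2·ln(10)·LOD at the
true locus ~ χ²_df(ncp) with ncp = n·f/(1 − f) for a locus explaining a
fraction f of variance, df = 2 for the a+d intercross model.

## Expression preprocessing and eQTL mapping

Probe-level intensities are quantile-normalized (columns mapped onto the
row-wise mean of sorted columns, ties sharing interpolated quantiles),
summarized to probesets by Tukey median polish (probeset value = overall +
sample effect), and batch-adjusted with parametric empirical-Bayes ComBat
(via scanpy; cross-checked against Bioconductor sva in the test suite).

Annotated probesets are scanned for a local eQTL within ±50 cM of the
gene's interpolated map position (window clipped at chromosome ends,
distances on the expanded final-generation map) and genome-wide outside
that window for distal (trans) eQTL; unannotated probesets are scanned
genome-wide, all hits distal. Excluding the local window from the distal
scan is config-switchable; the default excludes it so a probeset cannot
contribute a "distal" peak at its own locus. Distal candidates with ten or
fewer individuals in any observed genotype class at the peak's nearest
marker are discarded to avoid signals driven by a handful of birds.

Thresholds come from subsampled-probeset permutations: each replicate
draws 100 probesets, permutes individual labels once, and records (a) the
maximum LOD over the drawn probesets' local windows and (b) the maximum
genome-wide LOD; thresholds are the 95% quantiles of the replicate maxima.
Taking the max over the 100 probesets (rather than pooling) is the stricter
reading of simultaneous-probeset permutation and is the recorded choice.

Effect directions are summarized per sex by folding the interaction terms
into per-sex additive and dominance effects (a_male = a + a_by_sex, etc.);
dominance sign is the heterozygote's deviation from the mid-parental value.

## Hotspots and mediation

Distal-eQTL confidence intervals are piled onto 0.1 Mb half-open bins on
the physical genome. The null re-places the same interval lengths uniformly
on one unstructured 1 Gb line (the approximate autosomal genome span) and
records the maximum coverage per simulation; the hotspot threshold is the
95% quantile of these maxima, and a hotspot is the maximal run of bins
above it. For each hotspot, every overlapping local-eQTL gene is tested as
a mediator of every member trans association: mediator and target
expression are residualized on sex, batch and dye and correlated
(Pearson, two-sided), and the trans LOD at the peak is recomputed with the
mediator's expression as an additive covariate. The mediator flag requires
p < 0.05 and conditional LOD < 0.5 × unconditional. Mediator→target links
are exported as node/edge tables and a directed graph; no inference is
attempted among the trans targets themselves.

## Integration

Candidate quantitative trait genes must (1) have a local eQTL interval
overlapping the trait QTL interval (half-open Mb semantics) and (2) show a
trait–expression association at p < 0.05 (unadjusted) in a linear model
with dye and batch as covariates, using a joint F-test of expression and
expression-by-sex when the eQTL record carries a sex interaction. The same
model applied across the whole array with a max-statistic permutation test
(trait permuted, maximum |residual correlation| per permutation) yields
transcriptome-wide trait-associated probesets with family-wise error
control. Sweep overlap keeps each sweep's length and chromosome and
redraws its start uniformly; the empirical p is the fraction of null
replicates with at least the observed number of overlapping (QTL, sweep)
pairs. Sweep placement is per-chromosome, unlike the hotspot null's single
1 Gb line, because QTL support intervals live on chromosomes.

## The synthetic study

The generator emulates the real design at configurable scale. Defaults:

- F8 propagation: fully inbred founders, uniformly heterozygous F1,
  then random non-self mating at ~100 individuals per generation; the
  final generation is expanded to the requested sample size (300 by
  default; 471 in trait-recovery calibrations, 130 expression samples).
  The actual mating design of such flocks is rarely published; random
  pairing is a stand-in and is recorded in the output metadata.
- Meiosis: Haldane (Poisson crossovers, uniform positions, no
  interference), consistent with the HMM's transition model.
- Map: six chromosomes, 1500 cM total, 20 markers each (~13–21 cM
  spacing, comparable to a sparse SNP panel on an expanded AIL map);
  physical positions at 0.11 Mb/cM; 15% of markers observed as dominant;
  1% missing genotypes.
- Traits: four mass traits on a gram scale with strong sex dimorphism,
  batch effects at 30% of residual SD across six batches, a shared major
  locus sized to 9% of total variance in intermediate mass, a
  sex-interaction-only locus, a smaller adult-mass locus, and one planted
  additive×additive epistatic pair. Effect sizes are always specified as
  fractions of *total* phenotypic variance, the scale on which variance
  explained is estimated.
- Expression: 3000 probesets (scaled down in tests), log2-scale baseline
  ~N(8,1), unit assay noise, slide/batch and dye offsets, 200 local eQTL
  at the 16%-of-variance scale with random sign, 40 trans eQTL, one
  mediated hotspot (a mediator gene driven by genotype whose *observed*
  expression feeds 8 downstream targets — so conditioning on the measured
  mediator removes the genotype signal by construction), and one causal
  gene whose latent transcript feeds a mass trait, giving the candidate
  screen a true positive.

What the generator does *not* emulate: linkage disequilibrium beyond the
marker map, selection during propagation, founder heterozygosity (marker
informativeness is emulated by masking observation codes instead),
probe-level sequence artifacts, and intensity-dependent (non-additive)
array noise. Passing calibration on synthetic data therefore demonstrates
the statistical machinery under the stated model, not robustness to array
artifacts or mis-specified maps.

## Calibration results computed by the acceptance script

`scripts/acceptance.py` recomputes, from scratch at fixed seeds: the
genome-wide 5%/20% permutation thresholds on a synthetic cross; the null
rejection rate of the 5% threshold over 200 null genome scans; detection,
variance-explained and interval coverage for the planted 9% locus at
n = 471 over 25 seeds; Monte-Carlo vs analytic power for a 16% expression
QTL at n = 130 (this experiment simulates a drift-free intercross with
fully informative markers, matching the analytic assumptions: under F8
drift the realized variance fraction at a planted locus falls below its
nominal value and costs ~4 points of power, and the default 15%
dominant-marker rate costs ~6 more); subsampled
local/trans thresholds and detected eQTL counts on one synthetic study; and
hotspot call/mediator recovery rates over 10 seeds. Problem sizes (replicate
and permutation counts) were chosen so the whole script completes in
minutes at desk scale; all are arguments with larger values available.

Known limitations: variance-explained estimates are mildly attenuated
(typically ~8% recovered for a 9% locus) by partially informative markers;
the two-locus scan uses fixed declaration thresholds rather than
pair-specific permutations by default; the F2-transition approximation
understates information on a strongly expanded map; and the PC-based
family-structure control is a screen, not a mixed model.
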