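# Methods

This note documents the statistical model behind `crossqtl`, the choices
made where the design was genuinely open, and what the synthetic data do and
do not establish.

## Line-origin model

An F2 between two divergent founder lines (here called W, the sire line,
and E, the dam line) carries chromosomes that are mosaics of line-W and
line-E segments.  At a scan position the unobserved "genotype" of interest
is the ordered pair of line origins of the two gametes.  Conditioning each
gamete on its nearest informative flanking markers and assuming no
interference (Haldane map function, r = ½(1 − e^(−2d/100)) for d in cM),
the probability that the transmitted allele is of line-W origin given
flanking origins (O_L, O_R) at recombination fractions r_L, r_R is

    P = p_L p_R / (p_L p_R + (1 − p_L)(1 − p_R)),

where p_L = 1 − r_L if O_L = W else r_L, and likewise p_R.  Beyond the
outermost informative marker only the single flank conditions the
probability; with no informative marker the probability is ½; a scan
position that coincides with an informative marker is its own degenerate
flank.  The two gametes are independent given the parental marker data, so
p_ww, p_we, p_ee are products of the per-gamete probabilities, and the
regression codes are C_a = p_ww − p_ee ∈ [−1, 1] and C_d = p_we ∈ [0, 1].

Conditioning on the nearest informative flanks only (rather than all
markers jointly) is exact here because a no-interference crossover process
is Markov along the chromosome; the test suite verifies the probabilities
against exhaustive enumeration of crossover patterns on toy maps and
against Monte-Carlo gamete simulation.

Marker informativeness is resolved family by family from the pedigree:
each F1 allele is assigned to its founder (breed-labelled) parent wherever
Mendelian logic makes the assignment unique, and each F2 allele is traced
to one of its F1 parent's two alleles the same way.  A marker is dropped
for a gamete when the F1 is homozygous, the trace is ambiguous, or a
genotype is missing; when only one gamete is resolvable the other falls
back to probability ½.

## Models and tests

All tests are F ratios of residual sums of squares between nested
fixed-effect least-squares models on a common base (treatment contrasts;
aliased columns dropped and logged):

    model 1:  y = μ + batch + sex + PPARD + β·cw + e
    model 2:  model 1 + C_a·a + C_d·d
    model 3:  model 1 + CGL_g
    model 4:  model 1 + CGL_g + C_a·a + C_d·d

F = ((RSS_r − RSS_f)/(df_r − df_f)) / (RSS_f/df_f).  The scan evaluates
model 2 vs 1 on a 1-cM grid including both map ends (peak ties broken
toward the smaller position); the standard association test is model 3 vs
1; the marker-assisted test is model 4 vs 2 with the line-origin terms
taken at the QTL peak; the F-drop test compares the model-2-vs-1 peak
F(QTL) with the model-4-vs-3 statistic F(drop).

**Where F(drop) is read off.**  Two conventions exist: the maximum of the
adjusted (model 4 vs 3) curve, or its value at the position where the
unadjusted curve peaks.  For a SNP that fully captures the QTL the adjusted
curve is a null F process, and the chromosome-wide maximum of a null 2-df F
process over ~115 cM has median ≈ 3 and a long upper tail, so the peak-wise
convention measures the extreme-value behaviour of noise rather than the
residual QTL signal, and caps the achievable drop fraction well below what
a causal variant deserves.  `crossqtl` therefore reads F(drop) at the
F(QTL) peak position by default — comparing like with like at the mapped
QTL — and offers the peak-wise alternative via `mode="peak"`.

**Variance explained** is defined as the residual-variance reduction
relative to the base model, 100·(RSS_base − RSS_qtl)/RSS_base.  Other
definitions exist; this one is declared, not asserted to match any
particular legacy software.

**Permutation threshold.**  Phenotype records, with their fixed-effect
covariates attached, are permuted against the origin data; the maximum F
over the scan is recorded per permutation and the threshold is the
empirical (1 − α) quantile of the maxima.  Family structure is deliberately
ignored by the shuffle (the classical genome-scan permutation scheme).
Implementation note: permuting (y, X) jointly against the states is
algebraically identical to permuting the state rows, which lets the scan
reuse one orthonormal basis of the base design; each position then costs a
2×2 solve on residualised regressors, making 1000 permutations a
sub-second affair at n ≈ 1000.

**Bootstrap CI.**  Individuals are resampled with replacement, the
chromosome is re-scanned, and the 2.5/97.5 empirical percentiles of the
peak positions form the 95% CI.  A resample in which a declared factor
collapses to a single observed level is skipped and logged.

**Outbred validation lines** are analysed separately per line (no pooling
across stratified populations): a one-way genotype ANCOVA with any declared
covariates, pairwise contrasts adjusted by the studentized range
(Tukey–Kramer), and compact significance letters.

**Haplotype association.**  Tight SNP windows (≪ 1 cM) are phased by
Mendelian transmission plus a minimum-recombination rule (the transmitted
allele string must match one of the parent's haplotypes); unresolved
individuals are excluded, never imputed.  Phenotypes are pre-corrected for
batch, sex, carcass weight and additive infinitesimal effects by solving
the mixed-model equations with animal effects u ~ N(0, A·σ²_a), where A is
the exact (tabular-method) numerator relationship matrix and
λ = σ²_e/σ²_a comes from a user-supplied heritability (default 0.4, the
simulator's truth; REML estimation is out of scope, which keeps the stage
deterministic).  The corrected residuals are regressed on each haplotype's
copy number separately; P-values are Bonferroni-multiplied by the number
of haplotypes and capped at 1.  The joint variance explained drops one
copy column to break the rows-sum-to-2 aliasing.  Haplotypes absent from
the analysed subset are dropped with a log message.  The PPARD genotype is
not part of this correction: the correction mirrors the stated
batch/sex/weight/infinitesimal adjustment, while PPARD enters only the
four-model framework.

## The synthetic cross

The generator mirrors the study design: 2 line-W sires × 17 line-E dams,
9 F1 boars × 59 F1 sows chosen from their offspring, matings drawn at
random avoiding full-sib pairs, 1912 F2 of which 1029 are phenotyped.
Meiosis draws per-interval crossover indicators with Haldane-consistent
probabilities (no interference, consistent with the analysis model).

Defaults, chosen once from the published summary statistics and not
revisited:

| parameter | default | unit | rationale |
|---|---|---|---|
| linkage map | the 11-marker SSC5 map, Acr … SW995 (115.2 cM) | cM | printed map |
| QTN position | 60.7 (at SW1904) | cM | middle of the mapped QTL |
| additive effect a | −32.84 (line-W allele shrinks the ear) | cm² | printed additive effect |
| dominance d | 0 | cm² | no printed dominance |
| QTN variance share | ≈ 20% of post-fixed-effect variance | — | the QTL explained >17% |
| polygenic/residual split | h² = σ²_a/(σ²_a+σ²_e) = 0.4 | — | typical conformation-trait heritability |
| σ²_a, σ²_e | 862.7, 1294.1 | cm⁴ | implied by the two ratios above |
| μ, batch, sex, β·cw | 290; ±≈10; 12; 0.9 × N(75, 8²) | cm², kg | plausible ear-surface scale |
| PPARD-like unlinked QTL | a = −30, line-fixed | cm² | a second detected QTL held as fixed effect |
| microsatellites | 4–8 alleles, line-divergent geometric frequencies | — | divergence is a config knob |
| candidate window | snp_a (60.45), qtn (60.7), snp_b (60.95) | cM | a 0.5-cM gene-sized window |

The QTN is fixed for alternative alleles in the founder lines, so its
genotype equals its line-origin genotype — the cleanest version of "the
candidate is the QTN".  Window SNPs are divergent but segregate within
lines, which is what makes eight haplotypes appear in the F2.  Polygenic
values are generated recursively (parent average + Mendelian-sampling
deviation), which is exactly A-consistent here because no inbred animal is
itself a parent.  Carcass weight is independent of the QTN; batch is
uniform over 6 levels; sex is Bernoulli(½).

Scenarios: `paper_like` (full design), `qtn_genotyped` (the causal SNP
among the candidates), `null` (a = d = σ²_a = 0 at a scaled-down n = 400,
for calibration), `outbred_line` (a single 173-animal validation line with
genotype-class probabilities 0.52/0.44/0.04 and class means
258.6/292.6/323.5 cm²).

What the simulator does **not** emulate: genotyping error, missing-data
patterns, litter/maternal environment, selection, sex chromosomes, and any
within-line LD structure beyond what drift in 19 founders creates.  Tests
passing on these fixtures therefore establish the correctness and
calibration of the machinery under the declared generative model, not the
numerical values of the original study, whose raw data were never
deposited.

## Numerical choices and edge cases

* Rank deficiency: QR with column pivoting; aliased design columns are
  dropped and logged; a candidate whose genotype is fully aliased with the
  base model raises.
* The 2×2 position solve falls back to a 1-df test when the residualised
  (C_a, C_d) pair is numerically singular (relative determinant ≤ 1e-10).
* Degenerate resamples (a factor with one observed level) are skipped, not
  refitted.
* drop_fraction is NaN (flagged) when F(QTL) ≈ 0.
* Missing genotypes are "0"/"NA"; records with missing model variables are
  dropped with a logged count, and nested fits always share one record set.
* All randomness flows from one integer seed through
  `numpy.random.default_rng`; identical (inputs, config, seed) give
  byte-identical output bundles.

## Problem sizes used by the checks

The test suite exercises the full 1912/1029 design where the claim depends
on it (F-drop reproduction, effect recovery), and scaled-down crosses where
only calibration is at stake: 1000 null fixtures at n = 400 with 200
permutations each for the type-I rate of the 5% threshold, and 100
replicates at n = 600 with 200 bootstrap iterations for CI coverage.
These sizes keep Monte-Carlo error small relative to the acceptance bands
(binomial SE ≈ 0.7 percentage points at 1000 fixtures; ≈ 2.5 at 100
replicates).

## Known limitations

* Variance components are inputs, not estimates (no REML); the haplotype
  stage inherits whatever heritability is supplied.
* Phasing is pedigree-transmission logic for tight windows only; it is not
  a population-scale phasing algorithm and leaves multi-heterozygous
  founders unresolved.
* The marker-assisted test has little power when the map markers are
  nearly fully informative at the causal position (the line-origin terms
  already absorb the QTN); its ranking value comes from designs where the
  QTN sits between markers.
* Only a single-chromosome, single-QTL scan is provided; additional known
  QTL enter as fixed effects, not as a multi-QTL model.
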