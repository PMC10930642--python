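# Methods

This note records the models implemented in `rohscan`, the defaults and why
they were chosen, the numerical decisions, and what the synthetic-data tests
do and do not establish about real chip data.

## Quality control

Two marker sets are built from the same raw data because ROH analysis and
association testing want different things:

* **GWAS profile** — samples kept when call rate > 0.90 (removal at exactly
  0.90, i.e. "remove if ≤ threshold"); markers kept when call rate ≥ 0.95,
  at most two observed alleles, and MAF ≥ 0.01; then LD pruning; autosomes
  plus X retained (an all-female cohort makes X dosage 0/1/2 valid).
* **ROH profile** — the same sample and call-rate/biallelic filters, but no
  MAF filter and no LD pruning (rare-allele and high-LD markers carry real
  homozygosity signal), and the X chromosome is dropped because F_ROH is
  defined on the autosomal genome.

Filter order is fixed: samples → (X drop, ROH profile) → call rate →
biallelic → MAF → LD. MAF uses post-sample-filter genotypes with missing
calls excluded from denominators.

LD pruning is greedy and windowed in the `indep-pairwise` style: within a
window of 50 markers, while any pair of kept markers has genotype r² > 0.5,
drop the pair member with the lower MAF (tie: the later position), then
slide by 5 markers. Because removals re-window the survivors, a single pass
is not a fixed point; `build_dataset` iterates pruning until no marker is
removed, which makes the whole QC chain idempotent. Window, step and r² are
configurable; no published tool settings are being reproduced, so exact
survivor counts from any particular study are not an expectation.

## ROH calling

A segment is reported when all four rules hold: ≥ `min_snp` (25) homozygous
markers, span ≥ `min_length_bp` (1,000,000; positions are 1-based inclusive
and length is `end − start + 1`), zero heterozygotes, and at most
`max_missing` (5) unread markers inside the run. Segments are trimmed to
homozygous endpoints so missing edge markers never extend a span.

The missing-call budget is per segment. Within a heterozygote-free stretch
the caller enumerates, with a two-pointer sweep, every window that is
*maximal under the budget* (extending it in either direction would exceed
five missing calls or hit a heterozygote/chromosome end), keeps those
passing the SNP-count and span rules, and then selects them disjointly from
the left. This reproduces "a sixth unread call splits the run" behavior
while guaranteeing the reported segments of one sample never overlap and
that each is maximal. The linear-time scan is validated in the test suite
against a quadratic enumerator that checks every subinterval independently.

Length classes are half-open on the left: [1,2), [2,4), [4,8), [8,16),
[16,∞) Mbp, so every qualifying length maps to exactly one class and a
2.000000 Mbp segment is "2–4".

Cohort summaries follow the convention that per-class mean/SD/median/min/max
are computed over animals that have at least one ROH of that class (the
only convention under which per-class minima such as a 16.282 Mbp ">16"
minimum are meaningful when many animals have none); how common absence is
appears separately as a percentage per class. SD is the sample standard
deviation (n−1). The grand mean ROH length is Σ lengths / Σ counts.

## Genomic inbreeding

F_ROH = Σ segment lengths / L_auto per animal, with the denominator fixed at
the published *Bos taurus* autosome length 2,512,082,506 bp rather than the
sum of covered map lengths — this makes results comparable across chips and
reproduces the standard worked arithmetic (433.37 Mbp of ROH → F_ROH 0.173).
Simulated genomes pass their own length. Per-class F_ROH uses the same
denominator, so class values add exactly to the total. Overlapping input
segments are rejected (they indicate an upstream bug, and would double-count
coverage). Tables round to 3 decimals; files keep full precision.

## ROH islands

The per-marker statistic is the percentage of animals with at least one ROH
covering the marker (an animal counts once even if overlapping segments
cover a marker twice). Islands are maximal runs of consecutive markers at or
above the threshold — inclusive at the default 30%, matching "present in at
least 30% of the population" — with coordinates on the member-marker span so
they are reproducible from the marker map alone. A minimum marker count per
island (default 1) can suppress singletons. Note that raising the threshold
monotonically shrinks total island extent but can transiently increase the
island *count* when a wide island splits at an interior dip.

## Association models

* **Kinship** is VanRaden method 1: columns centered by 2p̂ and the
  cross-product scaled by 2 Σ p̂(1−p̂), on mean-imputed dosages with
  monomorphic markers excluded. Because p̂ is estimated from the sample, the
  matrix has exactly zero row sums, so off-diagonals of an unstructured
  cohort centre on −mean(diag)/(n−1), not on zero.
* **PCs**: top eigenvectors of the standardized genotype matrix via SVD;
  sign fixed by making each component's largest-magnitude marker loading
  positive, so results are deterministic.
* **GLM**: per-marker OLS of the trait on intercept + covariates + dosage,
  two-sided t-test on the dosage coefficient, vectorized by residualizing
  both trait and dosages on the covariate block. Missing phenotypes drop the
  sample from that trait's scan; missing dosages are mean-imputed per
  marker; constant-dosage markers are flagged untestable with β = 0, p = 1.
* **MLM**: y = Xb + gβ + u + e, u ~ N(0, σ²_g K). Null-model REML profiles
  the restricted likelihood over the variance ratio δ = σ²_e/σ²_g after
  rotating by the eigenvectors of K: a 61-point grid on log₁₀ δ ∈ [−5, 5]
  followed by bounded scalar refinement. Markers are then tested by GLS with
  the components fixed (P3D/EMMAX); exact per-marker REML re-estimation is
  available behind a flag for small problems. When REML pins δ at its upper
  bound (no detectable polygenic variance) the scan switches to the exact
  OLS path, so the σ²_g = 0 limit reproduces the GLM to machine precision
  rather than to grid resolution.
* p-values are floored at the smallest positive representable double, never
  reported as 0. λ is the median of the χ²₁ quantiles of the p-values over
  the exact χ²₁ median, so a degenerate all-0.5 input gives exactly 1.
* Bonferroni threshold is α/m over testable markers, α = 0.01 by default.
* Of the many published GWAS model families, only GLM and the single-locus
  kinship MLM are implemented; multi-locus and compressed variants
  (MLMM, FarmCPU, SUPER, CMLM and relatives) are distinct algorithms out of
  scope here — the two implemented models bracket the unadjusted and
  structure-adjusted ends of the single-locus spectrum.

## Synthetic data

The simulator is forward-in-time with explicit founder bookkeeping: every
chromosome of every individual is a mosaic of founder-haplotype segments,
gametes recombine with Poisson crossovers at 1 cM/Mbp, and an interval is
*truly* autozygous exactly when both gametes carry the same founder
haplotype. Truth is therefore independent of the genotypes the ROH caller
sees, which makes F_ROH accuracy a real measurement rather than a circular
one.

Defaults and rationale:

* cohort of 334 females; genome scaled down to 5 autosomes × 50 Mbp with
  1,000 markers each (20 markers/Mbp, matching medium-density chip spacing)
  so the full pipeline runs in seconds; `chip_like_config()` approximates a
  29-autosome, ~63k-marker array for demonstrations;
* founder allele frequencies Beta(0.5, 0.5) truncated to [0.05, 0.95]
  (the U-shaped spectrum typical of ascertained SNP panels), LD from a
  first-order copying process with neighbor-copy probability 0.5;
* 40 founder haplotypes, 6 generations, and a 0.3 fraction of sib matings
  per generation — chosen so that realized F_ROH lands near 0.05–0.15
  (typical of intensively selected dairy cattle) and all five ROH length
  classes are populated;
* genotyping noise of 1% missing calls and 0.1% heterozygote errors applied
  after truth is frozen; recovery experiments that state "error-free" set
  both to zero;
* sweeps replace both haplotypes of a carrier fraction with one founder
  haplotype over a region, guaranteeing a shared homozygous tract; QTL
  phenotypes are y = μ + β·dosage + u + e with the polygenic share drawn
  from N(0, σ²_g K) and β set from the requested variance fraction.

What passing tests show — and what they do not: the simulator produces
realistic run-length structure, family relatedness and planted signals, but
its LD is first-order (no long-range haplotype structure), allele
frequencies are stationary, there is no genotyping batch structure, and X
inheritance is treated as autosomal (defensible only because the cohort is
all-female). Thresholds verified here (e.g. F_ROH within 0.02 of truth at
20 markers/Mbp) should transfer to real chips of similar density but are
not guarantees under heavy genotyping error or very different demography.

## Problem sizes used in the checks

The recovery and calibration checks run at deliberately moderate sizes
chosen as this package's own validation design: 500 random chromosomes of
≤ 200 markers for oracle equivalence, a 100-animal error-free cohort for
F_ROH recovery, 150-animal cohorts for island recovery, and twenty
300-animal × 5,000-marker structured cohorts for mixed-model calibration
and power. At n = 300 the power of a Bonferroni-corrected (α = 0.01/5,000)
single-marker test for a QTL explaining 5% of phenotypic variance is about
20% by noncentral-χ² arithmetic — detection of such a QTL at this sample
size is expected to be sporadic, and the power figure the acceptance script
reports should be read against that baseline.

## Known limitations

* The ROH caller implements fixed-count consecutive-homozygote rules, not
  sliding-window scanning with proportional thresholds.
* No Hardy–Weinberg or relatedness-based sample QC.
* The binary PLINK reader trusts the .bim A1 allele as the counted allele;
  only the text reader re-derives minor-allele coding.
* Exact per-marker REML is O(markers × REML) and intended for small
  problems only.
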