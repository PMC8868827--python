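# Methods

## Scope and data model

The package reimplements, as a tested pipeline, an analysis of coordinated
*BRCA1/2* and homologous-recombination (HR) gene expression in ovarian
tumors measured with digital counting assays. The central container is a
`CountMatrix`: genes × samples nonnegative counts with a per-gene probe
class (endogenous, housekeeping, positive control, negative control) and a
pathway label. Sample sheets carry the group (tumor vs fallopian-tube
control) and replicate linkage. Since no public count data accompany the
study design, a synthetic-data module generates studies with the same shape
and statistical structure; it is first-class, tested code.

## Synthetic study generator

Counts are Poisson with log-normal means. For endogenous gene *g* in
sample *s*:

    K_gs ~ Poisson(L_s · E_s · μ_g · effect_gs · latent_gs · noise_gs) + B_gs

* `L_s` — lane size factor (RNA input), log-normal with σ = 0.25;
* `E_s` — lane hybridization efficiency, log-normal σ = 0.15, also scaling
  the positive-control titration (a 4-fold geometric series over 6 probes,
  top 16,384 counts);
* `μ_g` — per-gene baseline, log-normal around a median of 200 counts
  (σ = 1.0 on the log scale); housekeeping genes use a higher, tighter
  baseline (median 800, σ = 0.3) as reference transcripts should;
* `effect_gs` — multiplicative tumor effect: 2.0 for the 47 designated
  upregulated genes (the 14-gene HR module plus filler genes), 0.5 for the
  25 downregulated genes;
* `latent_gs = exp(σ_f · f_s − σ_f²/2)` — a shared per-sample factor
  applied to the HR module genes (BRCA1, BRCA2 and the 12 HR targets).
  The log-scale pairwise correlation between two module genes is
  σ_f²/(σ_f² + σ_n²); the defaults σ_f = 0.49, σ_n = 0.40 place it at
  ≈ 0.6, the regime of the observed anchored statistics (~0.59–0.69).
  Spearman on counts is mildly attenuated relative to this latent value
  (rank transform of a bivariate log-normal plus Poisson noise), which the
  generator tests account for with a ±0.15 band;
* `noise_gs` — per-cell log-normal noise, σ_n = 0.40 (the study reports no
  dispersion estimates; this value gives count CVs in the range typical of
  panel data and makes the downstream tests informative rather than
  saturated);
* `B_gs ~ Poisson(5)` — additive background, the same process that the
  negative-control probes observe directly.

Two samples (the first normal and the first tumor) are re-run as replicate
columns: independent Poisson redraws of the same lane mean, mirroring
repeat runs with different reagent batches. Droplet wells draw each droplet
independently positive with probability `1 − exp(−c·V_d)`; when a droplet
count is not specified it is drawn uniformly from the observed plausible
range 5,549–19,264. Every generator consumes one explicitly seeded
`numpy` Generator; a fixed seed gives byte-identical output.

What the generator does **not** emulate: FFPE degradation kinetics and
fragment-length effects, probe-specific hybridization efficiencies beyond a
gene-level baseline, imaging or binding-density artifacts, droplet "rain"
(intermediate fluorescence), and any real covariance structure beyond the
single shared HR factor. Passing tests therefore demonstrate correctness of
the statistical machinery under the stated model, not performance on any
particular clinical cohort.

## Normalization chain

Order: background → positive control → housekeeping → exclusion →
replicate averaging.

1. **Background**: subtract the per-sample mean of the negative controls
   from endogenous and housekeeping counts, clamped at 0. Mean (not
   mean + 2SD) is the default statistic; `mean_sd` with configurable k is
   available. Control rows are retained unmodified for audit.
2. **Positive controls**: per-sample factor = grand arithmetic mean of the
   per-sample geometric means of the positive controls, divided by that
   sample's geometric mean. The factor multiplies endogenous, housekeeping
   and positive-control rows, so factors recomputed on the output are
   exactly 1. Factors outside [0.3, 3] set a QC flag; samples are flagged,
   never dropped — dropping is the caller's decision.
3. **Housekeeping**: per-sample factor = grand mean of per-sample
   housekeeping means over that sample's housekeeping mean, applied to
   endogenous and housekeeping rows; housekeeping means are exactly equal
   across samples afterwards.
4. **Exclusion**: the canonical 12-gene defective-TagSet list (ERCC1–8,
   EXO1, FAN1, FANCA/B/C) leaves 168 of 180 endogenous genes; absent genes
   warn rather than error.
5. **Replicates**: replicate groups of any size collapse to the per-gene
   arithmetic mean under the base sample's id.

Values stay real-valued after normalization (no re-rounding): the
downstream test is rank-based and rounding would only discard information.

## Differential expression

Per gene, counts are rank-transformed across all samples pooled (average
ranks on ties), then Welch's unequal-variance t statistic compares the two
groups' rank subsets, with Welch–Satterthwaite degrees of freedom and a
two-tailed Student-t p-value. Bonferroni multiplies by the number of genes
actually tested (endogenous survivors plus the housekeeping genes, which
are tested identically — housekeeping genes can and do reach
significance); the multiplier is configurable. log2 fold change is the
log-ratio of group arithmetic means of normalized counts; the reported
direction follows the sign of the fold change. A gene with a nonpositive
group mean gets a missing fold change and a flag.

**Known limitation**: with bounded ranks and groups of 11 vs 38, the
Student-t reference is anti-conservative in the extreme tail. At the
Bonferroni threshold 0.05/180 the per-gene tail probability is inflated
roughly four-fold even on iid null data, so strict family-wise control at
0.05 is approximate (measured ≈ 0.17 over simulated null studies, with a
mean of ≈ 0.2 false-positive genes per study). The bulk of the p-value
distribution is well calibrated, and the regression tests pin exactly
that: bulk uniformity plus rare false discoveries. An exact permutation
reference would remove the inflation at the cost of per-gene permutation
loops; it is out of scope because the rank-t form is the method under
study.

## Clustering

Rows are standardized to mean 0 / SD 1 (sample SD, n−1); zero-variance
rows are dropped with a warning. Distances are `1 − Spearman ρ`; both gene
and sample axes are clustered with complete linkage on the scaled values
(for the gene axis the scaling is a per-row affine map and leaves Spearman
untouched — asserted as a test). The agglomeration is written out
explicitly so ties always merge the lexicographically smallest index pair,
giving identical dendrograms across platforms; the merge table uses the
standard linkage-matrix layout so scipy's tree utilities (leaf order,
maxclust cuts) operate on it directly, and heights are checked against
both an exhaustive oracle (≤6 points) and scipy's implementation.

## Co-regulation statistic

Observed statistic: Spearman ρ between the anchor and each target gene
across samples, pooled as `tanh(mean(atanh ρ))` (Fisher Z). |ρ| = 1 is
clamped at 1 − 10⁻¹² with a warning. Null: m random size-k subsets of a
candidate pool drawn without replacement (with-replacement available via
flag); the anchor is excluded from the pool, while the designated targets
remain in it — the draws must be exchangeable with the observed set for
the empirical p to be uniform under the null. Because the per-gene ρ does
not depend on the subset, correlations are computed once and each draw
pools a random subset of precomputed z′ values — algebraically identical
to recomputing the statistic per draw, which is what makes 10,000
iterations instant. Each draw uses the same Fisher pooling as the observed
statistic, and the null mean is the Fisher-pooled mean of the draws.
`P = (n+1)/(m+1)` with n counting draws ≥ observed under exact float
comparison; P is never 0 and never exceeds 1. Median splits for
descriptive group plots put ties in the low group by default
(`ties="high"` mirrors the alternative figure-legend convention).

## NMD rules

Coordinates are 1-based, fully closed, on the spliced transcript; all
distances are measured from the first nucleotide of the stop codon. For a
frameshift the variant is first applied to the transcript (exon lengths
and sequence edited; insertions land after the given position, deletions
remove a closed interval), and the mutant CDS is read codon by codon from
the start codon; the first stop codon is the PTC, and reading to the end
without one sets a `nonstop` flag (call `not_applicable`). The three rules:
distance to the last exon–exon junction > 50 nt (configurable 50–55; 50,
the permissive classical boundary, is the default), exon count > 2, and
distance from the start codon > 200 nt. The combined call is the strict
conjunction; refinements beyond these three positional rules (long last
exons, start-proximal reinitiation) are deliberately not implemented.

## ddPCR quantitation

`λ = −ln(negatives/total)` copies per droplet; `c = λ/V_d` copies/µL. The
droplet volume is always an explicit parameter recorded with every
estimate: 0.00085 µL is the instrument nominal, 0.001 µL the convention
under which 0.05 CPD ≡ 50 copies/µL (the package default, matching the
loading-scheme arithmetic). The 95% CI uses the delta method,
`SE(λ) = sqrt(p̂/((1−p̂)·N))`; simulated-well coverage stays within
93–97% across occupancies 0.01–1.5 CPD. Saturated wells report a finite
lower bound from half a pseudo-negative instead of infinity; zero-positive
wells report c = 0 with a rule-of-three upper bound. Duplex ratios use the
delta method on the log-ratio treating the channels as independent — they
share droplets, and the approximation is conservative at low occupancy.
The input-equalization scheme scales the second assay's RNA mass linearly
to put the reference gene at 0.05 CPD, flagging loads above a configurable
maximum (default 100 ng). No-RT controls fail above 0.2 copies/µL, just
above the maximum contamination level seen in accepted runs (0.16).
Cross-platform concordance reports Spearman and Pearson correlations on
paired samples and flags samples whose between-platform rank difference
exceeds half the cohort size — the signature of a single clearly
discordant sample in an otherwise monotone relation; the fraction is a
free parameter.

## Problem sizes and determinism

The simulation-based checks use: 1,000 wells of 15,000 droplets for
estimator bias, 2,000 wells for CI coverage, 500 null studies at m = 200
draws for permutation-test calibration, 100 seeded studies at m = 1,000
for power, 200 null studies for differential-expression calibration, and
20 studies for cluster-separation purity. These sizes put Monte Carlo
error comfortably inside each asserted band while keeping the full suite
around a minute of compute. All stochastic tests fix their seeds;
hypothesis-based property tests run derandomized.
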