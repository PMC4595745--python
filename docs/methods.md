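# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `sortedseq`.

## Quantification

Library size is the column sum over **all** rows, spike-ins included, for
CPM, FPKM and TPM alike, and spike-in rows are included in the TPM
denominator ("the sum of all FPKM values" is read literally). This makes
spike TPM directly comparable to endogenous TPM, which the copies-per-cell
calibration relies on: the spike-to-endogenous read ratio is then encoded
in the TPM values themselves. `compute_tpm(..., exclude_spikes=True)`
restricts the denominator to endogenous genes for users who prefer the
other convention.

The expression filter (CPM > 1 in ≥ 3 samples) and the DEG abundance
screen (group mean CPM > 20) use strict inequalities and **raw** library
sizes (no TMM), because both are applied before model-based normalization
is meaningful. Thresholds are `RunConfig` parameters.

## Differential expression

The engine re-implements the precision-weighted moderated-t workflow and
is verified in the test suite against the reference R implementation
(edgeR's TMM and limma's voom/lmFit/eBayes) on a small fixture, agreeing
to ≈1e-10 in factors, coefficients, t and p, including the estimated
prior degrees of freedom.

*Normalization.* TMM with double trimming: 30% of genes from each tail of
the M (log-ratio) distribution and 5% from each tail of the A (abundance)
distribution; weights are inverse asymptotic binomial variances; the
reference sample has the upper-quartile count proportion closest to the
mean; factors are rescaled to product 1. A sample with no expressed
overlap against the reference receives factor 1 with a warning.

*Weights.* y = log₂((count + 0.5)/(lib·factor + 1)·10⁶). The
mean–variance trend is a lowess (span 0.5, 3 robustness iterations,
delta = 1% of the x-range) of √(residual sd) against mean log₂ count from
unweighted per-gene fits; each observation's predicted standard deviation
is interpolated at its fitted log-count and **clamped to the trend range at
the extremes**; weight = predicted sd⁻⁴. Genes with zero counts in every
sample are excluded before fitting (their variance is undefined).

*Design and contrasts.* One coefficient per (cell type, condition) group,
no intercept; default contrasts are deprived-vs-fed within each cell type
plus the between-cell-type comparison at the fed baseline. All samples are
fitted jointly so the variance trend and the shrinkage prior are shared
across contrasts. Whether the original analysis fitted jointly or
pairwise is not documented; the joint fit is this package's choice.

*Moderation.* Residual variances are shrunk by moment matching on log
variances: with e = log s² − ψ(d/2) + log(d/2), the excess variance of e
over ψ′(d/2) is inverted through the trigamma function (Newton iteration,
relative tolerance 1e-8) to give d₀, and s₀² follows from the mean. If
the moment equation has no positive root, d₀ = ∞ and every gene receives
s₀² (the complete-shrinkage limit); `d0_override` exposes the d₀ = 0
(ordinary WLS) and d₀ = ∞ limits for testing. p-values use the t
distribution with d₀ + d_g degrees of freedom (normal when d₀ = ∞).

*Multiple testing.* BH step-up per contrast, computed over the genes that
entered that contrast's fit.

## Permutation FDR

Labels travel as (cell type, condition) pairs, so permuted designs have
exactly the original group sizes; per-sample covariates (cell counts)
stay put. The identity labeling is not excluded — with 21 samples its
probability is negligible. By default every permutation re-runs the whole
pipeline including TMM and the variance trend (the conservative choice;
`refit="reuse-factors"` keeps the observed factors). Empirical FDR is
undefined (NaN, flagged) when a contrast has zero observed DEG, never 0.

## Spike-in calibration

*Detection.* Each (spike, sample) pair is scored detected when its count
reaches the threshold (default 1 — the weakest presence/absence reading;
a parameter). Outcomes are pooled across samples into one
maximum-likelihood logistic fit on log₁₀(copies × kb), reflecting a single
assay-level sensitivity. The profile-likelihood interval for x₅₀ profiles
the slope at fixed midpoint and inverts the likelihood-ratio statistic at
the 95% χ²₁ cutoff. Perfect separation returns a censored result bounded
by the separating gap rather than an error. A caveat documented here
because it matters for interpretation: when the true detection law is
Poisson capture, P(detect) = 1 − e^(−rate·x) is asymmetric on the log
axis, and the symmetric logistic's midpoint sits systematically ~10–20%
below the true 50% point depending on how heterogeneous sequencing depth
is across samples. The logistic form is retained as the conventional
dose–response choice; the bias is within the package's validated
tolerance at study-like depth spread.

*Copies per TPM.* Per sample, OLS of log₁₀(copies) on log₁₀(TPM) over
detected spikes (TPM > 0); a sample needs ≥ 6 detected spikes spanning
≥ 2 decades of copy number or it is excluded with a logged warning.
Copies per cell at 1 TPM = 10^intercept / n_cells, aggregated as
mean ± sd across samples. At shallow (desk-scale) depth 1 TPM corresponds
to only ~1–2 reads, so detection truncation inflates TPM at the low end
and biases the estimate downward by roughly 20%; at published sequencing
depth this regime lies far above the detection limit.

## Profile analysis

Sample distance is 1 − Pearson r of log₂(TPM + 1) over genes with group
mean CPM > 20 in at least one group; the expression scale of the original
correlation computation is not documented, and log TPM is this package's
choice (configurable). MDS is classical Torgerson scaling (deterministic;
eigenvalues reported so the discarded mass is visible), not non-metric.
DEG clustering standardizes genes, correlates across samples, and applies
average linkage to 1 − r; zero-variance genes are dropped with a warning.
Purity is (reference + 1)/(sample mean + 1) per marker — the pseudocount
of 1 TPM protects against division by zero. The splicing test is the
classical pooled-variance unpaired one-tailed t (deprived > fed), with
Welch available by flag; groups that are numerically constant return
t = 0, p = 0.5 rather than 0/0.

## Synthetic data generator

The generator emulates the sorted-pool study at desk scale: 21 samples in
four groups (AGRP fed n=5, AGRP FD n=6, POMC fed n=5, POMC FD n=5), pools
of 44–214 cells (lognormal, median 100), library sizes lognormal with
mean 10⁶ and log-sd 0.35 (about a two-fold spread either way, matching
the relative depth spread of pooled-cell libraries; absolute depth is a
parameter and is far below a production run's tens of millions).

Endogenous counts are negative binomial with lognormal baseline
abundances (log-sd 1.6) and lognormal per-gene dispersions,
median 0.05 and log-sd 0.5, independent of abundance. The dispersion
level was calibrated so that a two-fold change at comfortable abundance
(CPM ≥ 20) is detected at q < 0.05 with ≈80% sensitivity at this
replication — the stated detection power of the emulated design. DEG
fractions are asymmetric between cell types (5% AGRP-FD, 0.5% POMC-FD,
4% between cell types) with effects ± Uniform(1, 3) in log₂ units.

Spike counts are Poisson with mean rate·copies·length·depth, so the true
detection midpoint has the closed form x₅₀ = ln 2/rate; the default rate
ln 2/22 per copy × kb places it at 22 copies × kb. The ladder is 92
species over 23 two-fold dilution levels with lengths 0.25–2 kb. The true
copies-per-cell at 1 TPM is computed from the expected count matrix
(ratio of expectations) and stored in the ground truth.

A designated transcript is emitted as spliced/unspliced isoform rows via
a per-condition binomial split of its (negative binomial) parent count —
the split conserves the parent total exactly — with spliced fractions
0.074 (fed) and 0.156 (FD), emulating Xbp1 splicing under energy deficit.
Trace contamination places non-neuronal marker genes (astrocyte,
oligodendrocyte, microglia, endothelial; four each) at 0.1% of their
reference expression of 1000 TPM.

Randomness uses one master seed spawned into per-stage substreams
(abundance, dispersion, effects, libraries, counts, spikes, splicing,
gene sets), so datasets are bit-reproducible and stages are isolated.
`generate_null_dataset` zeroes every group effect, including the
splicing-fraction difference.

What the generator does **not** model: sample correlation or batch
effects beyond library size, abundance-dependent dispersion trends,
UMI/read-level structure, isoform families beyond a single binary split,
and GC/length capture bias. Passing tests therefore demonstrate
correctness of the statistical machinery under the assumed count model,
not robustness to every artefact of real libraries.

## Validation problem sizes

The end-to-end checks run at 2,000 genes with the study's replication:
null calibration on 50 replicate null datasets (p-value uniformity by KS;
per-contrast zero-DEG rate ≥ 95%); permutation FDR on a 5%-DEG dataset at
200 permutations (median permuted count 0, empirical FDR < 5%); spike-in
x₅₀ and copies-per-cell recovery averaged over 20 seeds (within 15% and
25% respectively); log₂ fold-change recovery over 20 seeds (mean
sign-aligned bias < 0.15 for programmed effects ≥ 1 at CPM ≥ 20). Core
statistics are additionally checked against independent brute-force
oracles (naive TMM, per-gene WLS loops, exhaustive hypergeometric
enumeration for universes ≤ 12, pairwise correlation loops, MDS
reconstruction of known configurations) and against the R reference
implementation of the DE chain.

## Known limitations

- The moderation is the classical (non-robust) moment-matching variant:
  genes in the extreme dispersion tail are tested slightly
  anti-conservatively, which is visible as occasional single false DEG
  under label permutation — the same behaviour the empirical-FDR
  evaluation is designed to quantify.
- The logistic detection midpoint and the copies-per-TPM intercept carry
  the systematic biases described above; both are small relative to the
  assay's sample-to-sample variability but are not zero.
- Gene identifiers are opaque strings; annotation, isoform inference and
  upstream read processing are out of scope.
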