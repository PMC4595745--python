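# sortedseq

Cell type-resolved RNA-seq analysis for pooled sorted neurons.

`sortedseq` implements the complete downstream analysis used to profile
manually sorted hypothalamic AGRP and POMC neurons under fed and 24-h
food-deprived (FD) conditions: each sample is a pool of ~50–200 fluorescent
neurons from one mouse, sequenced deeply, with ERCC spike-ins added to the
tube. Starting from a gene × sample count matrix the package provides

- **Quantification** — CPM, FPKM and TPM exactly as defined for this assay
  (FPKM = counts / exon kb / library millions; TPM = FPKM rescaled to sum
  to 10⁶ per sample), plus the expression filter (CPM > 1 in ≥ 3 samples)
  and per-group mean CPM.
- **Spike-in calibration** — a maximum-likelihood logistic model of spike
  detection against log₁₀(copies × kb) whose 50% point
  x₅₀ = 10^(−β₀/β₁) summarizes assay sensitivity, and a per-sample
  log–log regression of spike copies on TPM that converts 1 TPM into
  absolute transcript copies per cell.
- **Differential expression** — a re-implementation of the
  TMM + precision-weight + moderated-t workflow: per-sample trimmed-mean
  (M-value) normalization factors; log₂-CPM with a lowess mean–variance
  trend inverted into observation weights w = s̄(μ)⁻⁴; per-gene weighted
  least squares on a group-means design; empirical-Bayes variance
  shrinkage s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g) with (d₀, s₀²) from
  moment matching on log variances; moderated t with d₀ + d_g degrees of
  freedom; Benjamini–Hochberg q-values; and the DEG rule
  q < 0.05 ∧ |log₂fc| > 1 ∧ group mean CPM > 20 in ≥ 1 group.
- **Permutation FDR** — the (cell type, condition) label multiset is
  shuffled across samples and the *entire* pipeline re-run per
  permutation; empirical FDR = 100 × mean(permuted DEG)/observed DEG.
- **Enrichment** — upper-tail hypergeometric over-representation of gene
  sets (GMT) among DEG, and Venn-region overlaps between DEG lists.
- **Profile analysis** — classical (Torgerson) MDS of the
  1 − Pearson-correlation pseudo-distance between samples, hierarchical
  clustering of DEG on gene–gene correlation, marker-based purity QC
  (fold-depletion of astrocyte/oligodendrocyte/microglia/endothelial
  markers), and a one-tailed pooled t-test on spliced-isoform fractions
  (e.g. Xbp1s/Xbp1, an unfolded-protein-response readout).
- **Synthetic data** — a negative-binomial generator that emulates the
  study design (2 cell types × 2 conditions, n = 5–6 pools, asymmetric DEG
  fractions, 92-spike 2-fold dilution ladder with Poisson capture,
  spliced/unspliced pairs, trace contamination) and records ground truth
  for end-to-end validation.

The DE engine is organised as a model/results pair:
`DifferentialExpression(counts, design).fit()` returns a `DEResults` with
estimates, moderated statistics, q-values, DEG flags, the shrinkage
hyperparameters and a `summary()` table. The spike-in calibrations follow
the same pattern (`DetectionCurveModel`, `CopiesPerTpmModel`).

## Worked example

Generate a synthetic study and run the pipeline from the shell (the same
calls are available as library functions):

```bash
sortedseq simulate --seed 5 --n-genes 1000 --out demo
sortedseq de       --counts demo/counts.tsv --design demo/design.tsv --out demo/de
sortedseq permfdr  --counts demo/counts.tsv --design demo/design.tsv --n-perm 20 --seed 5 --out demo/perm
sortedseq calibrate --counts demo/counts.tsv --ercc demo/ercc.tsv --design demo/design.tsv --out demo/cal
```

which prints

```
Moderated differential expression
==============================================
genes tested:        1018
residual df:         17.0
prior df (d0):       11.5
prior variance s0^2: 0.9323

contrast             DEG   (q<0.05, |lfc|>1.0, CPM>20.0)
  AGRP.FD-AGRP.fed       44
  POMC.FD-POMC.fed        4
  AGRP.fed-POMC.fed      38

Permutation study (20 permutations, seed 5)
==================================================================
contrast                 observed  perm mean  perm sd   FDR %
AGRP.FD-AGRP.fed               44       0.05     0.22     0.1
POMC.FD-POMC.fed                4       0.10     0.45     2.5
AGRP.fed-POMC.fed              38       0.00     0.00     0.0

Detection curve (ML fit): x50 = 20.3 copies x kb [17.4, 23.7], slope = 3.19,
1932 spike observations on 92 levels
1 TPM corresponds to 0.21 +/- 0.07 copies per cell (21 samples, 0 excluded)
```

Reading the output: 44 genes pass the DEG criteria for AGRP neurons under
food deprivation versus only 4 for POMC neurons — the generator programs
this asymmetry (energy deficit perturbs the AGRP transcriptome far more),
and the fit recovers it. Label permutations almost always produce zero
DEG, so the empirical FDR of the observed lists is a fraction of a
percent. The spike ladder places the 50%-detection point near
20 copies × kb (the generator's true value is 22, the closed form
ln 2 / capture rate), and at this sequencing depth 1 TPM corresponds to
roughly 0.2 transcript copies per cell. The prior degrees of freedom
(d₀ ≈ 11.5) indicate how strongly per-gene variances are shrunk toward
the common prior s₀².

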