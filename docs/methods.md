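# Methods

This note documents the statistical procedures implemented in `scbench`,
the generative model behind its synthetic data, the defaults and why they
were chosen, and what the package's validation does and does not
demonstrate about real data.

## Read downsampling and library complexity

A sequencing library is represented at the molecule level: one record per
(cell barcode, UMI, gene) with the number of reads supporting it.
Subsampling `n` of the library's `T` total reads without replacement
induces a multivariate hypergeometric distribution over molecules: a
molecule carrying `r` reads keeps `k` of them with probability
`C(r,k)·C(T−r,n−k)/C(T,n)`, and survives (k ≥ 1) with probability
`1 − C(T−r,n)/C(T,n)`. `downsample_reads` draws directly from this law
(`numpy`'s multivariate hypergeometric sampler), so the surviving reads
sum to `n` exactly and no independence approximation is involved. The
test suite pins the law to exhaustive subset enumeration on small pools.

Saturation curves evaluate detected genes (≥1 surviving molecule) and
detected UMIs (surviving molecules) at stepped depths — by default ten
equal steps up to full depth, since fixed 5M/10M-read steps are only
meaningful at production scale; explicit grids or step sizes are
accepted. Each depth is an independent draw with a per-depth child seed;
a nested mode (each shallower depth drawn from the previous one) exists
for monotone-coupling checks. Curves are summarised by OLS of the
response on depth with the 95% CI of the slope from the t distribution
(n−2 df). Two libraries are declared significantly different when their
slope CIs are disjoint; closed intervals, so touching endpoints count as
overlap (conservative). Non-overlap of two independent 95% CIs is itself
conservative relative to a 0.05-level test — the null calibration run in
the acceptance suite observes well under 10% disjoint pairs.

Degenerate fits are reported, not hidden: a zero-variance predictor sets
a `degenerate` flag with undefined slope; a constant response (a fully
saturated curve) yields slope 0 with a zero-width CI and undefined r².

Per-cell complexity applies the same OLS machinery across cells (genes ~
reads, UMIs ~ reads). The accumulation curve averages, over 100
repetitions, the union of detected genes in `n` randomly chosen cells for
`n = 1, 3, …, 99` (configurable); at `n = #cells` the value is exact with
zero variance.

Depth equalization emulates aggregation-time subsampling: every library
whose mean reads per barcode exceeds the shallowest library's mean by
more than 1% is read-downsampled to match it. Mean reads per barcode —
not total reads — is the equalized quantity, matching how aggregation
tools document their normalization. Equalization is an explicit,
optional pipeline stage because the ordering between equalization and
barcode filtering is a design choice the user should control.

## QC, normalization, highly variable genes

Per-cell metrics: total UMIs, detected genes, and mitochondrial /
ribosomal percentages (100 × flagged counts / total). Cells with zero
counts get flagged undefined percentages rather than being silently
dropped. Filtering is threshold-based; the package defaults
(min_umi 500, min_gene 200, max MT% 20) are deliberate round numbers for
libraries of a few thousand UMIs per cell and are configuration, not
claims. Two named presets implement the two-pass colon scheme used for
tissue with fragile epithelium: a permissive first MT% pass
(mouse 75%, human 85%), then lineage-specific cutoffs on the survivors
(epithelial 60%; non-epithelial 50% mouse, 25% human). Pass-2 lineage
labels come from supplied annotations (ground-truth labels for synthetic
data); intermediate clustering/annotation is out of scope. The filter
reports a per-rule removal tally and is idempotent.

Normalization: `ln(1 + scale · x / cell_total)` with `scale = 10^4`;
zeros stay zero, raw counts are retained in a `counts` layer.

HVGs are ranked by vst-style standardized variance: a smooth trend of
log10 variance on log10 mean is fitted across genes (degree-2 polynomial;
a loess would be conventional but adds a dependency without changing the
desk-scale behaviour), counts are standardized by the trend-expected SD,
clipped at √N, and genes ranked by the variance of the clipped values,
ties broken by gene id. The protocol-overlap statistic is
|top-n(A) ∩ top-n(B)|/n.

## Pseudo-bulk correlation

A pseudo-bulk profile is the per-gene mean of log-normalized expression
over a cell set ("mean of the log" — the alternative log-of-mean reading
is a config switch). Protocols are compared by Pearson correlation over
genes expressed in at least one profile (genes zero in both would inflate
r²); r² and the t-test p-value are reported. The global comparison always
runs; per-cell-type comparisons require >100 cells overall and >20 per
condition, and the larger condition is subsampled without replacement to
the smaller's size. Whether per-population support should be the union or
intersection of expressed genes is not a settled convention; the union is
used and recorded.

## Composition

Cell-type proportions per protocol, the log2 proportion ratio (0.5
pseudo-count on zero counts), and a percentile bootstrap 95% CI from
resampling cells within each protocol. This is a descriptive summary
chosen deliberately over Bayesian compositional inference, which is out
of scope here; no "credible change" language is emitted, and the report
marks the substitution.

## Differential expression

Genes expressed in <10% of cells in both groups are excluded before
testing. Tested genes get a two-sided Wilcoxon rank-sum test on
log-normalized values — a distribution-free substitute for hurdle-model
fits, chosen because the contribution being validated is the filter rule,
not the test — and BH adjustment over tested genes. The fold change is
computed on the de-logged scale: `log2((mean(expm1(x))_A + ε)/(… B + ε))`
with `ε = 1/mean(group sizes)`. A gene is significant iff |log2FC| > 1,
adjusted p < 0.05, and it passes the presence rule. Label swap negates
every fold change and leaves p-values untouched (tested explicitly).

## Signature scoring

For each cell, genes are ranked by decreasing expression with average
ranks on ties; ranks beyond `r_max` and zero/absent genes take the
ceiling `r_max + 1`. With `U = Σ ranks − n_s(n_s+1)/2`, the score is
`clamp(1 − U/(n_s·r_max), 0, 1)`: 1 when the signature occupies the top
ranks, 0 when it is absent. The score depends only on within-cell ranks,
hence is exactly invariant to monotone transforms, and an everywhere-
absent signature has the closed form `(n_s−1)/(2·r_max)`. `r_max = 1500`
is the conventional default of rank-based scoring at transcriptome scale
and is configurable (it must be below the gene count).

Protocol comparison caps cells at 250 per cell type per protocol by
seeded subsampling, then applies a two-sided rank-sum test per cell type
and globally. The groups are unpaired, so the rank-sum (Mann–Whitney)
test is the default; a signed-rank option exists for explicitly paired
designs of equal size.

## Pre-ranked GSEA

The enrichment score is the signed extremum of the weighted KS running
sum (hit increments `|s|^p/Σ_hits|s|^p` with `p = 1`, miss decrements
`1/(N−n_hits)`). When the positive and negative extrema tie in magnitude
(beyond float noise) the negative one is reported, matching the
convention of the standard implementations. The null is gene-permutation
— random same-size sets, appropriate because the input is a pre-ranked
list with no sample labels — with the empirical p-value computed against
the same-sign half of the null: `p = (1 + #{same-sign |null| ≥ |es|}) /
(1 + #same-sign nulls)`. Dividing instead by all permutations would cap
null p-values near 0.5 and destroy uniformity under the null, which the
acceptance suite verifies by KS test. `NES = es / mean(|null| of matching
sign)`; BH across retained sets. Sets are filtered to 10–300 in-universe
genes before testing; significance additionally requires >5 set genes in
the ranked universe covering >15% of the set ("overlap" is read as
in-universe size; the leading-edge size is reported alongside but not
filtered on). The default ranking statistic from the DE stage is
`−log10(p)·sign(log2FC)`, ties broken by gene id.

## Synthetic data generator

The generator emulates, with known ground truth, exactly the features the
statistics above consume:

* **Gene abundance** — log-normal base rates across genes
  (log-sd 1.5, spanning several orders of magnitude as real transcriptomes
  do), perturbed per cell type by independent log-normal multipliers
  (log-sd 0.4).
* **Mitochondrial content** — the 13 mtDNA-like genes are rescaled to an
  expected 5% of transcripts in healthy cells, the typical magnitude in
  real libraries; without this, no realistic MT threshold could ever
  detect the planted artifacts.
* **Cells** — per-protocol composition vectors (table of cells per type
  per protocol); per-cell totals log-normal (median 5000 UMIs,
  log-sd 0.35, ~10x-like); molecule gene identities multinomial from the
  type's rate vector.
* **Stress** — a designated gene set (default 30 genes) has its rates
  multiplied by `stress_fold` in the stressed protocol only (default
  1.5, a subtle handling artifact; the validation suite also uses fold 4
  for single-gene DE recovery).
* **Amplification** — each molecule carries `1 + NB(mean−1, dispersion)`
  reads (default mean 4, dispersion 1), the standard shifted-NB stand-in
  for PCR duplication guaranteeing every molecule at least one read. UMIs
  are random fixed-length tokens, regenerated on collision within
  (barcode, gene).
* **Low-quality cells** — a fraction (default 5%) of barcodes is shrunk
  below the 5th percentile of normal cell sizes and has its MT fraction
  boosted 8-fold (≈40%), flagged in the truth labels so QC recovery is
  checkable.
* **Seeding** — one master seed; per-stage child seeds via fixed spawn
  keys, so stages re-run independently and identically.

A count-matrix shortcut (`simulate_counts`) draws the same multinomial
layer directly, skipping UMI strings and read amplification; it is
distribution-identical to collapsing the molecule-level output and is
used for purely count-level simulations.

Deliberate simplifications: no gene–gene correlation, no ambient RNA, no
doublets, no splicing, no sequencing errors, no UMI collisions across the
ceiling. Consequently, passing validation demonstrates calibration and
power of the statistics under a clean generative model — it does not
certify behaviour under ambient contamination, doublet structure, or
correlated expression programs, and the generator's parameters are
stand-ins, not estimates of any particular dataset.

## Problem sizes used in validation

The automated validation runs at desk scale, chosen so the full suite
completes in minutes while keeping every statistical claim meaningful:
libraries of 40–600 cells, 500–2000 genes, 500–5000 UMIs per cell;
50 library pairs for CI-overlap calibration; 20 seeds for pseudo-bulk
null r²; 10+10 seeds for DE recovery/error control; 100+200 seeds for
signature power/type-I; 200 random sets for GSEA null uniformity. The
criterion-level quantities (cell counts per group, planted fold sizes,
filter thresholds) follow the benchmark design itself.

## Known limitations

* The CI-overlap rule is conservative; it under-rejects relative to a
  direct two-sample slope test and is used because it is the benchmark's
  stated decision rule, not because it is optimal.
* The descriptive composition table does not model compositional
  dependence between cell types; CIs are per-type marginals.
* Rank-sum DE on log-normalized values ignores zero-inflation structure;
  with the |log2FC| and presence filters this matters little for the
  benchmark's verdicts, but single-gene p-values should not be
  over-interpreted.
* The vst trend is a global polynomial; with very few distinct gene means
  the degree is reduced automatically, and pathological mean–variance
  shapes may mis-rank borderline genes.
* GSEA uses plain permutation p-values (resolution 1/(#same-sign nulls));
  very small p-values require raising `n_perm`.
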