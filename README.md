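# scbench

Benchmarking toolkit for comparing single-cell RNA-seq libraries prepared
under different protocols — e.g. fresh enzymatic dissociation versus
reversible fixation, with or without cryopreservation.

When the same cell pool is processed two ways and sequenced, the questions
a core facility or method developer asks are always the same: did the
protocol cost library complexity? Did it distort the transcriptome, shift
cell-type composition, or induce stress artifacts? `scbench` answers each
of these with an explicit statistical procedure over molecule-level data:

* **Library complexity** — reads are subsampled *without replacement* from
  the per-molecule read pools (a multivariate hypergeometric draw), giving
  saturation curves of detected genes and UMIs versus sequenced reads.
  Each curve is summarised by an OLS fit; two protocols differ
  significantly when the 95% confidence intervals of their depth slopes do
  not overlap. Per-cell complexity regressions and cumulative
  gene-accumulation curves (mean union of detected genes over 100 random
  subsets of 1..100 cells) complete the picture.
* **QC structure** — per-cell library size, complexity, mitochondrial and
  ribosomal percentages; single-pass threshold filters or the two-pass
  colon scheme (permissive MT% cutoff, then lineage-specific cutoffs for
  epithelial vs non-epithelial cells); library-size log normalization
  (`ln(1 + 10^4 · x/total)`); vst-style highly variable genes and the
  top-N HVG overlap between protocols.
* **Transcriptome concordance** — pseudo-bulk profiles (per-gene mean of
  log-normalized expression) compared by Pearson correlation, globally and
  per cell type; populations enter only with >100 cells overall and >20
  per condition, the larger side is downsampled to the smaller, and a
  correlation is called strong when r² > 0.9 and p < 0.05.
* **Composition** — per-type proportions, log2 proportion ratios with
  bootstrap 95% CIs (a descriptive summary, not Bayesian compositional
  inference).
* **Differential expression** — per-gene two-sided Wilcoxon rank-sum on
  log-normalized values; significant genes require |log2FC| > 1,
  BH-adjusted p < 0.05, and expression in ≥10% of cells.
* **Stress burden** — rank-based per-cell signature scores
  `score = 1 − U/(n_s·r_max)` from the Mann–Whitney U statistic of the
  signature genes' within-cell expression ranks (ceiling rank `r_max+1`,
  default `r_max = 1500`), capped at 250 cells per cell type per protocol
  and compared between protocols by rank-sum test.
* **Pathways** — pre-ranked GSEA (weighted Kolmogorov–Smirnov running
  sum) on the signed `−log10(p)·sign(log2FC)` DE statistic, with a
  gene-permutation null, set sizes restricted to 10–300, and significance
  requiring FDR < 0.05, >5 set genes in the ranked universe covering >15%
  of the set.

A molecule-level synthetic data generator (`scbench.simdata`) provides
paired-protocol libraries with known ground truth — per-type expression
profiles, protocol composition vectors, planted stress fold-changes, PCR
read amplification, and planted low-quality high-MT cells — so every
statistic above can be validated for calibration and power.

## Worked example

```python
import numpy as np, pandas as pd
from scbench import ProtocolBenchmark, BenchConfig, SyntheticSpec

spec = SyntheticSpec(
    n_genes=600, seed=5, n_cell_types=2,
    cells_per_type_per_protocol=pd.DataFrame(
        {"A": [60, 60], "B": [60, 60]}, index=["type0", "type1"]),
    library_size_log_mean=float(np.log(1000)),
    stress_fold=1.5, lowq_fraction=0.05)
cfg = BenchConfig(seed=7, n_hvg=200, gsea_n_perm=200, n_boot=200,
                  accumulation_grid=(1, 11, 21, 31, 41, 51),
                  accumulation_reps=20, signature_r_max=300)

results = ProtocolBenchmark.from_simulation(spec, config=cfg).fit()
print(results.summary())
```

prints (protocol A is the stressed preparation, B the protected one):

```
Protocol benchmark summary
==========================
lib_A: genes~reads slope 1.633e-05 (95% CI 7.055e-06 .. 2.561e-05)
lib_B: genes~reads slope 1.747e-05 (95% CI 2.912e-06 .. 3.203e-05)
saturation slopes (genes): protocols do not differ (CIs overlap)
saturation slopes (umis): protocols do not differ (CIs overlap)
QC: kept 221/240 cells, 596 genes
HVG overlap (top 200): 0.49
correlation [global]: r^2 = 0.9834, p = 0.00e+00, strong = True
correlation [type0]: r^2 = 0.9716, p = 0.00e+00, strong = True
correlation [type1]: r^2 = 0.9726, p = 0.00e+00, strong = True
DE: 0 significant of 550 tested genes
signature planted_stress: global p = 2.77e-20, median diff = 0.0553
GSEA: 1 significant of 1 retained sets (0 excluded by size)
note [composition]: descriptive proportions with bootstrap CIs in place of Bayesian compositional inference
note [differential_expression]: Wilcoxon rank-sum test in place of a hurdle-model fit
```

Reading it: the two libraries gain genes with depth at statistically
indistinguishable rates (overlapping slope CIs — no complexity loss), QC
removed the planted low-quality cells, the transcriptomes are strongly
concordant (r² ≳ 0.97 everywhere), and the modest 1.5-fold planted stress
effect is too small for single-gene DE at |log2FC| > 1 yet clearly
visible to the signature score (stressed protocol scores higher,
p ≈ 3e-20) and to GSEA on the planted stress set — exactly the
sensitivity ordering the method is designed to expose.

The same pipeline runs from the shell:

```bash
scbench simulate --seed 5 --out sim/
scbench saturation --molecules sim/molecules_A.tsv --molecules sim/molecules_B.tsv --out sat/
scbench run --config bench.yaml --out out/
```

`ProtocolBenchmark.from_config` / `scbench run` accept a YAML file naming
either molecule tables + labels or an embedded simulation spec, plus any
`BenchConfig` parameter under `params:`.

## Layout

```
src/scbench/
  simdata.py     synthetic paired-protocol generator (ground truth)
  molio.py       molecule-table / Matrix Market / GMT I/O, depth equalization
  saturation.py  read downsampling, saturation curves, CI-overlap comparison
  qcnorm.py      QC metrics, filters, normalization, HVGs
  compstats.py   pseudo-bulk correlation, composition, DE, biotype breakdown
  sigscore.py    rank-based signature scoring and protocol comparison
  gsea.py        pre-ranked GSEA with permutation null
  pipeline.py    ProtocolBenchmark / BenchmarkResults orchestration
  cli.py         `scbench` command-line interface
```

See `docs/methods.md` for the statistical methods, model assumptions,
parameter defaults, and known limitations.
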