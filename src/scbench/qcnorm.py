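"""Quality control, filtering, normalization and highly variable genes.

Implements per-cell QC metrics (library size, complexity, mitochondrial
and ribosomal percentages), single-pass threshold filtering, the two-pass
mitochondrial scheme used for colon tissue (a permissive first cutoff,
then lineage-specific cutoffs for epithelial vs non-epithelial cells),
gene filtering, library-size log normalization, and vst-style highly
variable gene selection with top-N overlap between protocols.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp


@dataclass
class TwoPassMT:
    """Two-pass mitochondrial filter: permissive pass then lineage cutoffs."""

    pass1_max_pct_mt: float
    lineage_max_pct_mt: dict[str, float]


@dataclass
class QCThresholds:
    min_umi: int | None = None
    min_gene: int | None = None
    max_umi: int | None = None
    max_gene: int | None = None
    max_pct_mt: float | None = None
    two_pass: TwoPassMT | None = None

    def __post_init__(self) -> None:
        for lo, hi in ((self.min_umi, self.max_umi), (self.min_gene, self.max_gene)):
            if lo is not None and hi is not None and lo > hi:
                raise ValueError("min threshold exceeds max threshold")


# Named presets. The colon two-pass mitochondrial cutoffs are tissue-specific
# published values; the generic single-pass numbers are package defaults.
PRESETS: dict[str, QCThresholds] = {
    "default": QCThresholds(min_umi=500, min_gene=200, max_pct_mt=20.0),
    "mouse_colon": QCThresholds(
        min_umi=500, min_gene=200,
        two_pass=TwoPassMT(75.0, {"epithelial": 60.0, "non_epithelial": 50.0}),
    ),
    "human_colon": QCThresholds(
        min_umi=500, min_gene=200,
        two_pass=TwoPassMT(85.0, {"epithelial": 60.0, "non_epithelial": 25.0}),
    ),
}


def compute_qc(matrix: ad.AnnData) -> pd.DataFrame:
    """Per-barcode QC metrics: n_umi, n_gene, pct_mt, pct_ribo.

    Percentages are 100 x (counts on flagged genes) / (total counts); cells
    with zero counts get NaN percentages and a ``pct_undefined`` flag (they
    are reported, not dropped).
    """
    for col in ("is_mito", "is_ribo"):
        if col not in matrix.var.columns:
            raise ValueError(f"gene_meta column {col!r} required")
    X = sp.csr_matrix(matrix.X)
    total = np.asarray(X.sum(axis=1)).ravel()
    n_gene = np.asarray((X > 0).sum(axis=1)).ravel()
    mt = np.asarray(X[:, matrix.var["is_mito"].to_numpy()].sum(axis=1)).ravel()
    ribo = np.asarray(X[:, matrix.var["is_ribo"].to_numpy()].sum(axis=1)).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        pct_mt = np.where(total > 0, 100.0 * mt / np.maximum(total, 1), np.nan)
        pct_ribo = np.where(total > 0, 100.0 * ribo / np.maximum(total, 1), np.nan)
    return pd.DataFrame({
        "n_umi": total.astype(np.int64),
        "n_gene": n_gene.astype(np.int64),
        "pct_mt": pct_mt,
        "pct_ribo": pct_ribo,
        "pct_undefined": total == 0,
    }, index=matrix.obs_names)


def filter_cells(
    matrix: ad.AnnData,
    metrics: pd.DataFrame,
    thresholds: QCThresholds,
    lineage_labels: pd.Series | None = None,
) -> tuple[pd.Index, dict[str, int]]:
    """Apply QC thresholds; returns (kept barcodes, per-rule removal tally).

    In two-pass mode, pass 1 removes cells above the permissive
    mitochondrial cutoff; pass 2 applies the lineage-specific cutoffs to
    the survivors (every survivor must carry a lineage label).
    """
    metrics = metrics.loc[matrix.obs_names]
    keep = pd.Series(True, index=metrics.index)
    tally: dict[str, int] = {}

    def apply_rule(name: str, bad: pd.Series) -> None:
        removed = bad & keep
        tally[name] = int(removed.sum())
        keep[removed] = False

    if thresholds.min_umi is not None:
        apply_rule("min_umi", metrics["n_umi"] < thresholds.min_umi)
    if thresholds.max_umi is not None:
        apply_rule("max_umi", metrics["n_umi"] > thresholds.max_umi)
    if thresholds.min_gene is not None:
        apply_rule("min_gene", metrics["n_gene"] < thresholds.min_gene)
    if thresholds.max_gene is not None:
        apply_rule("max_gene", metrics["n_gene"] > thresholds.max_gene)
    if thresholds.two_pass is not None:
        tp = thresholds.two_pass
        apply_rule("mt_pass1", metrics["pct_mt"] > tp.pass1_max_pct_mt)
        if lineage_labels is None:
            raise ValueError("two-pass filtering requires lineage labels")
        survivors = keep[keep].index
        missing = survivors.difference(lineage_labels.index)
        if len(missing):
            raise ValueError(f"lineage label missing for {missing[0]!r}")
        for lineage, cutoff in tp.lineage_max_pct_mt.items():
            in_lineage = pd.Series(False, index=metrics.index)
            lab = lineage_labels.reindex(metrics.index)
            in_lineage[(lab == lineage).fillna(False)] = True
            apply_rule(f"mt_pass2_{lineage}", in_lineage & (metrics["pct_mt"] > cutoff))
        unknown = keep[keep].index.difference(
            lineage_labels[lineage_labels.isin(tp.lineage_max_pct_mt)].index)
        if len(unknown):
            bad_label = lineage_labels.get(unknown[0])
            raise ValueError(f"lineage {bad_label!r} has no pass-2 cutoff")
    elif thresholds.max_pct_mt is not None:
        apply_rule("max_pct_mt", metrics["pct_mt"] > thresholds.max_pct_mt)
    return keep[keep].index, tally


def filter_genes(matrix: ad.AnnData, min_cells: int) -> ad.AnnData:
    """Drop genes detected (count > 0) in fewer than *min_cells* cells."""
    if min_cells < 0:
        raise ValueError("min_cells must be >= 0")
    X = sp.csr_matrix(matrix.X)
    n_cells = np.asarray((X > 0).sum(axis=0)).ravel()
    return matrix[:, n_cells >= min_cells].copy()


def normalize_log(matrix: ad.AnnData, scale: float = 10_000.0) -> ad.AnnData:
    """Library-size normalization followed by log transform.

    Each entry becomes ``ln(1 + scale * count / cell_total)``; zeros stay
    zero, so sparsity is preserved.  Raw counts are kept in
    ``layers["counts"]``.
    """
    X = sp.csr_matrix(matrix.X, dtype=np.float64)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if (totals == 0).any():
        raise ValueError("all-zero cell present; filter cells first")
    out = matrix.copy()
    norm = X.multiply(scale / totals[:, None]).tocsr()
    norm.data = np.log1p(norm.data)
    out.layers["counts"] = sp.csr_matrix(matrix.X).copy()
    out.X = norm
    return out


def select_hvgs(matrix: ad.AnnData, n_top: int = 2000) -> pd.DataFrame:
    """Rank genes by vst-style standardized variance on raw counts.

    A smooth mean-variance trend (degree-2 polynomial in log10 space) is
    fitted across genes; counts are standardized by the trend-expected
    standard deviation, clipped at sqrt(n_cells), and genes are ranked by
    the variance of the clipped values.  Ties break by gene id.  Raw counts
    are taken from ``layers["counts"]`` when present, else from ``X``.
    """
    X = matrix.layers["counts"] if "counts" in matrix.layers else matrix.X
    X = np.asarray(sp.csr_matrix(X).todense(), dtype=np.float64)
    n_cells, n_genes = X.shape
    if n_genes < n_top:
        raise ValueError(f"need at least n_top={n_top} genes, have {n_genes}")
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1)
    if np.all(var == 0):
        raise ValueError("no variable genes")
    fit_mask = (mean > 0) & (var > 0)
    log_mean = np.log10(mean[fit_mask])
    deg = min(2, max(0, len(np.unique(log_mean)) - 1))
    coeffs = np.polyfit(log_mean, np.log10(var[fit_mask]), deg=deg)
    exp_var = np.zeros(n_genes)
    exp_var[fit_mask] = 10 ** np.polyval(coeffs, log_mean)
    std_var = np.zeros(n_genes)
    clip = np.sqrt(n_cells)
    ok = exp_var > 0
    z = (X[:, ok] - mean[ok]) / np.sqrt(exp_var[ok])
    np.clip(z, -clip, clip, out=z)
    std_var[ok] = z.var(axis=0, ddof=1)
    ranking = pd.DataFrame({
        "gene_id": matrix.var_names,
        "mean": mean,
        "variance": var,
        "standardized_variance": std_var,
    }).sort_values(["standardized_variance", "gene_id"], ascending=[False, True],
                   kind="mergesort").reset_index(drop=True)
    ranking["rank"] = np.arange(1, n_genes + 1)
    return ranking


def hvg_overlap(list_a: pd.DataFrame | list[str], list_b: pd.DataFrame | list[str],
                n: int = 2000) -> float:
    """Fraction of the top-*n* highly variable genes shared by two rankings."""
    def top(obj) -> set[str]:
        genes = list(obj["gene_id"]) if isinstance(obj, pd.DataFrame) else list(obj)
        if len(genes) < n:
            raise ValueError(f"ranking shorter than n={n}")
        return set(genes[:n])
    return len(top(list_a) & top(list_b)) / n
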