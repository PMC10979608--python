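"""Protocol-comparison statistics.

Pseudo-bulk Pearson correlation (with the population-size and
cell-downsampling rules), a descriptive cell-type composition comparison
with bootstrap confidence intervals, Wilcoxon rank-sum differential
expression with the three-way significance filter (|log2FC| > 1,
BH-adjusted p < 0.05, expressed in >= 10% of cells), and gene-biotype
breakdowns of shared versus protocol-unique genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class CorrelationResult:
    scope: str  # "global" or a cell-type name
    r_squared: float
    p_value: float
    n_cells_a: int
    n_cells_b: int
    passed_strong: bool
    skipped: bool = False
    skip_reason: str = ""

    @classmethod
    def skip(cls, scope: str, reason: str, n_a: int = 0, n_b: int = 0) -> "CorrelationResult":
        return cls(scope, np.nan, np.nan, n_a, n_b, False, skipped=True, skip_reason=reason)


def _dense(matrix: ad.AnnData) -> np.ndarray:
    return np.asarray(sp.csr_matrix(matrix.X).todense(), dtype=np.float64)


def pseudobulk_profile(norm_matrix: ad.AnnData, cell_subset: pd.Index | list[str]) -> pd.Series:
    """Per-gene mean of log-normalized expression over a set of cells."""
    cell_subset = pd.Index(cell_subset)
    if len(cell_subset) == 0:
        raise ValueError("empty cell subset")
    sub = norm_matrix[cell_subset]
    prof = np.asarray(sp.csr_matrix(sub.X).mean(axis=0)).ravel()
    return pd.Series(prof, index=norm_matrix.var_names, name="pseudobulk")


def _correlate(profile_a: pd.Series, profile_b: pd.Series) -> tuple[float, float]:
    """Pearson r^2 and p over genes expressed in either profile."""
    expressed = (profile_a > 0) | (profile_b > 0)
    a, b = profile_a[expressed], profile_b[expressed]
    if len(a) < 3:
        return np.nan, np.nan
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan, np.nan
    r, p = stats.pearsonr(a, b)
    return float(r * r), float(p)


def pseudobulk_correlation(
    norm_matrix: ad.AnnData,
    protocol_labels: pd.Series,
    cell_type_labels: pd.Series | None = None,
    min_total: int = 100,
    min_per_cond: int = 20,
    downsample: bool = True,
    seed: int = 0,
) -> list[CorrelationResult]:
    """Pseudo-bulk correlation between two protocols, globally and per type.

    Per-type results are computed only for populations with more than
    *min_total* cells overall and more than *min_per_cond* cells in each
    protocol; the larger protocol is subsampled without replacement to the
    smaller's size first.  ``passed_strong`` flags r^2 > 0.9 and p < 0.05.
    """
    protocol_labels = protocol_labels.reindex(norm_matrix.obs_names)
    protos = sorted(protocol_labels.dropna().unique())
    if len(protos) != 2:
        raise ValueError(f"exactly two protocols required, found {protos}")
    rng = np.random.default_rng(seed)

    def one(scope: str, cells_a: pd.Index, cells_b: pd.Index) -> CorrelationResult:
        n_a, n_b = len(cells_a), len(cells_b)
        if downsample and n_a != n_b:
            m = min(n_a, n_b)
            if n_a > m:
                cells_a = pd.Index(rng.choice(cells_a, size=m, replace=False))
            else:
                cells_b = pd.Index(rng.choice(cells_b, size=m, replace=False))
        r2, p = _correlate(pseudobulk_profile(norm_matrix, cells_a),
                           pseudobulk_profile(norm_matrix, cells_b))
        strong = bool(r2 > 0.9 and p < 0.05) if np.isfinite(r2) else False
        return CorrelationResult(scope, r2, p, len(cells_a), len(cells_b), strong)

    idx_a = protocol_labels[protocol_labels == protos[0]].index
    idx_b = protocol_labels[protocol_labels == protos[1]].index
    results = [one("global", idx_a, idx_b)]
    if cell_type_labels is not None:
        cell_type_labels = cell_type_labels.reindex(norm_matrix.obs_names)
        for ct in sorted(cell_type_labels.dropna().unique()):
            cells = cell_type_labels[cell_type_labels == ct].index
            ct_a, ct_b = cells.intersection(idx_a), cells.intersection(idx_b)
            if len(cells) <= min_total:
                results.append(CorrelationResult.skip(ct, "min_total", len(ct_a), len(ct_b)))
            elif min(len(ct_a), len(ct_b)) <= min_per_cond:
                results.append(CorrelationResult.skip(ct, "min_per_cond", len(ct_a), len(ct_b)))
            else:
                results.append(one(ct, ct_a, ct_b))
    return results


def composition_compare(
    cell_type_labels: pd.Series,
    protocol_labels: pd.Series,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Descriptive cell-type composition comparison between two protocols.

    Reports per-type proportions, the log2 proportion ratio (A over B, with
    a 0.5 pseudo-count on zero cell counts), and a percentile bootstrap 95%
    CI of the ratio obtained by resampling cells within each protocol.
    This is a descriptive summary, not a compositional inference model.
    """
    protos = sorted(protocol_labels.dropna().unique())
    if len(protos) != 2:
        raise ValueError(f"exactly two protocols required, found {protos}")
    a, b = protos
    types = sorted(cell_type_labels.dropna().unique())
    la = cell_type_labels[protocol_labels == a].to_numpy()
    lb = cell_type_labels[protocol_labels == b].to_numpy()

    def log2_ratios(va: np.ndarray, vb: np.ndarray) -> np.ndarray:
        ca = np.array([(va == t).sum() for t in types], dtype=float)
        cb = np.array([(vb == t).sum() for t in types], dtype=float)
        ca_adj = np.where(ca == 0, 0.5, ca)
        cb_adj = np.where(cb == 0, 0.5, cb)
        return np.log2((ca_adj / ca_adj.sum()) / (cb_adj / cb_adj.sum()))

    obs_ratio = log2_ratios(la, lb)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, len(types)))
    for i in range(n_boot):
        boots[i] = log2_ratios(rng.choice(la, size=len(la), replace=True),
                               rng.choice(lb, size=len(lb), replace=True))
    lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
    prop_a = np.array([(la == t).mean() for t in types])
    prop_b = np.array([(lb == t).mean() for t in types])
    return pd.DataFrame({
        f"prop_{a}": prop_a,
        f"prop_{b}": prop_b,
        "log2_ratio": obs_ratio,
        "ci_low": lo,
        "ci_high": hi,
        "ci_excludes_zero": (lo > 0) | (hi < 0),
    }, index=pd.Index(types, name="cell_type"))


def differential_expression(
    norm_matrix: ad.AnnData,
    protocol_labels: pd.Series,
    min_pct: float = 0.10,
    logfc_min: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum DE between two protocols.

    Genes expressed in fewer than *min_pct* of cells in both groups are
    excluded before testing.  log2FC compares group means on the
    de-logged normalized scale (``expm1``), with a small pseudo-count
    ``eps = 1 / mean(group sizes)``.  Significance requires
    |log2FC| > *logfc_min*, BH-adjusted p < *alpha*, and the presence rule.
    """
    protocol_labels = protocol_labels.reindex(norm_matrix.obs_names)
    protos = sorted(protocol_labels.dropna().unique())
    if len(protos) != 2:
        raise ValueError(f"exactly two protocols required, found {protos}")
    mask_a = (protocol_labels == protos[0]).to_numpy()
    mask_b = (protocol_labels == protos[1]).to_numpy()
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    if min(n_a, n_b) < 3:
        raise ValueError("each group needs at least 3 cells")
    X = _dense(norm_matrix)
    Xa, Xb = X[mask_a], X[mask_b]
    pct_a = (Xa > 0).mean(axis=0)
    pct_b = (Xb > 0).mean(axis=0)
    tested = np.maximum(pct_a, pct_b) >= min_pct
    eps = 1.0 / ((n_a + n_b) / 2.0)
    mean_a = np.expm1(Xa).mean(axis=0)
    mean_b = np.expm1(Xb).mean(axis=0)
    log2fc = np.log2((mean_a + eps) / (mean_b + eps))
    p = np.full(X.shape[1], np.nan)
    if tested.any():
        res = stats.mannwhitneyu(Xa[:, tested], Xb[:, tested], axis=0,
                                 alternative="two-sided")
        p[tested] = res.pvalue
    p_adj = np.full_like(p, np.nan)
    if tested.any():
        p_adj[tested] = multipletests(p[tested], method="fdr_bh")[1]
    significant = tested & (np.abs(log2fc) > logfc_min) & (p_adj < alpha)
    return pd.DataFrame({
        "log2fc": log2fc,
        "pct_a": pct_a,
        "pct_b": pct_b,
        "tested": tested,
        "p_value": p,
        "p_adj": p_adj,
        "significant": significant,
    }, index=pd.Index(norm_matrix.var_names, name="gene_id"))


def gene_category_breakdown(
    genes_a: set[str] | list[str],
    genes_b: set[str] | list[str],
    biotype_map: pd.Series | dict[str, str],
) -> dict[str, pd.Series]:
    """Biotype fractions of shared and protocol-unique detected genes.

    Returns ``{"shared": ..., "unique_a": ..., "unique_b": ...}``, each a
    biotype -> fraction Series summing to 1 (empty sets give empty Series).
    Genes missing from the map count as "unannotated".
    """
    bmap = pd.Series(biotype_map) if isinstance(biotype_map, dict) else biotype_map
    sa, sb = set(genes_a), set(genes_b)
    groups = {"shared": sa & sb, "unique_a": sa - sb, "unique_b": sb - sa}
    out = {}
    for name, genes in groups.items():
        if not genes:
            out[name] = pd.Series(dtype=float)
            continue
        biotypes = bmap.reindex(sorted(genes)).fillna("unannotated")
        out[name] = biotypes.value_counts(normalize=True).sort_index()
    return out
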