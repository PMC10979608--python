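"""Pre-ranked gene-set enrichment analysis.

The enrichment score (ES) is the signed extremum of the classic weighted
Kolmogorov-Smirnov running sum over the ranked gene list: walking down the
list, hitting a set gene increments the sum by |stat|^p / sum_hits |stat|^p
and missing decrements by 1 / (N - n_hits).  Significance comes from a
gene-permutation null (random same-size sets), with the empirical p-value
and a normalized ES (observed ES over the mean |null ES| of matching
sign), BH adjustment across sets, and the reporting-level filters: a set
is called significant only when the adjusted p < 0.05, more than 5 of its
genes are present in the ranked universe, and those account for more than
15% of the set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests


def _prepare_ranking(ranked: pd.Series) -> pd.Series:
    """Sort decreasing by statistic, ties broken by gene id; genes unique."""
    if ranked.index.has_duplicates:
        raise ValueError("ranked gene list contains duplicate genes")
    order = pd.DataFrame({"stat": ranked, "gene": ranked.index})
    order = order.sort_values(["stat", "gene"], ascending=[False, True], kind="mergesort")
    return pd.Series(order["stat"].to_numpy(), index=order["gene"].to_numpy())


def _es_from_positions(positions: np.ndarray, weights: np.ndarray, n_genes: int) -> float:
    """ES from 0-based hit positions and per-hit weights (need not be normalized).

    The running sum is piecewise linear between hits, so its extrema occur
    just before or at each hit; both candidates are evaluated in O(k).
    """
    k = len(positions)
    if k == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if k == n_genes:
        return 1.0  # degenerate: no misses, the sum climbs to exactly 1
    order = np.argsort(positions)
    pos = positions[order].astype(np.int64)
    w = weights[order].astype(np.float64)
    w_sum = w.sum()
    if w_sum <= 0:
        w = np.full(k, 1.0 / k)
    else:
        w = w / w_sum
    cum_hit = np.cumsum(w)
    miss_step = 1.0 / (n_genes - k)
    j = np.arange(k)
    at_hit = cum_hit - (pos + 1 - (j + 1)) * miss_step  # after j-th hit
    before_hit = np.concatenate(([0.0], cum_hit[:-1])) - (pos - j) * miss_step
    max_run = max(float(at_hit.max()), 0.0)
    min_run = min(float(before_hit.min()), 0.0)
    # positive extremum wins only when larger in magnitude beyond float noise
    return max_run if max_run + min_run > 1e-12 else min_run


def enrichment_score(
    ranked: pd.Series,
    gene_set: list[str] | set[str],
    p_weight: float = 1.0,
) -> float:
    """Weighted KS enrichment score of *gene_set* in a pre-ranked list.

    *ranked* maps gene id -> ranking statistic; it is sorted by decreasing
    statistic (ties broken by gene id) before scoring.
    """
    ranked = _prepare_ranking(ranked)
    genes = ranked.index.to_numpy()
    in_set = np.isin(genes, np.array(sorted(set(gene_set))))
    positions = np.nonzero(in_set)[0]
    if len(positions) == 0:
        raise ValueError("gene set does not intersect the ranked list")
    weights = np.abs(ranked.to_numpy()[positions]) ** p_weight
    return _es_from_positions(positions, weights, len(genes))


@dataclass
class GseaResult:
    table: pd.DataFrame  # per-set results
    excluded: pd.DataFrame  # sets dropped by the size filter, with reasons
    n_perm: int


def preranked_gsea(
    ranked: pd.Series,
    gene_sets: dict[str, list[str]],
    min_size: int = 10,
    max_size: int = 300,
    n_perm: int = 1000,
    p_weight: float = 1.0,
    seed: int = 0,
) -> GseaResult:
    """Pre-ranked GSEA over a collection of gene sets.

    Sets are filtered by in-universe size to [*min_size*, *max_size*].  The
    null distribution per retained set is the ES of *n_perm* uniformly
    random same-size gene sets; the empirical p-value compares |es| against
    the same-sign half of the null, ``p = (1 + #{same-sign |null| >= |es|})
    / (1 + #same-sign nulls)``, so null p-values are uniform on (0, 1];
    ``nes = es / mean(|null| of matching sign)``.
    """
    ranked = _prepare_ranking(ranked)
    genes = ranked.index.to_numpy()
    stats_abs = np.abs(ranked.to_numpy()) ** p_weight
    n_genes = len(genes)
    if n_genes < max_size:
        raise ValueError(f"ranked list ({n_genes}) shorter than max_size ({max_size})")
    gene_pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    rows, excluded = [], []
    for name in sorted(gene_sets):
        members = sorted(set(gene_sets[name]))
        positions = np.array([gene_pos[g] for g in members if g in gene_pos], dtype=np.int64)
        n_overlap = len(positions)
        if not min_size <= n_overlap <= max_size:
            excluded.append((name, len(members), n_overlap, "size"))
            continue
        es = _es_from_positions(positions, stats_abs[positions], n_genes)
        null = np.empty(n_perm)
        for i in range(n_perm):
            perm_pos = rng.choice(n_genes, size=n_overlap, replace=False)
            null[i] = _es_from_positions(perm_pos, stats_abs[perm_pos], n_genes)
        same_sign = null >= 0 if es >= 0 else null < 0
        n_same = int(same_sign.sum())
        p = (1.0 + np.sum(same_sign & (np.abs(null) >= abs(es)))) / (1.0 + n_same)
        denom = np.abs(null[same_sign]).mean() if same_sign.any() else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        overlap_fraction = n_overlap / len(members)
        # leading edge: set genes at or before the ES extremum
        le = _leading_edge_size(positions, stats_abs[positions], n_genes, es)
        rows.append((name, es, nes, p, len(members), n_overlap, overlap_fraction, le))
    table = pd.DataFrame(rows, columns=[
        "set_name", "es", "nes", "p_value", "set_size", "n_overlap",
        "overlap_fraction", "leading_edge_size",
    ]).set_index("set_name")
    if len(table):
        table["p_adj"] = multipletests(table["p_value"], method="fdr_bh")[1]
        table["significant"] = (
            (table["p_adj"] < 0.05) & (table["n_overlap"] > 5) & (table["overlap_fraction"] > 0.15)
        )
    else:
        table["p_adj"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
    excluded_df = pd.DataFrame(excluded, columns=["set_name", "set_size", "n_overlap", "reason"])
    return GseaResult(table=table, excluded=excluded_df, n_perm=n_perm)


def _leading_edge_size(positions: np.ndarray, weights: np.ndarray, n_genes: int, es: float) -> int:
    """Number of set genes at or before the running-sum extremum."""
    order = np.argsort(positions)
    pos = positions[order]
    w = weights[order].astype(float)
    w = w / w.sum() if w.sum() > 0 else np.full(len(w), 1.0 / len(w))
    k = len(pos)
    if k == n_genes:
        return k
    cum_hit = np.cumsum(w)
    miss_step = 1.0 / (n_genes - k)
    j = np.arange(k)
    at_hit = cum_hit - (pos + 1 - (j + 1)) * miss_step
    if es >= 0:
        return int(np.argmax(at_hit) + 1)
    before_hit = np.concatenate(([0.0], cum_hit[:-1])) - (pos - j) * miss_step
    return int(np.argmin(before_hit))


def rank_from_de(de_table: pd.DataFrame) -> pd.Series:
    """Ranking statistic from a DE table: signed -log10(p) x sign(log2FC).

    Untested genes are dropped; zero p-values are floored to the smallest
    positive double.  Ties in the statistic break by gene id downstream.
    """
    tested = de_table[de_table["tested"]] if "tested" in de_table.columns else de_table
    p = np.clip(tested["p_value"].to_numpy(dtype=float), np.finfo(float).tiny, 1.0)
    stat = -np.log10(p) * np.sign(tested["log2fc"].to_numpy())
    return pd.Series(stat, index=tested.index, name="rank_stat")
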