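"""Rank-based per-cell gene-signature scoring and protocol comparison.

The score is the Mann-Whitney U statistic of the signature genes'
within-cell expression ranks, rescaled to [0, 1]: for a cell, genes are
ranked by decreasing expression (average ranks on ties); ranks beyond
``r_max`` and unexpressed or absent genes are set to the ceiling
``r_max + 1``; then

    U = sum(ranks of signature genes) - n_s (n_s + 1) / 2
    score = clamp(1 - U / (n_s * r_max), 0, 1)

so a cell whose top-ranked genes are exactly the signature scores 1.  The
score depends only on within-cell ranks and is invariant to any monotone
transform of the expression values.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats


@dataclass
class SignatureScores:
    signature_name: str
    scores: pd.Series  # per-cell, in [0, 1]
    n_signature_genes: int
    r_max: int


def score_signature(
    norm_matrix: ad.AnnData,
    signature: list[str],
    r_max: int = 1500,
    signature_name: str = "signature",
) -> SignatureScores:
    """U-statistic signature score per cell.

    Signature genes absent from the matrix contribute the ceiling rank
    ``r_max + 1`` (a fully absent signature is an error).
    """
    signature = list(dict.fromkeys(signature))
    if not signature:
        raise ValueError("empty signature")
    n_genes = norm_matrix.n_vars
    if r_max >= n_genes:
        raise ValueError(f"r_max={r_max} must be smaller than gene count {n_genes}")
    present = [g for g in signature if g in norm_matrix.var_names]
    if not present:
        raise ValueError("no signature gene present in the matrix")
    n_s = len(signature)
    ceiling = r_max + 1
    col_of = {g: i for i, g in enumerate(norm_matrix.var_names)}
    sig_cols = np.array([col_of[g] for g in present])

    X = sp.csr_matrix(norm_matrix.X)
    scores = np.empty(X.shape[0])
    n_absent = n_s - len(present)
    for i in range(X.shape[0]):
        start, end = X.indptr[i], X.indptr[i + 1]
        cols = X.indices[start:end]
        vals = X.data[start:end]
        pos = vals > 0
        cols, vals = cols[pos], vals[pos]
        ranks = stats.rankdata(-vals)  # decreasing expression
        ranks[ranks > r_max] = ceiling
        rank_sum = float(n_absent) * ceiling
        hit = np.isin(cols, sig_cols)
        rank_sum += ranks[hit].sum()
        rank_sum += ceiling * (len(sig_cols) - int(hit.sum()))  # zero-expression signature genes
        u = rank_sum - n_s * (n_s + 1) / 2.0
        scores[i] = min(max(1.0 - u / (n_s * r_max), 0.0), 1.0)
    return SignatureScores(signature_name, pd.Series(scores, index=norm_matrix.obs_names),
                           n_s, r_max)


def compare_scores(
    scores: SignatureScores,
    protocol_labels: pd.Series,
    cell_type_labels: pd.Series | None = None,
    max_cells_per_type: int = 250,
    seed: int = 0,
    paired: bool = False,
) -> pd.DataFrame:
    """Wilcoxon comparison of signature scores between two protocols.

    Cells are capped at *max_cells_per_type* per (cell type, protocol) by
    seeded subsampling; the test runs within each cell type and globally
    (on the pooled capped cells).  Unpaired protocol groups are compared
    with the two-sided rank-sum (Mann-Whitney) test; *paired* switches to
    the signed-rank test for explicitly paired designs of equal size.
    Strata missing a protocol are reported as skipped.
    """
    s = scores.scores
    protocol_labels = protocol_labels.reindex(s.index)
    protos = sorted(protocol_labels.dropna().unique())
    if len(protos) != 2:
        raise ValueError(f"exactly two protocols required, found {protos}")
    a, b = protos
    if cell_type_labels is None:
        cell_type_labels = pd.Series("all", index=s.index)
    cell_type_labels = cell_type_labels.reindex(s.index)
    rng = np.random.default_rng(seed)

    capped: dict[tuple[str, str], pd.Index] = {}
    for ct in sorted(cell_type_labels.dropna().unique()):
        for proto in protos:
            idx = s.index[(cell_type_labels == ct) & (protocol_labels == proto)]
            if len(idx) > max_cells_per_type:
                idx = pd.Index(rng.choice(idx, size=max_cells_per_type, replace=False))
            capped[(ct, proto)] = idx

    rows = []

    def test_stratum(name: str, idx_a: pd.Index, idx_b: pd.Index) -> None:
        if len(idx_a) == 0 or len(idx_b) == 0:
            rows.append((name, np.nan, np.nan, len(idx_a), len(idx_b), True,
                         "protocol absent from stratum"))
            return
        va, vb = s[idx_a].to_numpy(), s[idx_b].to_numpy()
        if paired:
            if len(va) != len(vb):
                raise ValueError("paired test requires equal group sizes")
            diff = va - vb
            p = 1.0 if np.all(diff == 0) else float(stats.wilcoxon(va, vb).pvalue)
        else:
            p = float(stats.mannwhitneyu(va, vb, alternative="two-sided").pvalue)
        rows.append((name, p, float(np.median(va) - np.median(vb)),
                     len(va), len(vb), False, ""))

    for ct in sorted(cell_type_labels.dropna().unique()):
        test_stratum(ct, capped[(ct, a)], capped[(ct, b)])
    all_a = pd.Index(np.concatenate([capped[(ct, a)] for ct in sorted(cell_type_labels.dropna().unique())]))
    all_b = pd.Index(np.concatenate([capped[(ct, b)] for ct in sorted(cell_type_labels.dropna().unique())]))
    test_stratum("global", all_a, all_b)
    return pd.DataFrame(rows, columns=[
        "stratum", "p_value", "median_diff", "n_a", "n_b", "skipped", "skip_reason",
    ]).set_index("stratum")
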