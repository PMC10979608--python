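"""Library-complexity analysis by read downsampling.

Reads are subsampled *without replacement* from the per-molecule read
pools: drawing ``n`` of the library's total reads induces a multivariate
hypergeometric distribution over molecules, so a molecule carrying ``r``
reads survives with probability ``1 - C(T-r, n) / C(T, n)``.  Detected
genes and UMIs versus depth give saturation curves; protocols are compared
by fitting ordinary least squares to each curve and asking whether the 95%
confidence intervals of the depth coefficients overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
import statsmodels.api as sm

from .molio import MoleculeTable


@dataclass
class SaturationCurve:
    library_id: str
    depths: list[int]
    genes_detected: list[int]
    umis_detected: list[int]

    def __post_init__(self) -> None:
        d = np.asarray(self.depths)
        if len(d) and (np.diff(d) <= 0).any():
            raise ValueError("depths must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "depth": self.depths,
            "genes_detected": self.genes_detected,
            "umis_detected": self.umis_detected,
        })


@dataclass
class LinearFitCI:
    """OLS fit of a response on sequencing depth with the slope's 95% CI."""

    slope: float
    intercept: float
    slope_ci_low: float
    slope_ci_high: float
    r_squared: float
    degenerate: bool = False  # zero-variance predictor: slope undefined

    def to_dict(self) -> dict:
        return {
            "slope": self.slope, "intercept": self.intercept,
            "slope_ci_low": self.slope_ci_low, "slope_ci_high": self.slope_ci_high,
            "r_squared": self.r_squared, "degenerate": self.degenerate,
        }


@dataclass
class ComparisonVerdict:
    significant: bool
    detail: str = ""


@dataclass
class AccumulationCurve:
    n_cells_grid: list[int]
    mean_genes: list[float]
    n_repetitions: int
    sd_genes: list[float] = field(default_factory=list)


def downsample_reads(table: MoleculeTable, n_reads: int, seed: int) -> MoleculeTable:
    """Sample *n_reads* of the library's reads without replacement.

    Surviving per-molecule read counts follow the multivariate
    hypergeometric law over the per-molecule read pools; molecules with no
    surviving read are dropped.  The surviving reads sum to *n_reads*
    exactly.  ``n_reads == total_reads`` returns the table unchanged (up to
    a copy).
    """
    total = table.total_reads
    if not 0 <= n_reads <= total:
        raise ValueError(f"n_reads={n_reads} outside [0, total_reads={total}]")
    if n_reads == total:
        return table.copy()
    if n_reads == 0:
        return MoleculeTable(table.data.iloc[0:0].copy(), table.library_id)
    rng = np.random.default_rng(seed)
    pools = table.data["read_count"].to_numpy(dtype=np.int64)
    survivors = rng.multivariate_hypergeometric(pools, n_reads, method="marginals")
    keep = survivors > 0
    out = table.data.loc[keep].copy()
    out["read_count"] = survivors[keep]
    return MoleculeTable(out.reset_index(drop=True), table.library_id)


def downsample_nested(table: MoleculeTable, depths: list[int], seed: int) -> list[MoleculeTable]:
    """Nested downsampling: each shallower depth is drawn from the previous.

    Guarantees monotone coupling — detected genes/UMIs are non-decreasing
    in depth along the returned list (ordered by the input *depths*).
    """
    order = np.argsort(depths)[::-1]
    rng_seeds = np.random.SeedSequence(seed).spawn(len(depths))
    current = table
    out: list[MoleculeTable | None] = [None] * len(depths)
    for rank, idx in enumerate(order):
        current = downsample_reads(current, depths[idx], int(rng_seeds[rank].generate_state(1)[0] % 2**31))
        out[idx] = current
    return out  # type: ignore[return-value]


def saturation_curve(
    table: MoleculeTable,
    depth_step: int | None = None,
    depth_grid: list[int] | None = None,
    n_steps: int = 10,
    seed: int = 0,
) -> SaturationCurve:
    """Detected genes / UMIs at stepped read depths.

    *depth_grid* wins if given; else multiples of *depth_step*; else
    ``n_steps`` equal steps up to full depth.  Full depth is always
    included as the last point.  Each depth is one independent
    :func:`downsample_reads` draw with a per-depth child seed.
    """
    if table.n_molecules == 0:
        raise ValueError("empty molecule table")
    total = table.total_reads
    if depth_grid is None:
        if depth_step is not None:
            if depth_step <= 0:
                raise ValueError("depth_step must be > 0")
            depth_grid = list(range(depth_step, total, depth_step))
        else:
            depth_grid = [int(round(total * k / n_steps)) for k in range(1, n_steps)]
    depth_grid = sorted(set(int(d) for d in depth_grid if 0 < d <= total) | {total})
    children = np.random.SeedSequence(seed).spawn(len(depth_grid))
    genes, umis = [], []
    for i, d in enumerate(depth_grid):
        sub = downsample_reads(table, d, int(children[i].generate_state(1)[0] % 2**31))
        genes.append(sub.data["gene_id"].nunique())
        umis.append(sub.n_molecules)
    return SaturationCurve(table.library_id, depth_grid, genes, umis)


def _ols_ci(x: np.ndarray, y: np.ndarray) -> LinearFitCI:
    if len(x) < 3:
        raise ValueError("need at least 3 points for a linear fit")
    if np.allclose(x, x[0]):
        return LinearFitCI(np.nan, np.nan, np.nan, np.nan, np.nan, degenerate=True)
    if np.allclose(y, y[0]):  # constant response: exact zero slope, r^2 undefined
        return LinearFitCI(0.0, float(y[0]), 0.0, 0.0, np.nan)
    X = sm.add_constant(np.asarray(x, dtype=float))
    model = sm.OLS(np.asarray(y, dtype=float), X).fit()
    ci = model.conf_int(alpha=0.05)
    return LinearFitCI(
        slope=float(model.params[1]), intercept=float(model.params[0]),
        slope_ci_low=float(ci[1][0]), slope_ci_high=float(ci[1][1]),
        r_squared=float(model.rsquared),
    )


def fit_depth_model(curve: SaturationCurve, response: str = "genes") -> LinearFitCI:
    """OLS of detected genes or UMIs on sequenced reads, with 95% slope CI."""
    if response not in ("genes", "umis"):
        raise ValueError("response must be 'genes' or 'umis'")
    y = curve.genes_detected if response == "genes" else curve.umis_detected
    return _ols_ci(np.asarray(curve.depths, dtype=float), np.asarray(y, dtype=float))


def ci_overlap_test(fit_a: LinearFitCI, fit_b: LinearFitCI) -> ComparisonVerdict:
    """Protocols differ significantly iff the 95% slope CIs are disjoint.

    Closed-interval convention: touching endpoints count as overlap, hence
    not significant (conservative).
    """
    if fit_a.degenerate or fit_b.degenerate:
        return ComparisonVerdict(False, "degenerate fit")
    disjoint = fit_a.slope_ci_high < fit_b.slope_ci_low or fit_b.slope_ci_high < fit_a.slope_ci_low
    return ComparisonVerdict(bool(disjoint), "disjoint CIs" if disjoint else "CIs overlap")


def per_cell_complexity(table: MoleculeTable) -> tuple[pd.DataFrame, dict[str, LinearFitCI]]:
    """Per-barcode (reads, umis, genes) plus across-cell OLS fits.

    Returns the per-cell table and fits of genes ~ reads and umis ~ reads.
    """
    if table.n_barcodes < 3:
        raise ValueError("need at least 3 barcodes")
    g = table.data.groupby("cell_barcode")
    cells = pd.DataFrame({
        "reads": g["read_count"].sum(),
        "umis": g.size(),
        "genes": g["gene_id"].nunique(),
    })
    fits = {
        "genes": _ols_ci(cells["reads"].to_numpy(), cells["genes"].to_numpy()),
        "umis": _ols_ci(cells["reads"].to_numpy(), cells["umis"].to_numpy()),
    }
    return cells, fits


def cumulative_gene_curve(
    matrix: ad.AnnData,
    n_grid: list[int] | None = None,
    reps: int = 100,
    seed: int = 0,
) -> AccumulationCurve:
    """Mean cumulative detected genes over random cell subsets.

    For each ``n`` in the grid (default 1..100 in steps of 2), draws *reps*
    subsets of ``n`` cells without replacement and averages the size of the
    union of detected genes.
    """
    n_cells = matrix.n_obs
    if n_grid is None:
        n_grid = list(range(1, min(101, n_cells + 1), 2))
    n_grid = sorted(set(int(n) for n in n_grid))
    if not n_grid or n_grid[0] < 1:
        raise ValueError("n_grid must contain positive integers")
    if n_grid[-1] > n_cells:
        raise ValueError(f"n_grid max {n_grid[-1]} exceeds cell count {n_cells}")
    presence = np.asarray((sp.csr_matrix(matrix.X) > 0).todense())
    rng = np.random.default_rng(seed)
    means, sds = [], []
    for n in n_grid:
        if n == n_cells:  # union of all cells, no sampling variance
            total = int((presence.any(axis=0)).sum())
            means.append(float(total))
            sds.append(0.0)
            continue
        vals = np.empty(reps)
        for r in range(reps):
            idx = rng.choice(n_cells, size=n, replace=False)
            vals[r] = presence[idx].any(axis=0).sum()
        means.append(float(vals.mean()))
        sds.append(float(vals.std(ddof=1)) if reps > 1 else 0.0)
    return AccumulationCurve(n_grid, means, reps, sds)
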