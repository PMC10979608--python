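"""Molecule-level and matrix-level I/O.

The molecule table is the format-agnostic equivalent of a 10x
``molecule_info`` record stream: one row per distinct (cell barcode, UMI,
gene) molecule, with the number of sequenced reads supporting it.  Count
matrices are represented as :class:`anndata.AnnData` (cells x genes), with
cell metadata in ``obs`` and gene metadata (biotype, mitochondrial /
ribosomal flags) in ``var``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

MOLECULE_COLUMNS = ["cell_barcode", "umi", "gene_id", "read_count"]


class MoleculeTableError(ValueError):
    """Raised for malformed molecule tables."""


@dataclass
class MoleculeTable:
    """Per-molecule records of one sequencing library.

    Parameters
    ----------
    data
        DataFrame with columns ``cell_barcode``, ``umi``, ``gene_id``,
        ``read_count``.  Each row is one UMI-collapsed molecule; the
        (barcode, umi, gene) triple must be unique and ``read_count >= 1``.
    library_id
        Free-text identifier of the library.
    """

    data: pd.DataFrame
    library_id: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = [c for c in MOLECULE_COLUMNS if c not in self.data.columns]
        if missing:
            raise MoleculeTableError(f"missing column(s): {missing}")
        if len(self.data) == 0:
            self.data = self.data.astype({"read_count": np.int64})
            return
        rc = self.data["read_count"]
        if not pd.api.types.is_integer_dtype(rc):
            bad = rc[pd.to_numeric(rc, errors="coerce").isna() | (pd.to_numeric(rc, errors="coerce") % 1 != 0)]
            row = bad.index[0] if len(bad) else rc.index[0]
            raise MoleculeTableError(f"non-integer read_count at row {row}")
        if (rc < 1).any():
            row = rc.index[(rc < 1).to_numpy().nonzero()[0][0]]
            raise MoleculeTableError(f"read_count < 1 at row {row}")
        dup = self.data.duplicated(subset=["cell_barcode", "umi", "gene_id"])
        if dup.any():
            row = self.data.index[dup.to_numpy().nonzero()[0][0]]
            raise MoleculeTableError(f"duplicate (barcode, umi, gene) at row {row}")

    # -- summary quantities -------------------------------------------------
    @property
    def total_reads(self) -> int:
        return int(self.data["read_count"].sum())

    @property
    def n_molecules(self) -> int:
        return len(self.data)

    @property
    def n_barcodes(self) -> int:
        return self.data["cell_barcode"].nunique()

    def barcodes(self) -> np.ndarray:
        return np.sort(self.data["cell_barcode"].unique())

    def copy(self) -> "MoleculeTable":
        return MoleculeTable(self.data.copy(), self.library_id)


def read_molecule_table(path: str | os.PathLike, library_id: str | None = None) -> MoleculeTable:
    """Read a molecule table from TSV (columns as in :data:`MOLECULE_COLUMNS`)."""
    df = pd.read_csv(path, sep="\t", dtype={"cell_barcode": str, "umi": str, "gene_id": str})
    missing = [c for c in MOLECULE_COLUMNS if c not in df.columns]
    if missing:
        raise MoleculeTableError(f"{path}: missing column(s): {missing}")
    rc_num = pd.to_numeric(df["read_count"], errors="coerce")
    bad = rc_num.isna() | (rc_num % 1 != 0)
    if bad.any():
        raise MoleculeTableError(f"{path}: non-integer read_count at row {bad.idxmax()}")
    df["read_count"] = rc_num.astype(np.int64)
    if library_id is None:
        library_id = os.path.splitext(os.path.basename(path))[0]
    return MoleculeTable(df[MOLECULE_COLUMNS], library_id)


def write_molecule_table(table: MoleculeTable, path: str | os.PathLike) -> None:
    table.data[MOLECULE_COLUMNS].to_csv(path, sep="\t", index=False)


def collapse_to_matrix(
    table: MoleculeTable,
    gene_universe: list[str] | None = None,
    gene_meta: pd.DataFrame | None = None,
) -> ad.AnnData:
    """Collapse molecules to a cells x genes UMI count matrix.

    Each matrix entry is the number of distinct molecules for that
    (barcode, gene) pair; per-molecule read counts are ignored.  Barcodes
    and genes are ordered lexicographically for determinism.
    """
    df = table.data
    if len(df) == 0:
        X = sp.csr_matrix((0, 0), dtype=np.int64)
        adata = ad.AnnData(X=X, obs=pd.DataFrame(index=pd.Index([], name="barcode")),
                           var=pd.DataFrame(index=pd.Index([], name="gene_id")))
        return adata
    barcodes = np.sort(df["cell_barcode"].unique())
    genes = np.array(sorted(gene_universe)) if gene_universe is not None else np.sort(df["gene_id"].unique())
    bc_idx = pd.Series(np.arange(len(barcodes)), index=barcodes)
    g_idx = pd.Series(np.arange(len(genes)), index=genes)
    rows = bc_idx[df["cell_barcode"]].to_numpy()
    cols = g_idx[df["gene_id"]].to_numpy()
    X = sp.coo_matrix((np.ones(len(df), dtype=np.int64), (rows, cols)),
                      shape=(len(barcodes), len(genes))).tocsr()
    X.sum_duplicates()
    var = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    if gene_meta is not None:
        var = var.join(gene_meta)
    annotate_gene_meta(var)
    adata = ad.AnnData(X=X, obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")), var=var)
    adata.uns["library_id"] = table.library_id
    return adata


def annotate_gene_meta(var: pd.DataFrame) -> pd.DataFrame:
    """Fill in is_mito / is_ribo / biotype columns in a gene-metadata frame.

    Mitochondrial genes are recognised by an ``mt-`` name prefix and
    ribosomal-protein genes by ``rps`` / ``rpl`` prefixes (case-insensitive),
    unless the columns are already present.
    """
    names = var.index.str.lower()
    if "is_mito" not in var.columns:
        var["is_mito"] = names.str.startswith("mt-")
    if "is_ribo" not in var.columns:
        var["is_ribo"] = names.str.startswith("rps") | names.str.startswith("rpl")
    if "biotype" not in var.columns:
        var["biotype"] = "unannotated"
    return var


# -- Matrix Market I/O ------------------------------------------------------

def write_mtx(adata: ad.AnnData, directory: str | os.PathLike) -> None:
    """Write an AnnData as CellRanger-style genes x cells Matrix Market triplet.

    Produces ``matrix.mtx``, ``features.tsv`` (gene_id, name, biotype) and
    ``barcodes.tsv`` in *directory*.
    """
    os.makedirs(directory, exist_ok=True)
    X = sp.csr_matrix(adata.X)
    scipy.io.mmwrite(os.path.join(directory, "matrix.mtx"), X.T.astype(np.int64), field="integer")
    var = adata.var
    feats = pd.DataFrame({
        "gene_id": adata.var_names,
        "name": var["name"] if "name" in var.columns else adata.var_names,
        "biotype": var["biotype"] if "biotype" in var.columns else "unannotated",
    })
    feats.to_csv(os.path.join(directory, "features.tsv"), sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(os.path.join(directory, "barcodes.tsv"), sep="\t", header=False, index=False)


def read_mtx(directory: str | os.PathLike) -> ad.AnnData:
    """Read a genes x cells Matrix Market directory back into AnnData."""
    mtx_path = os.path.join(directory, "matrix.mtx")
    try:
        M = scipy.io.mmread(mtx_path)
    except Exception as exc:  # malformed header etc.
        raise MoleculeTableError(f"cannot parse {mtx_path}: {exc}") from exc
    feats = pd.read_csv(os.path.join(directory, "features.tsv"), sep="\t", header=None,
                        names=["gene_id", "name", "biotype"], dtype=str)
    barcodes = pd.read_csv(os.path.join(directory, "barcodes.tsv"), sep="\t", header=None, dtype=str)[0]
    if M.shape[0] != len(feats) or M.shape[1] != len(barcodes):
        raise MoleculeTableError(
            f"dimension mismatch: matrix {M.shape} vs {len(feats)} features, {len(barcodes)} barcodes")
    X = sp.csr_matrix(M.T).astype(np.int64)
    var = feats.set_index("gene_id")
    var.index.name = "gene_id"
    annotate_gene_meta(var)
    obs = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    return ad.AnnData(X=X, obs=obs, var=var)


# -- gene sets (GMT) --------------------------------------------------------

def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    """Read GMT-style gene sets: one set per line, name <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise MoleculeTableError(f"{path}: line {i + 1} has fewer than 3 fields")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | os.PathLike, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


# -- depth equalization -----------------------------------------------------

def equalize_depth(tables: list[MoleculeTable], seed: int, tolerance: float = 0.01) -> list[MoleculeTable]:
    """Downsample libraries so mean reads per barcode match the shallowest.

    This emulates the role of the ``cellranger aggr`` subsampling step:
    every library whose mean reads per barcode exceeds the minimum library's
    mean by more than *tolerance* is read-downsampled (without replacement)
    to ``n_barcodes * target_mean`` total reads.  The shallowest library is
    returned unchanged.
    """
    from .saturation import downsample_reads  # local import: avoids cycle

    if len(tables) < 2:
        raise ValueError("equalize_depth requires at least 2 libraries")
    means = np.array([t.total_reads / t.n_barcodes for t in tables])
    target = means.min()
    children = np.random.SeedSequence(seed).spawn(len(tables))
    out = []
    for i, (t, m) in enumerate(zip(tables, means)):
        if m <= target * (1 + tolerance):
            out.append(t)
        else:
            n_target = int(round(t.n_barcodes * target))
            child_seed = int(children[i].generate_state(1)[0] % (2**31))
            out.append(downsample_reads(t, n_target, seed=child_seed))
    return out
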