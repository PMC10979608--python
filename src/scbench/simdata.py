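"""Synthetic paired-protocol single-cell libraries with known ground truth.

The generator produces molecule-level records for two libraries prepared
from the same cell pool under two protocols: protocol A plays the role of a
"stressed" preparation (e.g. fresh enzymatic dissociation), protocol B a
"protected" one (e.g. reversible fixation).  The generative model is:

* gene abundance rates are log-normal across genes, perturbed per cell type
  by independent log-normal multipliers;
* in protocol A only, a designated stress gene set has its rates multiplied
  by ``stress_fold``;
* each cell draws its total UMI count log-normally and assigns molecule
  gene identities multinomially from its type's rate vector;
* each molecule receives ``1 + NegativeBinomial`` sequenced reads (every
  molecule observed at least once), emulating PCR amplification;
* a fraction of barcodes is converted to low-quality cells (shrunken
  library, boosted mitochondrial fraction) that QC must remove.

Gene-gene correlation, ambient RNA, doublets and splicing are deliberately
not modelled; every downstream statistic in this package depends only on
the structure above.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .molio import MoleculeTable, annotate_gene_meta

_UMI_ALPHABET = np.array(list("ACGT"))
_UMI_LENGTH = 10

PROTOCOL_STRESSED = "A"
PROTOCOL_PROTECTED = "B"


@dataclass
class SyntheticSpec:
    """Full parameterization of a paired-protocol simulation.

    Defaults describe the benchmark scenario used throughout the package:
    three cell types of 200 cells each per protocol, 2000 genes with
    log-normal abundance spanning several orders of magnitude
    (log-sd 1.5), median library size ~5000 UMIs per cell, a 30-gene
    stress signature induced 1.5-fold in the stressed protocol, 5%
    low-quality cells, and a mean of 4 reads per molecule.
    """

    n_cell_types: int = 3
    cells_per_type_per_protocol: pd.DataFrame | None = None  # index=type, columns=[A, B]
    n_genes: int = 2000
    base_rate_log_mean: float = 0.0
    base_rate_log_sd: float = 1.5
    library_size_log_mean: float = float(np.log(5000.0))
    library_size_log_sd: float = 0.35
    type_effect_sd: float = 0.4
    stress_gene_ids: tuple[str, ...] = ()
    stress_fold: float = 1.5
    mt_gene_ids: tuple[str, ...] = ()
    mt_rate_share: float = 0.05  # expected mito fraction in healthy cells
    lowq_fraction: float = 0.05
    lowq_mt_boost: float = 8.0
    amplification_mean: float = 4.0
    amplification_dispersion: float = 1.0
    seed: int = 0

    # populated in __post_init__
    gene_ids: tuple[str, ...] = field(default=(), repr=False)

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_cell_types <= 0:
            raise ValueError("n_genes and n_cell_types must be positive")
        if self.stress_fold <= 0:
            raise ValueError("stress_fold must be > 0")
        if not 0 <= self.lowq_fraction <= 1:
            raise ValueError("lowq_fraction must be in [0, 1]")
        if self.amplification_mean < 1:
            raise ValueError("amplification_mean must be >= 1")
        if not self.gene_ids:
            self.gene_ids = default_gene_ids(self.n_genes)
        if not self.mt_gene_ids:
            self.mt_gene_ids = tuple(g for g in self.gene_ids if g.startswith("mt-"))
        if not self.stress_gene_ids:
            # last 30 non-mito genes by default
            pool = [g for g in self.gene_ids if g not in set(self.mt_gene_ids)]
            self.stress_gene_ids = tuple(pool[-min(30, len(pool)):])
        universe = set(self.gene_ids)
        if not set(self.stress_gene_ids) <= universe:
            raise ValueError("stress gene not in gene universe")
        if not set(self.mt_gene_ids) <= universe:
            raise ValueError("mt gene not in gene universe")
        if self.cells_per_type_per_protocol is None:
            self.cells_per_type_per_protocol = pd.DataFrame(
                200,
                index=[f"type{i}" for i in range(self.n_cell_types)],
                columns=[PROTOCOL_STRESSED, PROTOCOL_PROTECTED],
            )
        comp = self.cells_per_type_per_protocol
        if len(comp) != self.n_cell_types:
            raise ValueError("cells_per_type_per_protocol rows must match n_cell_types")
        if (comp.to_numpy() < 0).any():
            raise ValueError("cell counts must be >= 0")
        for proto in comp.columns:
            if comp[proto].sum() <= 0:
                raise ValueError(f"no cells for protocol {proto!r}")

    @property
    def protocols(self) -> list[str]:
        return list(self.cells_per_type_per_protocol.columns)

    @property
    def cell_types(self) -> list[str]:
        return list(self.cells_per_type_per_protocol.index)


def default_gene_ids(n_genes: int, n_mito: int = 13, n_ribo: int = 40) -> tuple[str, ...]:
    """Deterministic gene universe with mito / ribosomal-protein blocks.

    13 mitochondrial genes mirror the protein-coding mtDNA complement;
    ribosomal-protein genes get rps/rpl prefixes so the QC flags resolve.
    """
    n_mito = min(n_mito, max(n_genes - 2, 0))
    n_ribo = min(n_ribo, max(n_genes - n_mito - 1, 0))
    ids = [f"mt-nd{i}" for i in range(n_mito)]
    ids += [f"rps{i}" if i % 2 == 0 else f"rpl{i}" for i in range(n_ribo)]
    ids += [f"gene{i:05d}" for i in range(n_genes - len(ids))]
    return tuple(ids)


def default_biotypes(gene_ids: tuple[str, ...]) -> pd.Series:
    """Deterministic biotype assignment: ~80% protein_coding, 15% lncRNA, 5% unannotated."""
    out = []
    for i, g in enumerate(gene_ids):
        if g.startswith(("mt-", "rps", "rpl")):
            out.append("protein_coding")
        elif i % 20 == 19:
            out.append("unannotated")
        elif i % 20 >= 17:
            out.append("lncRNA")
        else:
            out.append("protein_coding")
    return pd.Series(out, index=list(gene_ids), name="biotype")


@dataclass
class SimulationTruth:
    """Ground truth accompanying a simulated protocol pair."""

    labels: pd.DataFrame  # barcode-indexed: protocol, cell_type, low_quality
    rates: dict[str, pd.DataFrame]  # protocol -> (type x gene) multinomial probabilities
    spec: SyntheticSpec


def _rng_for(spec: SyntheticSpec, stage: int) -> np.random.Generator:
    """Child generator for a pipeline stage, derived from the master seed.

    Fixed stage offsets let individual stages be re-drawn independently.
    """
    return np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(stage,)))


def _gene_rates(spec: SyntheticSpec) -> dict[str, pd.DataFrame]:
    """Per-protocol, per-type multinomial gene probabilities."""
    rng = _rng_for(spec, 0)
    genes = np.array(spec.gene_ids)
    base = rng.lognormal(spec.base_rate_log_mean, spec.base_rate_log_sd, size=len(genes))
    mt_mask = np.isin(genes, np.array(spec.mt_gene_ids)) if spec.mt_gene_ids else np.zeros(len(genes), bool)
    if mt_mask.any() and 0 < spec.mt_rate_share < 1:
        # rescale mito rates so their expected share matches healthy-cell MT%
        target = spec.mt_rate_share / (1 - spec.mt_rate_share) * base[~mt_mask].sum()
        base[mt_mask] *= target / base[mt_mask].sum()
    type_mult = rng.lognormal(0.0, spec.type_effect_sd, size=(spec.n_cell_types, len(genes)))
    rates = base[None, :] * type_mult
    stress_mask = np.isin(genes, np.array(spec.stress_gene_ids))
    out = {}
    for proto in spec.protocols:
        r = rates.copy()
        if proto == PROTOCOL_STRESSED and spec.stress_fold != 1.0:
            r[:, stress_mask] *= spec.stress_fold
        p = r / r.sum(axis=1, keepdims=True)
        out[proto] = pd.DataFrame(p, index=spec.cell_types, columns=genes)
    return out


def _umi_tokens(rng: np.random.Generator, n: int) -> np.ndarray:
    codes = rng.integers(0, 4, size=(n, _UMI_LENGTH))
    return _UMI_ALPHABET[codes].view((np.str_, _UMI_LENGTH)).ravel()


def _amplify(rng: np.random.Generator, n: int, mean: float, dispersion: float) -> np.ndarray:
    """1 + NB reads per molecule; mean of the NB part is mean - 1."""
    m = mean - 1.0
    if m <= 0:
        return np.ones(n, dtype=np.int64)
    r = dispersion
    p = r / (r + m)
    return 1 + rng.negative_binomial(r, p, size=n).astype(np.int64)


def _cells_to_molecules(
    rng: np.random.Generator,
    spec: SyntheticSpec,
    protocol: str,
    rates: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw all cells of one protocol; return (molecule frame, label frame)."""
    genes = rates.columns.to_numpy()
    comp = spec.cells_per_type_per_protocol[protocol]
    mol_parts, label_rows = [], []
    cell_counter = 0
    for cell_type in spec.cell_types:
        n_cells = int(comp[cell_type])
        if n_cells == 0:
            continue
        p = rates.loc[cell_type].to_numpy()
        totals = np.maximum(1, np.round(rng.lognormal(
            spec.library_size_log_mean, spec.library_size_log_sd, size=n_cells))).astype(np.int64)
        counts = rng.multinomial(totals, p)  # n_cells x n_genes
        barcode_arr = np.array([f"{protocol}-{cell_counter + i:05d}" for i in range(n_cells)])
        cell_counter += n_cells
        nz_cell, nz_gene = counts.nonzero()
        reps = counts[nz_cell, nz_gene]
        mol_parts.append(pd.DataFrame({
            "cell_barcode": np.repeat(barcode_arr[nz_cell], reps),
            "gene_id": np.repeat(genes[nz_gene], reps),
        }))
        label_rows += [(bc, protocol, cell_type) for bc in barcode_arr]
    mol = pd.concat(mol_parts, ignore_index=True)
    labels = pd.DataFrame(label_rows, columns=["barcode", "protocol", "cell_type"]).set_index("barcode")
    return mol, labels


def _assign_unique_umis(rng: np.random.Generator, mol: pd.DataFrame) -> pd.DataFrame:
    """Attach UMI tokens, regenerating collisions within (barcode, gene)."""
    mol = mol.copy()
    mol["umi"] = _umi_tokens(rng, len(mol))
    for _ in range(100):
        dup = mol.duplicated(subset=["cell_barcode", "gene_id", "umi"])
        if not dup.any():
            return mol
        mol.loc[dup, "umi"] = _umi_tokens(rng, int(dup.sum()))
    raise RuntimeError("could not generate unique UMIs")


def simulate_library(spec: SyntheticSpec, protocol: str, rates: pd.DataFrame,
                     stage: int) -> tuple[MoleculeTable, pd.DataFrame]:
    """Simulate one library; returns the molecule table and its truth labels."""
    rng = _rng_for(spec, stage)
    mol, labels = _cells_to_molecules(rng, spec, protocol, rates)
    mol = _assign_unique_umis(rng, mol)
    mol["read_count"] = _amplify(rng, len(mol), spec.amplification_mean, spec.amplification_dispersion)
    table = MoleculeTable(mol[["cell_barcode", "umi", "gene_id", "read_count"]], library_id=f"lib_{protocol}")
    return table, labels


def simulate_protocol_pair(spec: SyntheticSpec) -> tuple[MoleculeTable, MoleculeTable, SimulationTruth]:
    """Simulate the stressed (A) and protected (B) libraries of one benchmark.

    Deterministic given ``spec.seed``.  Low-quality cells are planted in
    each library when ``spec.lowq_fraction > 0`` and flagged in the returned
    truth labels.
    """
    rates = _gene_rates(spec)
    table_a, labels_a = simulate_library(spec, PROTOCOL_STRESSED, rates[PROTOCOL_STRESSED], stage=1)
    table_b, labels_b = simulate_library(spec, PROTOCOL_PROTECTED, rates[PROTOCOL_PROTECTED], stage=2)
    labels = pd.concat([labels_a, labels_b])
    labels["low_quality"] = False
    if spec.lowq_fraction > 0:
        table_a, flagged_a = plant_low_quality_cells(table_a, spec, stage=3)
        table_b, flagged_b = plant_low_quality_cells(table_b, spec, stage=4)
        labels.loc[list(flagged_a) + list(flagged_b), "low_quality"] = True
    truth = SimulationTruth(labels=labels, rates=rates, spec=spec)
    return table_a, table_b, truth


def plant_low_quality_cells(table: MoleculeTable, spec: SyntheticSpec,
                            stage: int = 3) -> tuple[MoleculeTable, list[str]]:
    """Degrade a fraction of barcodes into low-quality cells.

    Exactly ``round(lowq_fraction * n_barcodes)`` barcodes are chosen; each
    has its molecule count shrunk below the 5th percentile of the untouched
    cells and its mitochondrial molecule fraction boosted ``lowq_mt_boost``-fold
    (capped at 90%) by re-assigning non-mitochondrial molecules to random
    mitochondrial genes with fresh UMIs.
    """
    if spec.lowq_fraction == 0:
        return table, []
    if not spec.mt_gene_ids:
        raise ValueError("mt_gene_ids empty while lowq_fraction > 0")
    rng = _rng_for(spec, stage)
    df = table.data
    barcodes = np.sort(df["cell_barcode"].unique())
    n_flag = int(round(spec.lowq_fraction * len(barcodes)))
    flagged = list(rng.choice(barcodes, size=n_flag, replace=False))
    if n_flag == 0:
        return table, []
    sizes = df.groupby("cell_barcode").size()
    normal_sizes = sizes.drop(index=flagged)
    p5 = np.percentile(normal_sizes, 5) if len(normal_sizes) else sizes.median()
    mt_set = set(spec.mt_gene_ids)
    mt_frac_lib = df["gene_id"].isin(mt_set).mean()
    flagged_set = set(flagged)
    keep_parts = [df[~df["cell_barcode"].isin(flagged_set)]]
    groups = {bc: g for bc, g in df[df["cell_barcode"].isin(flagged_set)].groupby("cell_barcode")}
    for bc in flagged:
        cell = groups[bc]
        target_total = max(1, int(rng.uniform(0.2, 0.8) * p5))
        if target_total < len(cell):
            keep_idx = rng.choice(len(cell), size=target_total, replace=False)
            cell = cell.iloc[np.sort(keep_idx)]
        cell = cell.copy()
        is_mt = cell["gene_id"].isin(mt_set).to_numpy()
        base_frac = is_mt.mean() if is_mt.any() else mt_frac_lib
        target_frac = min(0.9, spec.lowq_mt_boost * max(base_frac, mt_frac_lib))
        n_mt_needed = int(round(target_frac * len(cell)))
        n_convert = max(0, n_mt_needed - int(is_mt.sum()))
        non_mt_pos = np.nonzero(~is_mt)[0]
        if n_convert > 0 and len(non_mt_pos) > 0:
            conv = rng.choice(non_mt_pos, size=min(n_convert, len(non_mt_pos)), replace=False)
            new_genes = rng.choice(np.array(spec.mt_gene_ids), size=len(conv))
            col_g = cell.columns.get_loc("gene_id")
            col_u = cell.columns.get_loc("umi")
            cell.iloc[conv, col_g] = new_genes
            cell.iloc[conv, col_u] = _umi_tokens(rng, len(conv))
        keep_parts.append(cell)
    out = pd.concat(keep_parts, ignore_index=True)
    # resolve any residual UMI collisions introduced by re-assignment
    for _ in range(100):
        dup = out.duplicated(subset=["cell_barcode", "gene_id", "umi"])
        if not dup.any():
            break
        out.loc[dup, "umi"] = _umi_tokens(rng, int(dup.sum()))
    return MoleculeTable(out, table.library_id), flagged


def simulate_counts(spec: SyntheticSpec, protocol: str | None = None) -> tuple[ad.AnnData, SimulationTruth]:
    """Simulate UMI count matrices directly, skipping the molecule level.

    Equivalent in distribution to collapsing :func:`simulate_protocol_pair`
    output (the multinomial layer is shared; read amplification does not
    affect UMI counts).  Used for statistical simulations where per-read
    structure is irrelevant.  Returns one AnnData holding both protocols
    (or just *protocol* if given), with labels in ``obs``.
    """
    rates = _gene_rates(spec)
    protocols = [protocol] if protocol is not None else spec.protocols
    genes = np.array(spec.gene_ids)
    blocks, obs_rows = [], []
    for stage, proto in enumerate(protocols, start=1):
        rng = _rng_for(spec, 10 + stage)
        comp = spec.cells_per_type_per_protocol[proto]
        for cell_type in spec.cell_types:
            n_cells = int(comp[cell_type])
            if n_cells == 0:
                continue
            p = rates[proto].loc[cell_type].to_numpy()
            totals = np.maximum(1, np.round(rng.lognormal(
                spec.library_size_log_mean, spec.library_size_log_sd, size=n_cells))).astype(np.int64)
            blocks.append(rng.multinomial(totals, p))
            obs_rows += [(proto, cell_type)] * n_cells
    X = sp.csr_matrix(np.vstack(blocks).astype(np.int64))
    obs = pd.DataFrame(obs_rows, columns=["protocol", "cell_type"])
    obs.index = pd.Index([f"{p}-{i:05d}" for i, p in enumerate(obs["protocol"])], name="barcode")
    var = pd.DataFrame({"biotype": default_biotypes(spec.gene_ids)},
                       index=pd.Index(genes, name="gene_id"))
    annotate_gene_meta(var)
    adata = ad.AnnData(X=X, obs=obs, var=var)
    truth = SimulationTruth(labels=obs.copy(), rates=rates, spec=spec)
    return adata, truth


def spec_to_dict(spec: SyntheticSpec) -> dict:
    """Serialise a SyntheticSpec to plain types (for YAML/JSON provenance)."""
    comp = spec.cells_per_type_per_protocol
    return {
        "n_cell_types": spec.n_cell_types,
        "cells_per_type_per_protocol": {c: comp[c].to_dict() for c in comp.columns},
        "n_genes": spec.n_genes,
        "base_rate_log_mean": spec.base_rate_log_mean,
        "base_rate_log_sd": spec.base_rate_log_sd,
        "library_size_log_mean": spec.library_size_log_mean,
        "library_size_log_sd": spec.library_size_log_sd,
        "type_effect_sd": spec.type_effect_sd,
        "stress_gene_ids": list(spec.stress_gene_ids),
        "stress_fold": spec.stress_fold,
        "mt_gene_ids": list(spec.mt_gene_ids),
        "mt_rate_share": spec.mt_rate_share,
        "lowq_fraction": spec.lowq_fraction,
        "lowq_mt_boost": spec.lowq_mt_boost,
        "amplification_mean": spec.amplification_mean,
        "amplification_dispersion": spec.amplification_dispersion,
        "seed": spec.seed,
    }


def spec_from_dict(d: dict) -> SyntheticSpec:
    d = dict(d)
    comp = d.get("cells_per_type_per_protocol")
    if isinstance(comp, dict):
        d["cells_per_type_per_protocol"] = pd.DataFrame(comp)
    for key in ("stress_gene_ids", "mt_gene_ids"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    return SyntheticSpec(**d)


def write_simulation(directory: str, spec: SyntheticSpec) -> None:
    """Materialise a simulated pair on disk: molecule TSVs, MTX, labels, spec."""
    import os

    import yaml

    from . import molio

    os.makedirs(directory, exist_ok=True)
    table_a, table_b, truth = simulate_protocol_pair(spec)
    molio.write_molecule_table(table_a, os.path.join(directory, "molecules_A.tsv"))
    molio.write_molecule_table(table_b, os.path.join(directory, "molecules_B.tsv"))
    biotypes = default_biotypes(spec.gene_ids)
    for name, table in [("A", table_a), ("B", table_b)]:
        adata = molio.collapse_to_matrix(table, gene_universe=list(spec.gene_ids),
                                         gene_meta=biotypes.to_frame())
        molio.write_mtx(adata, os.path.join(directory, f"matrix_{name}"))
    truth.labels.to_csv(os.path.join(directory, "truth_labels.tsv"), sep="\t")
    with open(os.path.join(directory, "spec.yaml"), "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=True)
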