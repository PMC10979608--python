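"""End-to-end benchmark orchestration.

:class:`ProtocolBenchmark` is the model object: it is built from a pair of
molecule-level libraries (plus cell labels and optional gene sets), or
directly from a :class:`~scbench.simdata.SyntheticSpec`, together with a
:class:`BenchConfig` of stage toggles and parameters.  Its :meth:`fit`
runs the enabled stages in dependency order — depth equalization,
saturation/complexity analysis, QC + normalization + HVG overlap,
pseudo-bulk correlation, composition comparison, differential expression,
signature scoring, pre-ranked GSEA — and returns a
:class:`BenchmarkResults` carrying every verdict, a ``summary()`` table
and a deterministic JSON report.
"""

from __future__ import annotations

import datetime
import json
import os
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import compstats, gsea, molio, qcnorm, saturation, sigscore
from .molio import MoleculeTable
from .qcnorm import PRESETS, QCThresholds
from .simdata import (SimulationTruth, SyntheticSpec, default_biotypes,
                      simulate_protocol_pair, spec_from_dict, spec_to_dict)

SUBSTITUTION_NOTES = {
    "differential_expression": "Wilcoxon rank-sum test in place of a hurdle-model fit",
    "composition": "descriptive proportions with bootstrap CIs in place of Bayesian compositional inference",
}


@dataclass
class BenchConfig:
    """Stage toggles and parameters for one benchmark run."""

    seed: int = 0
    stages: tuple[str, ...] = (
        "equalize", "saturation", "qc", "correlation", "composition",
        "differential_expression", "signatures", "gsea",
    )
    # saturation
    depth_steps: int = 10
    accumulation_reps: int = 100
    accumulation_grid: tuple[int, ...] | None = None
    # qc
    qc_preset: str = "default"
    min_cells_per_gene: int = 3
    normalize_scale: float = 10_000.0
    n_hvg: int = 500
    # correlation
    corr_min_total: int = 100
    corr_min_per_cond: int = 20
    # composition
    n_boot: int = 1000
    # DE
    de_min_pct: float = 0.10
    de_logfc_min: float = 1.0
    de_alpha: float = 0.05
    # signatures
    signature_r_max: int = 1500
    signature_cap: int = 250
    # gsea
    gsea_min_size: int = 10
    gsea_max_size: int = 300
    gsea_n_perm: int = 1000
    gsea_p_weight: float = 1.0

    def __post_init__(self) -> None:
        known = {"equalize", "saturation", "qc", "correlation", "composition",
                 "differential_expression", "signatures", "gsea"}
        bad = set(self.stages) - known
        if bad:
            raise ValueError(f"unknown stage(s): {sorted(bad)}")
        if self.qc_preset not in PRESETS:
            raise ValueError(f"unknown QC preset {self.qc_preset!r}")


class ProtocolBenchmark:
    """Protocol-comparison benchmark model over two single-cell libraries."""

    def __init__(
        self,
        tables: list[MoleculeTable],
        labels: pd.DataFrame,
        gene_sets: dict[str, list[str]] | None = None,
        gene_biotypes: pd.Series | None = None,
        config: BenchConfig | None = None,
        truth: SimulationTruth | None = None,
    ) -> None:
        if len(tables) != 2:
            raise ValueError("exactly two libraries are compared")
        for col in ("protocol", "cell_type"):
            if col not in labels.columns:
                raise ValueError(f"labels must carry a {col!r} column")
        self.tables = tables
        self.labels = labels
        self.gene_sets = gene_sets or {}
        self.gene_biotypes = gene_biotypes
        self.config = config or BenchConfig()
        self.truth = truth

    @classmethod
    def from_simulation(cls, spec: SyntheticSpec, config: BenchConfig | None = None,
                        gene_sets: dict[str, list[str]] | None = None) -> "ProtocolBenchmark":
        """Build the model from a synthetic paired-protocol simulation.

        The planted stress gene set is added as a gene set ("planted_stress")
        so the signature and GSEA stages have a target out of the box.
        """
        table_a, table_b, truth = simulate_protocol_pair(spec)
        sets = dict(gene_sets or {})
        sets.setdefault("planted_stress", list(spec.stress_gene_ids))
        return cls([table_a, table_b], truth.labels, gene_sets=sets,
                   gene_biotypes=default_biotypes(spec.gene_ids),
                   config=config, truth=truth)

    @classmethod
    def from_config(cls, cfg: dict | str) -> "ProtocolBenchmark":
        """Build from a declarative YAML config (path or parsed dict).

        The config either names molecule-table files (``molecules: [a, b]``
        plus ``labels:``) or embeds a ``simulation:`` spec; ``params:``
        feeds :class:`BenchConfig`.
        """
        if isinstance(cfg, str):
            with open(cfg) as fh:
                cfg = yaml.safe_load(fh)
        config = BenchConfig(**cfg.get("params", {}))
        gene_sets = {}
        if cfg.get("gene_sets"):
            gene_sets = molio.read_gmt(cfg["gene_sets"])
        if "simulation" in cfg:
            spec = spec_from_dict(cfg["simulation"])
            return cls.from_simulation(spec, config=config, gene_sets=gene_sets or None)
        tables = [molio.read_molecule_table(p) for p in cfg["molecules"]]
        labels = pd.read_csv(cfg["labels"], sep="\t", index_col=0)
        biotypes = None
        if cfg.get("biotypes"):
            biotypes = pd.read_csv(cfg["biotypes"], sep="\t", index_col=0).iloc[:, 0]
        return cls(tables, labels, gene_sets=gene_sets, gene_biotypes=biotypes, config=config)

    # -- fitting ------------------------------------------------------------
    def fit(self) -> "BenchmarkResults":
        cfg = self.config
        stages = cfg.stages
        report: dict = {"stages": {}, "substitutions": {}, "config": asdict_config(cfg)}
        if self.truth is not None:
            report["config"]["simulation"] = spec_to_dict(self.truth.spec)
        ss = np.random.SeedSequence(cfg.seed)
        stage_seed = {name: int(child.generate_state(1)[0] % 2**31)
                      for name, child in zip(
                          ("equalize", "saturation", "correlation", "composition",
                           "signatures", "gsea", "accumulation"),
                          ss.spawn(7))}

        tables = self.tables
        if "equalize" in stages:
            means_before = [t.total_reads / t.n_barcodes for t in tables]
            tables = molio.equalize_depth(tables, seed=stage_seed["equalize"])
            report["stages"]["equalize"] = {
                "mean_reads_per_barcode_before": means_before,
                "mean_reads_per_barcode_after": [t.total_reads / t.n_barcodes for t in tables],
            }

        matrices = [molio.collapse_to_matrix(
            t, gene_meta=self.gene_biotypes.to_frame("biotype") if self.gene_biotypes is not None else None)
            for t in tables]

        if "saturation" in stages:
            report["stages"]["saturation"] = self._fit_saturation(tables, matrices, stage_seed)

        norm, labels_kept = None, None
        if "qc" in stages:
            norm, labels_kept, qc_report = self._fit_qc(matrices)
            report["stages"]["qc"] = qc_report

        needs_norm = {"correlation", "differential_expression", "signatures", "gsea"} & set(stages)
        if needs_norm and norm is None:
            norm, labels_kept, _ = self._fit_qc(matrices)

        if "correlation" in stages:
            results = compstats.pseudobulk_correlation(
                norm, labels_kept["protocol"], labels_kept["cell_type"],
                min_total=cfg.corr_min_total, min_per_cond=cfg.corr_min_per_cond,
                seed=stage_seed["correlation"])
            report["stages"]["correlation"] = [vars(r) for r in results]

        if "composition" in stages:
            comp = compstats.composition_compare(
                labels_kept["cell_type"], labels_kept["protocol"],
                n_boot=cfg.n_boot, seed=stage_seed["composition"])
            report["stages"]["composition"] = json.loads(comp.reset_index().to_json(orient="records"))
            report["substitutions"]["composition"] = SUBSTITUTION_NOTES["composition"]

        de_table = None
        if {"differential_expression", "gsea"} & set(stages):
            de_table = compstats.differential_expression(
                norm, labels_kept["protocol"], min_pct=cfg.de_min_pct,
                logfc_min=cfg.de_logfc_min, alpha=cfg.de_alpha)
        if "differential_expression" in stages:
            sig = de_table[de_table["significant"]]
            report["stages"]["differential_expression"] = {
                "n_tested": int(de_table["tested"].sum()),
                "n_significant": int(de_table["significant"].sum()),
                "significant_genes": sorted(sig.index),
            }
            report["substitutions"]["differential_expression"] = SUBSTITUTION_NOTES["differential_expression"]

        if "signatures" in stages and self.gene_sets:
            sig_report = {}
            r_max = min(cfg.signature_r_max, norm.n_vars - 1)
            for name, genes in sorted(self.gene_sets.items()):
                present = [g for g in genes if g in norm.var_names]
                if not present:
                    sig_report[name] = {"skipped": "no signature gene in matrix"}
                    continue
                sc = sigscore.score_signature(norm, genes, r_max=r_max, signature_name=name)
                cmp_tbl = sigscore.compare_scores(
                    sc, labels_kept["protocol"], labels_kept["cell_type"],
                    max_cells_per_type=cfg.signature_cap, seed=stage_seed["signatures"])
                sig_report[name] = json.loads(cmp_tbl.reset_index().to_json(orient="records"))
            report["stages"]["signatures"] = sig_report

        if "gsea" in stages and self.gene_sets:
            ranked = gsea.rank_from_de(de_table)
            max_size = min(cfg.gsea_max_size, max(1, len(ranked) - 1))
            res = gsea.preranked_gsea(
                ranked, self.gene_sets, min_size=cfg.gsea_min_size,
                max_size=max_size, n_perm=cfg.gsea_n_perm,
                p_weight=cfg.gsea_p_weight, seed=stage_seed["gsea"])
            report["stages"]["gsea"] = {
                "table": json.loads(res.table.reset_index().to_json(orient="records")),
                "excluded": json.loads(res.excluded.to_json(orient="records")),
            }

        return BenchmarkResults(report, norm=norm, de_table=de_table, model=self)

    def _fit_saturation(self, tables, matrices, stage_seed) -> dict:
        cfg = self.config
        out: dict = {"libraries": {}}
        fits = {}
        for t in tables:
            curve = saturation.saturation_curve(t, n_steps=cfg.depth_steps,
                                                seed=stage_seed["saturation"])
            fit_g = saturation.fit_depth_model(curve, "genes")
            fit_u = saturation.fit_depth_model(curve, "umis")
            cells, cell_fits = saturation.per_cell_complexity(t)
            fits[t.library_id] = {"genes": fit_g, "umis": fit_u}
            out["libraries"][t.library_id] = {
                "curve": curve.to_frame().to_dict(orient="list"),
                "fit_genes": fit_g.to_dict(),
                "fit_umis": fit_u.to_dict(),
                "per_cell_fit_genes": cell_fits["genes"].to_dict(),
                "per_cell_fit_umis": cell_fits["umis"].to_dict(),
            }
        lib_a, lib_b = tables[0].library_id, tables[1].library_id
        for resp in ("genes", "umis"):
            verdict = saturation.ci_overlap_test(fits[lib_a][resp], fits[lib_b][resp])
            out[f"ci_overlap_{resp}"] = {"significant": verdict.significant,
                                         "detail": verdict.detail}
        grid = list(self.config.accumulation_grid) if self.config.accumulation_grid else None
        for m in matrices:
            acc_grid = grid or list(range(1, min(101, m.n_obs + 1), 2))
            acc = saturation.cumulative_gene_curve(m, n_grid=acc_grid,
                                                   reps=cfg.accumulation_reps,
                                                   seed=stage_seed["accumulation"])
            out["libraries"][m.uns["library_id"]]["accumulation"] = {
                "n_cells": acc.n_cells_grid, "mean_genes": acc.mean_genes,
            }
        return out

    def _fit_qc(self, matrices):
        cfg = self.config
        import anndata as ad

        combined = ad.concat(matrices, join="outer", merge="first", fill_value=0)
        combined.var = matrices[0].var.reindex(combined.var_names).combine_first(
            matrices[1].var.reindex(combined.var_names))
        for col in ("is_mito", "is_ribo"):
            combined.var[col] = combined.var[col].astype(bool)
        metrics = qcnorm.compute_qc(combined)
        thresholds = PRESETS[cfg.qc_preset]
        lineage = None
        if thresholds.two_pass is not None:
            lineage = self.labels["lineage"].reindex(combined.obs_names)
        kept, tally = qcnorm.filter_cells(combined, metrics, thresholds, lineage)
        filtered = combined[kept].copy()
        filtered = qcnorm.filter_genes(filtered, cfg.min_cells_per_gene)
        norm = qcnorm.normalize_log(filtered, scale=cfg.normalize_scale)
        labels_kept = self.labels.reindex(norm.obs_names)
        qc_report: dict = {
            "n_cells_in": int(combined.n_obs),
            "n_cells_kept": int(norm.n_obs),
            "removal_tally": tally,
            "n_genes_kept": int(norm.n_vars),
        }
        if "low_quality" in self.labels.columns:
            lowq = self.labels["low_quality"].reindex(combined.obs_names).fillna(False)
            removed = combined.obs_names.difference(kept)
            qc_report["planted_lowq_removed"] = int(lowq[removed].sum())
            qc_report["planted_lowq_total"] = int(lowq.sum())
        # HVG overlap between protocols on the jointly QCed matrix
        protos = sorted(labels_kept["protocol"].dropna().unique())
        if len(protos) == 2 and norm.n_vars >= cfg.n_hvg:
            rankings = []
            for proto in protos:
                cells = labels_kept.index[labels_kept["protocol"] == proto]
                sub = norm[cells].copy()
                try:
                    rankings.append(qcnorm.select_hvgs(sub, n_top=cfg.n_hvg))
                except ValueError:
                    rankings.append(None)
            if all(r is not None for r in rankings):
                qc_report["hvg_overlap"] = qcnorm.hvg_overlap(rankings[0], rankings[1], n=cfg.n_hvg)
        return norm, labels_kept, qc_report


def asdict_config(cfg: BenchConfig) -> dict:
    d = asdict(cfg)
    d["stages"] = list(d["stages"])
    if d.get("accumulation_grid") is not None:
        d["accumulation_grid"] = list(d["accumulation_grid"])
    return d


class BenchmarkResults:
    """Results object: verdict payload, summary table, report serialization.

    The JSON payload is deterministic for a given config and seed; the
    timestamp lives next to the payload, not inside it, so reports can be
    compared byte-for-byte.
    """

    def __init__(self, report: dict, norm=None, de_table=None, model=None) -> None:
        self.report = report
        self.norm = norm
        self.de_table = de_table
        self.model = model

    # -- serialization ------------------------------------------------------
    def payload_json(self) -> str:
        return json.dumps(self.report, sort_keys=True, indent=1, default=_jsonify)

    def to_json(self) -> str:
        doc = {"payload": self.report,
               "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat()}
        return json.dumps(doc, sort_keys=True, indent=1, default=_jsonify)

    def save(self, directory: str) -> None:
        os.makedirs(directory, exist_ok=True)
        with open(os.path.join(directory, "report.json"), "w") as fh:
            fh.write(self.to_json())
        with open(os.path.join(directory, "summary.txt"), "w") as fh:
            fh.write(self.summary())
        if self.de_table is not None:
            self.de_table.to_csv(os.path.join(directory, "differential_expression.tsv"), sep="\t")

    # -- human-readable summary ---------------------------------------------
    def summary(self) -> str:
        r = self.report
        lines = ["Protocol benchmark summary", "=" * 26]
        sat = r["stages"].get("saturation")
        if sat:
            for lib, d in sorted(sat["libraries"].items()):
                fg = d["fit_genes"]
                lines.append(
                    f"{lib}: genes~reads slope {fg['slope']:.3e} "
                    f"(95% CI {fg['slope_ci_low']:.3e} .. {fg['slope_ci_high']:.3e})")
            for resp in ("genes", "umis"):
                v = sat[f"ci_overlap_{resp}"]
                word = "DIFFER" if v["significant"] else "do not differ"
                lines.append(f"saturation slopes ({resp}): protocols {word} ({v['detail']})")
        qc = r["stages"].get("qc")
        if qc:
            lines.append(f"QC: kept {qc['n_cells_kept']}/{qc['n_cells_in']} cells, "
                         f"{qc['n_genes_kept']} genes")
            if "hvg_overlap" in qc:
                lines.append(f"HVG overlap (top {r['config']['n_hvg']}): {qc['hvg_overlap']:.2f}")
        corr = r["stages"].get("correlation")
        if corr:
            for c in corr:
                if c.get("skipped"):
                    lines.append(f"correlation [{c['scope']}]: skipped ({c['skip_reason']})")
                else:
                    lines.append(f"correlation [{c['scope']}]: r^2 = {c['r_squared']:.4f}, "
                                 f"p = {c['p_value']:.2e}, strong = {c['passed_strong']}")
        de = r["stages"].get("differential_expression")
        if de:
            lines.append(f"DE: {de['n_significant']} significant of {de['n_tested']} tested genes")
        sig = r["stages"].get("signatures")
        if sig:
            for name, entries in sorted(sig.items()):
                if isinstance(entries, dict):
                    continue
                glob = [e for e in entries if e["stratum"] == "global"]
                if glob:
                    lines.append(f"signature {name}: global p = {glob[0]['p_value']:.3g}, "
                                 f"median diff = {glob[0]['median_diff']:.4f}")
        gs = r["stages"].get("gsea")
        if gs:
            n_sig = sum(1 for row in gs["table"] if row["significant"])
            lines.append(f"GSEA: {n_sig} significant of {len(gs['table'])} retained sets "
                         f"({len(gs['excluded'])} excluded by size)")
        for stage, note in sorted(r.get("substitutions", {}).items()):
            lines.append(f"note [{stage}]: {note}")
        return "\n".join(lines) + "\n"

    # -- plotting -----------------------------------------------------------
    def plot_saturation(self, response: str = "genes", ax=None):
        """Saturation curves per library (requires the saturation stage)."""
        import matplotlib.pyplot as plt

        sat = self.report["stages"].get("saturation")
        if not sat:
            raise ValueError("saturation stage was not run")
        if ax is None:
            _, ax = plt.subplots()
        for lib, d in sorted(sat["libraries"].items()):
            curve = d["curve"]
            ax.plot(curve["depth"], curve[f"{response}_detected"], marker="o", label=lib)
        ax.set_xlabel("sequenced reads")
        ax.set_ylabel(f"detected {response}")
        ax.legend()
        return ax

    def plot_accumulation(self, ax=None):
        """Cumulative detected-genes curves over sampled cells."""
        import matplotlib.pyplot as plt

        sat = self.report["stages"].get("saturation")
        if not sat:
            raise ValueError("saturation stage was not run")
        if ax is None:
            _, ax = plt.subplots()
        for lib, d in sorted(sat["libraries"].items()):
            acc = d.get("accumulation")
            if acc:
                ax.plot(acc["n_cells"], acc["mean_genes"], label=lib)
        ax.set_xlabel("cells sampled")
        ax.set_ylabel("mean cumulative genes")
        ax.legend()
        return ax


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_benchmark(config: BenchConfig | dict | str, **model_kwargs) -> BenchmarkResults:
    """Functional wrapper: build a :class:`ProtocolBenchmark` and fit it.

    *config* may be a :class:`BenchConfig` (then molecule tables and labels
    must be passed as keyword arguments) or a YAML path / dict consumed by
    :meth:`ProtocolBenchmark.from_config`.
    """
    if isinstance(config, BenchConfig):
        model = ProtocolBenchmark(config=config, **model_kwargs)
    else:
        model = ProtocolBenchmark.from_config(config)
    return model.fit()
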