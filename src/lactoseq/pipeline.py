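"""End-to-end orchestration: expression -> DEG testing -> temporal
profiles -> co-expression -> pathway impact, with every stage product
materialized to TSV and a machine-readable report.json.

The pipeline is a pure function of (inputs, config, seed): rerunning with
the same configuration produces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .degs import DEGThresholds, canonical_comparisons, run_deg_analysis
from .dia import TermAnnotation, score_terms, summarize_categories, top_impacted
from .expression import (
    ExpressionMatrix,
    classify_abundance,
    compute_rpkm,
    stage_mean_rpkm,
    stage_presence,
)
from .io import read_expression_matrix, read_gmt, read_lengths, write_rpkm
from .network import CorrelationDiagnostics, build_network, rank_node_genes
from .patterns import (
    assign_genes,
    cluster_significant_profiles,
    enumerate_candidate_profiles,
    profile_significance,
    select_model_profiles,
)
from .simulate import SimulationConfig, simulate_annotation, simulate_counts, write_fixture

log = logging.getLogger("lactoseq")

__all__ = ["PipelineConfig", "run_pipeline", "write_report", "format_report_value"]


@dataclass
class PipelineConfig:
    """Everything the pipeline needs; either file paths or a simulation
    block must be present."""

    counts: "str | None" = None
    samples: "str | None" = None
    lengths: "str | None" = None
    terms: "str | None" = None
    simulation: "SimulationConfig | None" = None
    out_dir: str = "lactoseq_out"
    seed: int = 0

    # expression_core
    presence_tau: float = 0.0
    # deg_testing
    p_cut: float = 0.05
    fdr_cut: float = 0.05
    dia_fc_cut: float = 2.0
    dia_p_cut: float = 0.001
    pseudocount: float = 0.125
    strict_dual_test: bool = False
    # profile_patterns
    max_profiles: int = 20
    max_unit_change: int = 2
    cluster_corr_threshold: float = 0.7
    # coexpression
    corr_threshold: float = 0.92
    corr_use_abs: bool = True
    top_k: int = 20
    block_size: int = 512
    # impact_dia
    dia_combination: str = "product"
    log_base: float = 10.0
    top_n: int = 10

    def validate(self) -> None:
        has_files = all(x is not None for x in (self.counts, self.samples, self.lengths))
        if not has_files and self.simulation is None:
            raise ValueError("config needs either input file paths or a simulation block")
        for name, lo, hi in (
            ("p_cut", 0, 1), ("fdr_cut", 0, 1), ("dia_p_cut", 0, 1),
            ("corr_threshold", 0, 1), ("cluster_corr_threshold", -1, 1),
        ):
            v = getattr(self, name)
            if not lo < v <= hi:
                raise ValueError(f"{name} must lie in ({lo}, {hi}], got {v}")
        if self.max_profiles < 1 or self.max_unit_change < 1:
            raise ValueError("max_profiles and max_unit_change must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            sim["stages"] = tuple(sim.get("stages", ("L", "D", "NP")))
            if "planted_profiles" in sim:
                sim["planted_profiles"] = tuple(
                    (tuple(l), float(w)) for l, w in sim["planted_profiles"]
                )
            for key in ("gene_length_range", "term_size_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            cfg.simulation = SimulationConfig(**sim)
        return cfg

    def thresholds(self) -> DEGThresholds:
        return DEGThresholds(
            p_cut=self.p_cut, fdr_cut=self.fdr_cut, dia_fc_cut=self.dia_fc_cut,
            dia_p_cut=self.dia_p_cut, pseudocount=self.pseudocount,
            strict_dual_test=self.strict_dual_test,
        )


def format_report_value(v):
    """Floats formatted to 9 significant digits for byte-stable reports."""
    if isinstance(v, dict):
        return {k: format_report_value(x) for k, x in v.items()}
    if isinstance(v, (list, tuple)):
        return [format_report_value(x) for x in v]
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    if isinstance(v, (float, np.floating)):
        return float(f"{float(v):.9g}")
    if isinstance(v, (int, np.integer)):
        return int(v)
    return v


def write_report(report: dict, path) -> None:
    Path(path).write_text(
        json.dumps(format_report_value(report), sort_keys=True, indent=2) + "\n"
    )


def _load_inputs(config: PipelineConfig):
    if config.simulation is not None:
        sim_cfg = config.simulation
        dataset = simulate_counts(sim_cfg)
        dataset.terms = simulate_annotation(sim_cfg, dataset.truth)
        terms = [
            TermAnnotation(r["term_id"], r["name"], r["category"], r["subcategory"], r["genes"])
            for _, r in dataset.terms.iterrows()
        ]
        return dataset.counts, dataset.lengths, terms, dataset
    counts = read_expression_matrix(config.counts, config.samples)
    lengths = read_lengths(config.lengths)
    missing = counts.gene_ids.difference(lengths.index)
    extra = lengths.index.difference(counts.gene_ids)
    if len(missing) or len(extra):
        raise ValueError(
            "gene sets disagree between counts and lengths; symmetric difference starts with "
            f"{(missing.tolist() + extra.tolist())[:10]}"
        )
    terms = read_gmt(config.terms) if config.terms else []
    return counts, lengths, terms, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages, write stage TSVs plus report.json under
    ``config.out_dir``, and return the report dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    report: dict = {"tool": "lactoseq", "version": __version__, "seed": config.seed}

    t0 = time.perf_counter()
    counts, lengths, terms, dataset = _load_inputs(config)
    if dataset is not None:
        write_fixture(dataset, out / "simulated_input")
    timings["load"] = time.perf_counter() - t0
    log.info("loaded %d genes x %d samples", len(counts.gene_ids), len(counts.sample_ids))

    # --- expression core ---
    t0 = time.perf_counter()
    rpkm = compute_rpkm(counts, lengths)
    write_rpkm(rpkm, out / "rpkm.tsv")
    means = stage_mean_rpkm(rpkm)
    presence = stage_presence(means, tau=config.presence_tau)
    bins = {
        stage: pd.Series(classify_abundance(means[stage].to_numpy()))
        .value_counts().reindex(["high", "medium", "low"], fill_value=0).to_dict()
        for stage in rpkm.stages
    }
    report["expression"] = {
        "n_genes": int(len(rpkm.gene_ids)),
        "n_samples": int(len(rpkm.sample_ids)),
        "per_stage_expressed": presence.per_stage_totals(),
        "per_stage_unique": {s: len(presence.unique_genes(s)) for s in rpkm.stages},
        "abundance_bins": {s: {k: int(v) for k, v in b.items()} for s, b in bins.items()},
        "venn": {"+".join(sorted(k)) if k else "none": v for k, v in presence.venn.items()},
    }
    timings["expression"] = time.perf_counter() - t0

    # --- differential testing ---
    t0 = time.perf_counter()
    deg_table, fits = run_deg_analysis(counts, rpkm, thresholds=config.thresholds())
    deg_table.to_csv(out / "deg_results.tsv", sep="\t", index=False, float_format="%.6g")
    deg_summary = {}
    for cmp_label, sub in deg_table.groupby("comparison", sort=True):
        deg_summary[cmp_label] = {
            "n_deg": int(sub["is_deg"].sum()),
            "n_up": int((sub["direction"] == "up").sum()),
            "n_down": int((sub["direction"] == "down").sum()),
            "n_dia_filtered": int(sub["passes_dia_filter"].sum()),
            "rvm_a": fits[cmp_label].a,
            "rvm_b": fits[cmp_label].b,
        }
    report["deg"] = deg_summary
    timings["deg"] = time.perf_counter() - t0
    log.info("DEG testing done: %s", {k: v["n_deg"] for k, v in deg_summary.items()})

    deg_union = deg_table.loc[deg_table["is_deg"], "gene_id"].unique()

    # --- temporal profiles (on DEGs, as pattern analysis targets DEGs) ---
    t0 = time.perf_counter()
    candidates = enumerate_candidate_profiles(t=len(rpkm.stages), c=config.max_unit_change)
    profiles = select_model_profiles(candidates, m=config.max_profiles)
    pattern_genes = means.loc[deg_union] if len(deg_union) else means.iloc[:0]
    if len(pattern_genes):
        assignment = assign_genes(pattern_genes, profiles, pseudocount=config.pseudocount)
        significance = profile_significance(pattern_genes, profiles, pseudocount=config.pseudocount)
        significance["cluster_id"] = cluster_significant_profiles(
            significance, profiles, config.cluster_corr_threshold
        ).to_numpy()
    else:
        assignment = pd.DataFrame(columns=["profile_id", "correlation"])
        significance = pd.DataFrame(
            columns=["profile_id", "levels", "observed", "expected", "p",
                     "p_bonferroni", "significant", "cluster_id"])
    assignment.rename_axis("gene_id").to_csv(out / "patterns.tsv", sep="\t", float_format="%.6g")
    significance.to_csv(out / "profiles.tsv", sep="\t", index=False, float_format="%.6g")
    report["patterns"] = {
        "n_candidate_profiles": len(candidates),
        "n_model_profiles": len(profiles),
        "n_assigned_genes": int(len(assignment)),
        "n_significant_profiles": int(significance["significant"].sum()) if len(significance) else 0,
        "n_profiles_with_genes": int((significance["observed"] > 0).sum()) if len(significance) else 0,
    }
    timings["patterns"] = time.perf_counter() - t0

    # --- co-expression network over DEGs ---
    t0 = time.perf_counter()
    diag = CorrelationDiagnostics()
    if len(deg_union) >= 2:
        edges = build_network(
            rpkm, genes=deg_union, threshold=config.corr_threshold,
            use_abs=config.corr_use_abs, pseudocount=config.pseudocount,
            block_size=config.block_size, diagnostics=diag,
        )
    else:
        edges = pd.DataFrame(columns=["gene_a", "gene_b", "r"])
    degrees, top_nodes = rank_node_genes(edges, gene_universe=deg_union, top_k=config.top_k)
    edges.to_csv(out / "network_edges.tsv", sep="\t", index=False, float_format="%.6g")
    degrees.to_csv(out / "network_degrees.tsv", sep="\t", index=False)
    report["network"] = {
        "n_genes": int(len(deg_union)),
        "n_edges": int(len(edges)),
        "n_zero_variance": len(diag.zero_variance_genes),
        "top_nodes": [
            {"gene_id": r["gene_id"], "degree": int(r["degree"])}
            for _, r in top_nodes.head(config.top_k).iterrows()
        ],
    }
    timings["network"] = time.perf_counter() - t0

    # --- DIA pathway impact ---
    t0 = time.perf_counter()
    impacts = score_terms(
        terms, deg_table, measured_genes=rpkm.gene_ids,
        combination=config.dia_combination, log_base=config.log_base,
    )
    impacts.to_csv(out / "dia_impacts.tsv", sep="\t", index=False, float_format="%.6g")
    summary = summarize_categories(impacts) if len(impacts) else pd.DataFrame()
    summary.to_csv(out / "dia_categories.tsv", sep="\t", index=False, float_format="%.6g")
    top = top_impacted(impacts, n=config.top_n)
    report["dia"] = {
        "n_terms_scored": int(impacts["term_id"].nunique()) if len(impacts) else 0,
        "n_terms_skipped": len({t for t, _, _ in impacts.attrs.get("skipped_terms", [])}),
        "top_terms": [
            {"term_id": r["term_id"], "mean_impact": float(r["mean_impact"]),
             "mean_flux": float(r["mean_flux"])}
            for _, r in top.iterrows()
        ],
    }
    timings["dia"] = time.perf_counter() - t0

    # timings go to the log only, so report.json stays byte-stable
    log.info("stage timings (s): %s", {k: round(v, 3) for k, v in timings.items()})
    report["config"] = _config_echo(config)
    write_report(report, out / "report.json")
    return report


def _config_echo(config: PipelineConfig) -> dict:
    d = asdict(config)
    # filesystem locations are run placement, not analysis parameters;
    # dropping them keeps report.json byte-identical across output dirs
    for key in ("out_dir", "counts", "samples", "lengths", "terms"):
        d.pop(key, None)
    if config.simulation is not None:
        from .simulate import _config_to_jsonable

        d["simulation"] = _config_to_jsonable(config.simulation)
    return d
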