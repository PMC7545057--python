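"""Seeded synthetic data with planted ground truth.

Emulates the study design the rest of the package analyzes: three lactation
stages (peak lactation L, dry-off D, involution NP) with three biological
replicates each, gene-level tag counts, and a term annotation whose
"enriched" terms preferentially contain the planted differentially
expressed genes.

Model
-----
Per-gene baseline means are lognormal (median ~55 counts by default, long
right tail, as in bulk tag-count data).  A fraction ``frac_de`` of genes
receives a planted integer temporal template ``(0, l1, l2)``; the expected
count in stage ``j`` is ``baseline * 2**(level_j * effect_log2fc)``.
Counts are negative binomial with a shared dispersion ``alpha``
(``var = mu + alpha * mu**2``).  Non-DE genes are flat.  Everything is a
pure function of the config, including its seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import DEFAULT_STAGES, ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedDataset",
    "DEFAULT_PLANTED_PROFILES",
    "simulate_counts",
    "simulate_annotation",
    "write_fixture",
]

#: Default planted temporal templates (integer levels per stage, first = 0)
#: with their mixing weights.  All four are valid model profiles for three
#: timepoints with maximum unit change 2, and each is the lowest-id member
#: of its correlation class (profiles with proportional level vectors
#: correlate perfectly, and assignment ties go to the lowest profile id),
#: so each template is recoverable by profile assignment.  The weights are
#: chosen so the expected total RNA output of the planted genes is
#: identical in every stage (sum of w * 2**(level * effect) is
#: stage-independent at the default effect of 2): the planted regulation is
#: compositionally balanced, which is the assumption that justifies global
#: library-size normalization.  Unbalanced planted fold changes would shift
#: every null gene's relative abundance between stages.
DEFAULT_PLANTED_PROFILES: tuple[tuple[tuple[int, ...], float], ...] = (
    ((0, 1, 1), 5 / 42),
    ((0, -2, -2), 8 / 21),
    ((0, 1, 0), 5 / 42),
    ((0, -2, 0), 8 / 21),
)

_CATEGORY_POOL = (
    ("Metabolism", "Lipid Metabolism"),
    ("Metabolism", "Carbohydrate Metabolism"),
    ("Metabolism", "Amino Acid Metabolism"),
    ("Genetic Information Processing", "Translation"),
    ("Genetic Information Processing", "Folding, Sorting and Degradation"),
    ("Environmental Information Processing", "Signal Transduction"),
    ("Cellular Processes", "Transport and Catabolism"),
    ("Organismal Systems", "Endocrine System"),
)


@dataclass
class SimulationConfig:
    """Knobs of the generator; all outputs are deterministic in this
    object, including ``seed``."""

    n_genes: int = 2000
    stages: tuple[str, ...] = DEFAULT_STAGES
    replicates_per_stage: int = 3
    baseline_log_mean: float = 4.0   # natural-log mean of the lognormal baseline
    baseline_log_sd: float = 1.5
    nb_dispersion: float = 0.05      # alpha in var = mu + alpha mu^2
    frac_de: float = 0.2
    effect_log2fc: float = 2.0       # log2 fold change per unit template level
    planted_profiles: tuple[tuple[tuple[int, ...], float], ...] = DEFAULT_PLANTED_PROFILES
    gene_length_range: tuple[int, int] = (300, 5000)
    n_terms: int = 50
    term_size_range: tuple[int, int] = (10, 40)
    frac_enriched_terms: float = 0.1
    enrichment_odds: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        bad = []
        if self.n_genes < 1:
            bad.append("n_genes")
        if len(self.stages) < 2:
            bad.append("stages")
        if self.replicates_per_stage < 1:
            bad.append("replicates_per_stage")
        if self.baseline_log_sd < 0:
            bad.append("baseline_log_sd")
        if self.nb_dispersion <= 0:
            bad.append("nb_dispersion")
        if not 0 <= self.frac_de <= 1:
            bad.append("frac_de")
        if self.effect_log2fc < 0:
            bad.append("effect_log2fc")
        if self.gene_length_range[0] < 1 or self.gene_length_range[0] > self.gene_length_range[1]:
            bad.append("gene_length_range")
        if self.n_terms < 0:
            bad.append("n_terms")
        if self.term_size_range[0] < 1 or self.term_size_range[0] > self.term_size_range[1]:
            bad.append("term_size_range")
        if self.term_size_range[0] > self.n_genes:
            bad.append("term_size_range")
        if not 0 <= self.frac_enriched_terms <= 1:
            bad.append("frac_enriched_terms")
        if self.enrichment_odds <= 0:
            bad.append("enrichment_odds")
        for levels, w in self.planted_profiles:
            if len(levels) != len(self.stages) or levels[0] != 0 or w < 0:
                bad.append("planted_profiles")
                break
        if self.planted_profiles:
            total = sum(w for _, w in self.planted_profiles)
            if not math.isclose(total, 1.0, rel_tol=1e-9):
                bad.append("planted_profiles (weights must sum to 1)")
        if bad:
            raise ValueError(f"invalid SimulationConfig field(s): {sorted(set(bad))}")


@dataclass
class GroundTruth:
    """Planted labels: per-gene DE status, true log2 fold changes for every
    stage pair, planted template; per-term enrichment flag."""

    genes: pd.DataFrame   # is_de, log2fc_<pair> columns, profile_template
    terms: pd.DataFrame   # term_id, is_enriched (empty until annotation drawn)


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    counts: ExpressionMatrix
    lengths: pd.Series
    truth: GroundTruth
    terms: "pd.DataFrame | None" = None  # set by simulate_annotation


def _pair_key(a: str, b: str) -> str:
    return f"log2fc_{a}_{b}"


def simulate_counts(config: SimulationConfig) -> SimulatedDataset:
    """Draw the count matrix, gene lengths, and ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, t = config.n_genes, len(config.stages)
    gene_ids = [f"g{i:05d}" for i in range(n)]

    lengths = pd.Series(
        rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1, size=n),
        index=gene_ids,
        name="length_bp",
    )
    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, size=n)

    is_de = rng.random(n) < config.frac_de
    flat = tuple([0] * t)
    templates = np.empty(n, dtype=object)
    templates[:] = [flat] * n
    if config.planted_profiles and is_de.any():
        weights = np.array([w for _, w in config.planted_profiles])
        choice = rng.choice(len(config.planted_profiles), size=int(is_de.sum()),
                            p=weights / weights.sum())
        de_idx = np.flatnonzero(is_de)
        for i, c in zip(de_idx, choice):
            templates[i] = tuple(config.planted_profiles[c][0])

    levels = np.array([list(tpl) for tpl in templates], dtype=float)  # n x t
    mu = baseline[:, None] * np.power(2.0, levels * config.effect_log2fc)

    r = 1.0 / config.nb_dispersion
    reps = config.replicates_per_stage
    cols, stage_of_sample = [], {}
    data = np.empty((n, t * reps), dtype=np.int64)
    for j, stage in enumerate(config.stages):
        for k in range(reps):
            sid = f"{stage}{k + 1}"
            cols.append(sid)
            stage_of_sample[sid] = stage
            p = r / (r + mu[:, j])
            data[:, j * reps + k] = rng.negative_binomial(r, p)

    counts = ExpressionMatrix(
        values=pd.DataFrame(data, index=gene_ids, columns=cols),
        stage_of_sample=stage_of_sample,
        value_kind="counts",
        stages=tuple(config.stages),
    )

    gt = pd.DataFrame({"is_de": is_de}, index=gene_ids)
    for i in range(t):
        for j in range(i + 1, t):
            a, b = config.stages[i], config.stages[j]
            gt[_pair_key(a, b)] = (levels[:, j] - levels[:, i]) * config.effect_log2fc
    gt["profile_template"] = [",".join(str(v) for v in tpl) for tpl in templates]

    truth = GroundTruth(genes=gt, terms=pd.DataFrame(columns=["term_id", "is_enriched"]))
    return SimulatedDataset(config=config, counts=counts, lengths=lengths, truth=truth)


def simulate_annotation(config: SimulationConfig, truth: GroundTruth) -> pd.DataFrame:
    """Draw the term annotation (GMT-style table).

    Returns a DataFrame with columns term_id, name, category, subcategory,
    genes (tuple of member ids), is_enriched.  Enriched terms sample member
    genes with probability weight ``enrichment_odds`` on planted DE genes;
    other terms sample uniformly.  Also records per-term flags into
    ``truth.terms``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    genes = truth.genes.index.to_numpy()
    n = len(genes)
    lo, hi = config.term_size_range
    if lo > n:
        raise ValueError(f"term_size_range minimum {lo} exceeds n_genes {n}")
    sizes = rng.integers(lo, min(hi, n) + 1, size=config.n_terms)

    n_enriched = int(round(config.frac_enriched_terms * config.n_terms))
    enriched_ids = set(rng.choice(config.n_terms, size=n_enriched, replace=False).tolist())

    de_mask = truth.genes["is_de"].to_numpy()
    w_enriched = np.where(de_mask, config.enrichment_odds, 1.0)
    w_enriched = w_enriched / w_enriched.sum()

    rows = []
    for i in range(config.n_terms):
        enriched = i in enriched_ids
        p = w_enriched if enriched else None
        members = rng.choice(genes, size=sizes[i], replace=False, p=p)
        cat, sub = _CATEGORY_POOL[i % len(_CATEGORY_POOL)]
        rows.append({
            "term_id": f"T{i:04d}",
            "name": f"synthetic term {i}",
            "category": cat,
            "subcategory": sub,
            "genes": tuple(sorted(members.tolist())),
            "is_enriched": enriched,
        })
    terms = pd.DataFrame(rows)
    truth.terms = terms[["term_id", "is_enriched"]].copy()
    return terms


def write_fixture(dataset: SimulatedDataset, directory) -> dict[str, Path]:
    """Write counts.tsv, samples.tsv, lengths.tsv, truth.tsv, terms.gmt and
    a manifest.json recording the generating config."""
    if dataset.counts.values.empty:
        raise ValueError("refusing to write an empty dataset")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}

    counts_path = directory / "counts.tsv"
    dataset.counts.values.rename_axis("gene_id").to_csv(counts_path, sep="\t")
    paths["counts"] = counts_path

    samples = pd.DataFrame({
        "sample_id": dataset.counts.sample_ids,
        "stage": [dataset.counts.stage_of_sample[s] for s in dataset.counts.sample_ids],
        "replicate": [int(s[len(dataset.counts.stage_of_sample[s]):]) for s in dataset.counts.sample_ids],
    })
    samples_path = directory / "samples.tsv"
    samples.to_csv(samples_path, sep="\t", index=False)
    paths["samples"] = samples_path

    lengths_path = directory / "lengths.tsv"
    dataset.lengths.rename_axis("gene_id").to_frame().to_csv(lengths_path, sep="\t")
    paths["lengths"] = lengths_path

    truth_path = directory / "truth.tsv"
    dataset.truth.genes.rename_axis("gene_id").to_csv(truth_path, sep="\t")
    paths["truth"] = truth_path

    if dataset.terms is not None:
        gmt_path = directory / "terms.gmt"
        with open(gmt_path, "w", encoding="utf-8") as fh:
            for _, row in dataset.terms.iterrows():
                meta = f"{row['category']}|{row['subcategory']}|{row['name']}"
                fh.write("\t".join([row["term_id"], meta, *row["genes"]]) + "\n")
        paths["terms"] = gmt_path

    manifest = {"config": _config_to_jsonable(dataset.config)}
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest"] = manifest_path
    return paths


def _config_to_jsonable(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["stages"] = list(config.stages)
    d["planted_profiles"] = [[list(l), w] for l, w in config.planted_profiles]
    d["gene_length_range"] = list(config.gene_length_range)
    d["term_size_range"] = list(config.term_size_range)
    return d


def config_from_jsonable(d: dict) -> SimulationConfig:
    """Inverse of the manifest encoding, for fixture regeneration."""
    d = dict(d)
    d["stages"] = tuple(d["stages"])
    d["planted_profiles"] = tuple((tuple(l), float(w)) for l, w in d["planted_profiles"])
    d["gene_length_range"] = tuple(d["gene_length_range"])
    d["term_size_range"] = tuple(d["term_size_range"])
    return SimulationConfig(**d)
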