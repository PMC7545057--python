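"""Dynamic Impact Approach (DIA) pathway scoring.

For each annotated term and each stage comparison, the perturbation
("impact") combines three signals from the strictly filtered DEGs
(|fold change| > 2, P < 0.001) that belong to the term:

    impact = (|D| / k) * mean_D |log2FC| * mean_D (-log10 p)

where D is the set of filtered DEGs in the term and k the number of term
members measured in the expression matrix.  The direction ("flux") is the
difference between the impact computed on up-regulated and down-regulated
DEGs alone.  Impacts are normalized to [0, 100] within a comparison, rolled
up into category/subcategory means, and ranked across comparisons to give
the overall most-impacted terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TermAnnotation",
    "term_impact",
    "score_terms",
    "normalize_impacts",
    "summarize_categories",
    "top_impacted",
]


@dataclass(frozen=True)
class TermAnnotation:
    """One annotated term (pathway / GO-style category) and its members."""

    term_id: str
    name: str
    category: str
    subcategory: str
    genes: tuple

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"term {self.term_id!r} has no member genes")


def _impact_component(log2fc: np.ndarray, p: np.ndarray, k: int,
                      combination: str, log_base: float) -> float:
    """Impact of one DEG subset against k measured members."""
    if len(log2fc) == 0 or k == 0:
        return 0.0
    prop = len(log2fc) / k
    mean_fc = float(np.mean(np.abs(log2fc)))
    mean_logp = float(np.mean(-np.log(p) / np.log(log_base)))
    if combination == "product":
        return prop * mean_fc * mean_logp
    if combination == "sum":
        return prop + mean_fc + mean_logp
    raise ValueError(f"unknown combination rule {combination!r}")


def term_impact(
    term: TermAnnotation,
    deg_records: pd.DataFrame,
    measured_genes,
    combination: str = "product",
    log_base: float = 10.0,
) -> "dict | None":
    """Impact and flux of one term for one comparison.

    ``deg_records`` must hold one row per gene (single comparison) with
    columns gene_id, log2fc, p_rvm, passes_dia_filter.  Returns None when no
    term member is measured (term skipped).
    """
    measured = set(measured_genes)
    members = [g for g in term.genes if g in measured]
    k = len(members)
    if k == 0:
        return None
    rec = deg_records[deg_records["gene_id"].isin(members) & deg_records["passes_dia_filter"]]
    fc = rec["log2fc"].to_numpy(dtype=float)
    p = rec["p_rvm"].to_numpy(dtype=float)
    up = fc > 0
    impact = _impact_component(fc, p, k, combination, log_base)
    impact_up = _impact_component(fc[up], p[up], k, combination, log_base)
    impact_down = _impact_component(fc[~up], p[~up], k, combination, log_base)
    if combination == "sum":
        # the additive rule is not zero on empty subsets by construction;
        # force the no-DEG convention explicitly
        if len(fc) == 0:
            impact = impact_up = impact_down = 0.0
        if up.sum() == 0:
            impact_up = 0.0
        if (~up).sum() == 0:
            impact_down = 0.0
    return {
        "term_id": term.term_id,
        "name": term.name,
        "category": term.category,
        "subcategory": term.subcategory,
        "k": k,
        "n_deg": int(len(fc)),
        "n_up": int(up.sum()),
        "n_down": int((~up).sum()),
        "impact": impact,
        "impact_up": impact_up,
        "impact_down": impact_down,
        "flux": impact_up - impact_down,
    }


def score_terms(
    terms: list[TermAnnotation],
    deg_table: pd.DataFrame,
    measured_genes,
    combination: str = "product",
    log_base: float = 10.0,
) -> pd.DataFrame:
    """Score every term for every comparison present in ``deg_table``.

    Terms without measured members are skipped (recorded in the
    ``skipped_terms`` attribute of the result).  Impacts are normalized
    within each comparison.
    """
    frames, skipped = [], []
    for comparison, sub in deg_table.groupby("comparison", sort=True):
        rows = []
        for term in terms:
            res = term_impact(term, sub, measured_genes, combination, log_base)
            if res is None:
                skipped.append((term.term_id, comparison, "no measured member genes"))
                continue
            res["comparison"] = comparison
            rows.append(res)
        if rows:
            frame = pd.DataFrame(rows)
            frame["impact_norm"] = normalize_impacts(frame["impact"].to_numpy())
            frames.append(frame)
    if not frames:
        out = pd.DataFrame(columns=[
            "term_id", "name", "category", "subcategory", "comparison",
            "k", "n_deg", "n_up", "n_down", "impact", "impact_up",
            "impact_down", "flux", "impact_norm",
        ])
    else:
        out = pd.concat(frames, ignore_index=True)
    out.attrs["skipped_terms"] = skipped
    return out


def normalize_impacts(impacts: np.ndarray) -> np.ndarray:
    """Scale impacts so the maximum within a comparison maps to 100; an
    all-zero table stays zero."""
    impacts = np.asarray(impacts, dtype=float)
    if impacts.size == 0:
        return impacts
    top = impacts.max()
    return np.zeros_like(impacts) if top <= 0 else 100.0 * impacts / top


def summarize_categories(impacts: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean impact and flux per (comparison, category,
    subcategory), plus category-level rows with subcategory '*'."""
    frame = impacts.copy()
    frame["category"] = frame["category"].fillna("uncategorized").replace("", "uncategorized")
    sub = (
        frame.groupby(["comparison", "category", "subcategory"], sort=True)[["impact", "flux"]]
        .mean()
        .reset_index()
    )
    cat = (
        frame.groupby(["comparison", "category"], sort=True)[["impact", "flux"]]
        .mean()
        .reset_index()
    )
    cat["subcategory"] = "*"
    out = pd.concat([cat[sub.columns], sub], ignore_index=True)
    return out.sort_values(["comparison", "category", "subcategory"], ignore_index=True)


def top_impacted(impacts: pd.DataFrame, n: int = 10) -> pd.DataFrame:
    """Terms ranked by impact averaged across the supplied comparisons,
    descending, ties by term id; per-comparison flux values are attached."""
    if impacts.empty:
        return pd.DataFrame(columns=["term_id", "name", "mean_impact", "mean_flux"])
    agg = (
        impacts.groupby(["term_id", "name"], sort=True)[["impact", "flux"]]
        .mean()
        .rename(columns={"impact": "mean_impact", "flux": "mean_flux"})
        .reset_index()
        .sort_values(["mean_impact", "term_id"], ascending=[False, True], ignore_index=True)
    )
    return agg.head(n)
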