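"""Differential-expression calling per stage comparison.

For each of the canonical comparisons (L vs D, L vs NP, D vs NP) the RVM
moderated t-test runs on log2(RPKM + pseudocount), a Pearson chi-square
count test runs on per-group summed counts versus library totals, p-values
get Benjamini-Hochberg FDR control within the comparison, and genes are
flagged as DEGs at P < 0.05 and FDR < 0.05.  A stricter filter
(|fold change| > 2 and P < 0.001) marks the input set for pathway impact
scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix, stage_mean_rpkm
from .rvm import RVMFit, fit_rvm, rvm_t_test

__all__ = [
    "StageComparison",
    "DEGThresholds",
    "canonical_comparisons",
    "chisq_count_test",
    "bh_fdr",
    "call_degs",
    "dia_filter",
    "run_deg_analysis",
]


@dataclass(frozen=True)
class StageComparison:
    """Ordered stage pair; for (reference, target) the fold change is
    log2(target mean / reference mean), so positive log2fc means
    up-regulated in the target stage."""

    reference: str
    target: str

    def __post_init__(self):
        if self.reference == self.target:
            raise ValueError("reference and target stages must differ")

    @property
    def label(self) -> str:
        return f"{self.reference}_vs_{self.target}"


@dataclass
class DEGThresholds:
    p_cut: float = 0.05
    fdr_cut: float = 0.05
    dia_fc_cut: float = 2.0
    dia_p_cut: float = 0.001
    pseudocount: float = 0.125
    strict_dual_test: bool = False   # require the chi-square p < p_cut too


def canonical_comparisons(stages) -> list[StageComparison]:
    """All ordered pairs (earlier, later) in stage order: for the default
    design (L, D), (L, NP), (D, NP)."""
    stages = list(stages)
    return [
        StageComparison(stages[i], stages[j])
        for i in range(len(stages))
        for j in range(i + 1, len(stages))
    ]


def chisq_count_test(count_ref, count_target, total_ref: float, total_target: float):
    """Pearson chi-square on the 2x2 table
    [[count, total - count] per group], 1 df, no continuity correction.
    Vectorized over genes; returns (statistic, p)."""
    c1 = np.asarray(count_ref, dtype=float)
    c2 = np.asarray(count_target, dtype=float)
    if total_ref <= 0 or total_target <= 0:
        raise ValueError("library totals must be positive")
    if (c1 > total_ref).any() or (c2 > total_target).any():
        raise ValueError("gene count exceeds its library total")
    n1, n2 = float(total_ref), float(total_target)
    n = n1 + n2
    # chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)) for [[a,b],[c,d]]
    a, b, c, d = c1, n1 - c1, c2, n2 - c2
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(denom > 0, n * (a * d - b * c) ** 2 / denom, 0.0)
    from scipy.stats import chi2

    p = chi2.sf(stat, df=1)
    return stat, p


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(records: pd.DataFrame, thresholds: "DEGThresholds | None" = None) -> pd.DataFrame:
    """Flag DEGs (p < p_cut and FDR < fdr_cut) and set direction from the
    sign of log2fc; non-DEGs get direction 'none'."""
    th = thresholds or DEGThresholds()
    out = records.copy()
    is_deg = (out["p_rvm"] < th.p_cut) & (out["fdr"] < th.fdr_cut)
    if th.strict_dual_test:
        is_deg &= out["p_chisq"] < th.p_cut
    out["is_deg"] = is_deg
    out["direction"] = np.where(
        ~is_deg, "none", np.where(out["log2fc"] > 0, "up", "down")
    )
    return out


def dia_filter(log2fc, p, fc_cut: float = 2.0, p_cut: float = 0.001) -> np.ndarray:
    """Pathway-impact input filter: |fold change| strictly > fc_cut and
    p strictly < p_cut."""
    return (np.abs(np.asarray(log2fc, float)) > np.log2(fc_cut)) & (
        np.asarray(p, float) < p_cut
    )


def run_deg_analysis(
    counts: ExpressionMatrix,
    rpkm: ExpressionMatrix,
    comparisons: "list[StageComparison] | None" = None,
    thresholds: "DEGThresholds | None" = None,
) -> tuple[pd.DataFrame, dict[str, RVMFit]]:
    """Full DEG table over all comparisons.

    Returns (records, fits): one row per gene per comparison with columns
    gene_id, comparison, log2fc, p_rvm, p_chisq, fdr, direction, is_deg,
    passes_dia_filter; and the per-comparison RVM fits.
    """
    th = thresholds or DEGThresholds()
    comparisons = comparisons or canonical_comparisons(rpkm.stages)
    logx = np.log2(rpkm.values + th.pseudocount)
    lib = counts.library_sizes()
    means = stage_mean_rpkm(rpkm)

    frames, fits = [], {}
    for cmp_ in comparisons:
        ref_samples = rpkm.samples_of_stage(cmp_.reference)
        tgt_samples = rpkm.samples_of_stage(cmp_.target)
        n1, n2 = len(ref_samples), len(tgt_samples)
        m1 = logx[ref_samples].mean(axis=1).to_numpy()
        m2 = logx[tgt_samples].mean(axis=1).to_numpy()
        v1 = logx[ref_samples].var(axis=1, ddof=1).to_numpy()
        v2 = logx[tgt_samples].var(axis=1, ddof=1).to_numpy()
        d = n1 + n2 - 2
        pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / d
        fit = fit_rvm(pooled, d=d)
        fits[cmp_.label] = fit
        _, _, p_rvm = rvm_t_test(m1, m2, v1, v2, n1, n2, fit)

        c_ref = counts.values[counts.samples_of_stage(cmp_.reference)].sum(axis=1)
        c_tgt = counts.values[counts.samples_of_stage(cmp_.target)].sum(axis=1)
        t_ref = float(lib[counts.samples_of_stage(cmp_.reference)].sum())
        t_tgt = float(lib[counts.samples_of_stage(cmp_.target)].sum())
        _, p_chisq = chisq_count_test(c_ref.to_numpy(), c_tgt.to_numpy(), t_ref, t_tgt)

        log2fc = np.log2(
            (means[cmp_.target] + th.pseudocount) / (means[cmp_.reference] + th.pseudocount)
        ).to_numpy()

        frame = pd.DataFrame({
            "gene_id": rpkm.gene_ids,
            "comparison": cmp_.label,
            "log2fc": log2fc,
            "p_rvm": p_rvm,
            "p_chisq": p_chisq,
        })
        frame["fdr"] = bh_fdr(frame["p_rvm"].to_numpy())  # within-comparison FDR
        frame = call_degs(frame, th)
        frame["passes_dia_filter"] = dia_filter(
            frame["log2fc"], frame["p_rvm"], th.dia_fc_cut, th.dia_p_cut
        )
        frames.append(frame)

    return pd.concat(frames, ignore_index=True), fits
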