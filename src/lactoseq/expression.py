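"""Expression-matrix data model, RPKM normalization, abundance classes,
and stage-presence (Venn) logic.

The backbone container is :class:`ExpressionMatrix`, a thin validated
wrapper around a pandas DataFrame (genes x samples) that also carries the
lactation-stage label of every sample.  Downstream stages (differential
testing, temporal profiles, co-expression, pathway impact) all consume it.

RPKM (reads per kilobase of transcript per million mapped reads) is the
normalized unit used throughout::

    RPKM[g, s] = 1e9 * counts[g, s] / (library_size[s] * length_bp[g])

where ``library_size[s]`` is the column sum of the count matrix.  Genes are
binned into three abundance classes: low (< 10 RPKM), medium (10-500 RPKM,
half-open) and high (>= 500 RPKM).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "HIGH_RPKM_CUT",
    "LOW_RPKM_CUT",
    "DEFAULT_STAGES",
    "compute_rpkm",
    "classify_abundance",
    "stage_mean_rpkm",
    "stage_presence",
    "StagePresence",
    "count_unique_by_stage",
]

#: Abundance-class boundaries in RPKM.  The bins form a partition of
#: [0, inf): low = [0, 10), medium = [10, 500), high = [500, inf).
HIGH_RPKM_CUT = 500.0
LOW_RPKM_CUT = 10.0

#: Canonical stage ordering: peak lactation (L), dry-off (D),
#: non-lactating/non-pregnant involution (NP).
DEFAULT_STAGES: tuple[str, ...] = ("L", "D", "NP")


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of counts or RPKM with stage labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample.
        All entries must be finite and non-negative.
    stage_of_sample
        Mapping from sample id to stage label; every column of ``values``
        must be covered and every stage must have at least one sample.
    value_kind
        Either ``"counts"`` or ``"rpkm"``.
    stages
        Ordered stage labels of the design.  Defaults to the distinct
        labels of ``stage_of_sample`` ordered as in :data:`DEFAULT_STAGES`
        when applicable, else by first appearance.
    """

    values: pd.DataFrame
    stage_of_sample: dict[str, str]
    value_kind: str = "counts"
    stages: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.value_kind not in ("counts", "rpkm"):
            raise ValueError(f"value_kind must be 'counts' or 'rpkm', got {self.value_kind!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:10]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:10]}")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("expression matrix contains non-finite entries")
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative expression value at gene {self.values.index[g]!r}, "
                f"sample {self.values.columns[s]!r}"
            )
        missing = [s for s in self.values.columns if s not in self.stage_of_sample]
        if missing:
            raise ValueError(f"samples without stage label: {missing}")
        if not self.stages:
            seen = list(dict.fromkeys(self.stage_of_sample[s] for s in self.values.columns))
            if set(seen) == set(DEFAULT_STAGES):
                seen = list(DEFAULT_STAGES)
            self.stages = tuple(seen)
        for stage in self.stages:
            if not any(self.stage_of_sample[s] == stage for s in self.values.columns):
                raise ValueError(f"stage {stage!r} has no samples")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_of_stage(self, stage: str) -> list[str]:
        return [s for s in self.values.columns if self.stage_of_sample[s] == stage]

    def library_sizes(self) -> pd.Series:
        """Column sums — total counted reads per sample."""
        return self.values.sum(axis=0)


def compute_rpkm(counts: ExpressionMatrix, lengths: pd.Series) -> ExpressionMatrix:
    """Normalize a count matrix to RPKM.

    ``lengths`` maps gene id to transcript length in base pairs (>= 1).
    Library size is the column sum of the count matrix.
    """
    if counts.value_kind != "counts":
        raise ValueError("compute_rpkm expects a counts matrix")
    missing = counts.gene_ids.difference(lengths.index)
    if len(missing):
        raise ValueError(f"missing gene lengths for: {missing[:10].tolist()}")
    glen = lengths.reindex(counts.gene_ids).astype(float)
    if (glen < 1).any():
        bad = glen.index[glen < 1][:10].tolist()
        raise ValueError(f"gene lengths must be >= 1 bp, offending genes: {bad}")
    lib = counts.library_sizes()
    if (lib <= 0).any():
        bad = lib.index[lib <= 0][:10].tolist()
        raise ValueError(f"zero library size for sample(s): {bad}")
    rpkm = counts.values.div(lib, axis=1).div(glen, axis=0) * 1e9
    return ExpressionMatrix(
        values=rpkm,
        stage_of_sample=dict(counts.stage_of_sample),
        value_kind="rpkm",
        stages=counts.stages,
    )


def classify_abundance(rpkm_value):
    """Bin RPKM value(s) into {'low', 'medium', 'high'}.

    Accepts a scalar or array-like; vectorized.  The bins are half-open:
    low = [0, 10), medium = [10, 500), high = [500, inf).
    """
    arr = np.asarray(rpkm_value, dtype=float)
    if (arr < 0).any():
        raise ValueError("RPKM values must be non-negative")
    out = np.where(arr >= HIGH_RPKM_CUT, "high", np.where(arr >= LOW_RPKM_CUT, "medium", "low"))
    if np.isscalar(rpkm_value) or arr.ndim == 0:
        return str(out)
    return out


def stage_mean_rpkm(rpkm: ExpressionMatrix) -> pd.DataFrame:
    """Arithmetic mean of replicate RPKM per stage (genes x stages)."""
    cols = {}
    for stage in rpkm.stages:
        samples = rpkm.samples_of_stage(stage)
        if not samples:
            raise ValueError(f"stage {stage!r} has no samples")
        cols[stage] = rpkm.values[samples].mean(axis=1)
    return pd.DataFrame(cols, index=rpkm.gene_ids)[list(rpkm.stages)]


@dataclass
class StagePresence:
    """Presence of each gene per stage with the Venn partition.

    ``present`` is a boolean genes x stages frame (stage-mean RPKM > tau).
    ``venn`` maps a frozenset of stages (every non-empty combination plus
    the empty set for absent-everywhere genes) to its gene count.
    """

    present: pd.DataFrame
    tau: float
    stages: tuple[str, ...]
    venn: dict[frozenset, int] = field(default_factory=dict)

    @property
    def presence_sets(self) -> pd.Series:
        stages = list(self.stages)
        return self.present.apply(lambda row: frozenset(s for s in stages if row[s]), axis=1)

    def unique_genes(self, stage: str) -> list:
        """Genes expressed in exactly one stage — this one."""
        sets = self.presence_sets
        return sets.index[sets == frozenset({stage})].tolist()

    def per_stage_totals(self) -> dict[str, int]:
        return {s: int(self.present[s].sum()) for s in self.stages}


def stage_presence(stage_means: pd.DataFrame, tau: float = 0.0) -> StagePresence:
    """Mark genes present per stage (stage-mean RPKM > tau) and tally the
    Venn partition over stages.  Default tau = 0: any positive stage mean
    counts as detected."""
    if tau < 0:
        raise ValueError("presence threshold tau must be >= 0")
    stages = tuple(stage_means.columns)
    present = stage_means > tau
    venn: dict[frozenset, int] = {}
    from itertools import combinations

    for r in range(0, len(stages) + 1):
        for combo in combinations(stages, r):
            venn[frozenset(combo)] = 0
    for _, row in present.iterrows():
        key = frozenset(s for s in stages if row[s])
        venn[key] += 1
    return StagePresence(present=present, tau=tau, stages=stages, venn=venn)


def count_unique_by_stage(
    records: pd.DataFrame,
    stage_column: str = "stage",
    stages: Sequence[str] = DEFAULT_STAGES,
) -> dict[str, int]:
    """Tally stage labels of a (gene, stage) table; stages with no record
    report 0.  Unknown labels raise."""
    counts = {s: 0 for s in stages}
    for label in records[stage_column]:
        if label not in counts:
            raise ValueError(f"unknown stage label {label!r}; expected one of {list(stages)}")
        counts[label] += 1
    return counts
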