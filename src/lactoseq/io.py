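"""Readers and writers for the pipeline's plain-text dialects.

counts.tsv   header of sample ids, one row per gene (gene_id first).
samples.tsv  columns sample_id, stage, replicate.
lengths.tsv  columns gene_id, length_bp.
terms.gmt    term_id TAB "category|subcategory|name" TAB gene ids...
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .dia import TermAnnotation
from .expression import ExpressionMatrix

__all__ = [
    "read_counts",
    "read_samples",
    "read_lengths",
    "read_gmt",
    "write_gmt",
    "write_rpkm",
    "read_expression_matrix",
]


def read_samples(path) -> pd.DataFrame:
    samples = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "stage": str})
    required = {"sample_id", "stage"}
    if not required.issubset(samples.columns):
        raise ValueError(f"{path}: samples table needs columns {sorted(required)}")
    if samples["sample_id"].duplicated().any():
        dup = samples.loc[samples["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    return samples


def read_counts(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    arr = frame.to_numpy()
    if not np.isfinite(arr).all() or (arr < 0).any():
        bad = np.argwhere(~np.isfinite(arr) | (arr < 0))[0]
        raise ValueError(
            f"{path}: invalid count at gene {frame.index[bad[0]]!r}, "
            f"sample {frame.columns[bad[1]]!r}"
        )
    frame.index.name = None  # canonical in-memory form; writers re-add gene_id
    return frame


def read_expression_matrix(counts_path, samples_path, value_kind: str = "counts") -> ExpressionMatrix:
    counts = read_counts(counts_path)
    samples = read_samples(samples_path)
    extra = set(counts.columns) ^ set(samples["sample_id"])
    if extra:
        raise ValueError(
            f"sample ids disagree between {counts_path} and {samples_path}: "
            f"{sorted(extra)[:10]}"
        )
    stage_of_sample = dict(zip(samples["sample_id"], samples["stage"]))
    return ExpressionMatrix(values=counts, stage_of_sample=stage_of_sample, value_kind=value_kind)


def read_lengths(path) -> pd.Series:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if "length_bp" not in frame.columns:
        raise ValueError(f"{path}: lengths table needs a length_bp column")
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    lengths = frame["length_bp"].astype(int)
    if (lengths < 1).any():
        raise ValueError(f"{path}: gene lengths must be positive integers")
    lengths.index.name = None
    return lengths


def read_gmt(path) -> list[TermAnnotation]:
    terms, seen = [], set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields")
            term_id, meta, genes = fields[0], fields[1], tuple(fields[2:])
            if term_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate term id {term_id!r}")
            seen.add(term_id)
            parts = meta.split("|")
            category = parts[0] if len(parts) > 0 else ""
            subcategory = parts[1] if len(parts) > 1 else ""
            name = parts[2] if len(parts) > 2 else term_id
            terms.append(TermAnnotation(term_id, name, category, subcategory, genes))
    return terms


def write_gmt(terms: list[TermAnnotation], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term in terms:
            meta = f"{term.category}|{term.subcategory}|{term.name}"
            fh.write("\t".join([term.term_id, meta, *term.genes]) + "\n")


def write_rpkm(rpkm: ExpressionMatrix, path) -> None:
    """RPKM matrix mirroring the counts dialect, 6-decimal fixed format."""
    rpkm.values.rename_axis("gene_id").to_csv(path, sep="\t", float_format="%.6f")
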