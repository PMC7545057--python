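"""Small bundled example tables."""

from importlib import resources

import pandas as pd

__all__ = ["load_unique_deg_example"]


def load_unique_deg_example() -> pd.DataFrame:
    """Example table of stage-unique DEGs from dairy goat mammary tissue:
    one row per gene with its accession, symbol, description, RPKM in the
    stage where it is expressed, and that stage label (D = dry-off,
    NP = non-lactating/non-pregnant)."""
    path = resources.files("lactoseq.data") / "unique_degs_example.tsv"
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")
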