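"""Packaged count tables from the source MA study.

Three small tables ship with the package: per-lineage single-base
substitution and indel counts for the sixteen MMR-null-like lineages (plus
the genomic wild type), the six-category genome-wide mutation spectrum, and
the per-motif-class insertion/deletion counts.  They are the printed inputs
from which all published percentages, rates, folds and bias p-values can be
recomputed.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("mapipe.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def lineage_counts() -> pd.DataFrame:
    """Per-lineage SBS/indel counts; functional_class marks the 16 null-like
    lineages vs the genomic wild type."""
    return _load("lineage_counts.tsv")


def spectrum_counts() -> pd.Series:
    df = _load("spectrum_counts.tsv")
    return df.set_index("category")["count"]


def indel_bias_counts() -> pd.DataFrame:
    """Insertions/deletions per canonical motif class."""
    return _load("indel_bias_counts.tsv")
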