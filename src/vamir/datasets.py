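"""Packaged reference tables from the published Amur grape small-RNA survey.

Three plain-text fixtures transcribed from the published characterization
of a deep-sequenced *Vitis amurensis* (Amur grape) small-RNA library:

* the annotation-category distribution (unique/redundant counts),
* the ortholog mature-sequence pairs with terminal divergence versus
  *V. vinifera* and the 'Summer Black' hybrid cultivar, and
* the catalog of novel hairpin-derived miRNA candidates (sequence, read
  count, stem-loop length, genomic start, MFE, miRNA* support).

These serve as worked inputs for the summary/divergence machinery; the
raw sequencing library itself is not distributed and is emulated by the
:mod:`vamir.simulate` generator.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_category_counts",
    "load_ortholog_pairs",
    "load_novel_candidates",
    "RAW_READS",
    "CLEAN_READS",
    "GENOME_MATCHED_READS",
    "TOTAL_UNIQUE_TAGS",
]

# Published library totals (read counts).
RAW_READS = 19_692_474
CLEAN_READS = 18_902_700
GENOME_MATCHED_READS = 8_706_269
TOTAL_UNIQUE_TAGS = 6_740_185


def _read(name: str) -> pd.DataFrame:
    with resources.files("vamir.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_category_counts() -> pd.DataFrame:
    """Category -> (unique, redundant) counts of the published library."""
    return _read("category_counts_amur.tsv").set_index("category")


def load_ortholog_pairs(comparison: str = "vinifera") -> pd.DataFrame:
    """Ortholog mature-sequence pairs; ``comparison`` is ``vinifera`` or
    ``summer_black``."""
    if comparison not in {"vinifera", "summer_black"}:
        raise ValueError(f"unknown comparison {comparison!r}")
    return _read(f"ortholog_pairs_{comparison}.tsv")


def load_novel_candidates() -> pd.DataFrame:
    """Published novel-candidate catalog (one row per genomic locus;
    ``candidate_id`` groups multi-locus candidates)."""
    df = _read("novel_candidates_amur.tsv")
    df["star"] = df["star"].fillna("").eq("Y")
    return df
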