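"""Packaged Tamil Nadu survey fixture.

The package ships a curated transcription of the published 31-population x
21-haplogroup frequency table (1680 Y chromosomes) together with the
population groupings used throughout: the seven subsistence-based major
population groups (MPG), the tribe/caste dichotomy, and the rank strata.
See ``data/tn31_provenance.md`` for how the transcription was checksummed.
"""
from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .datamodel import HAPLOGROUPS, CountMatrix, Grouping, counts_from_frequencies

__all__ = [
    "table2_fixture",
    "fixture_frequencies",
    "mpg_grouping",
    "tribe_caste_grouping",
    "rank_grouping",
    "grouping_frame",
]


def _data(name: str):
    return resources.files("ystrat.data").joinpath(name)


def fixture_frequencies() -> pd.DataFrame:
    """The curated percentage table (31 rows, 21 haplogroup columns, N)."""
    with _data("tn31_haplogroup_freq.csv").open() as fh:
        return pd.read_csv(fh)


def table2_fixture() -> CountMatrix:
    """Integer counts reconstructed from the printed percentages.

    Every row satisfies its checksum (counts sum to the printed N); the grand
    total is 1680 chromosomes over 21 haplogroups.
    """
    df = fixture_frequencies()
    counts = np.vstack([
        counts_from_frequencies(row[list(HAPLOGROUPS)].to_numpy(dtype=float),
                                int(row["N"]))
        for _, row in df.iterrows()
    ])
    return CountMatrix(list(df["population"]), list(HAPLOGROUPS), counts)


def grouping_frame() -> pd.DataFrame:
    with _data("tn31_groupings.csv").open() as fh:
        return pd.read_csv(fh)


def _grouping(column: str, name: str) -> Grouping:
    df = grouping_frame()
    return Grouping(name, dict(zip(df["population"], df[column])))


def mpg_grouping() -> Grouping:
    """Seven major population groups (HTF, HTC, HTK, SC, DLF, AW, BRH)."""
    return _grouping("mpg", "7-MPG")


def tribe_caste_grouping() -> Grouping:
    """12 tribal vs 19 non-tribal (caste) populations."""
    return _grouping("caste_tribe", "tribe-caste")


def rank_grouping() -> Grouping:
    """Tribes plus the three self-assigned rank strata (TR/LOW/MID/HIGH)."""
    return _grouping("rank", "rank")
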