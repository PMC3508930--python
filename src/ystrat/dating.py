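"""Lineage age estimation from Y-STR repeat variance.

Under the single-step mutation model the expected repeat variance accumulated
along a lineage grows linearly with time, so the mean across-locus variance
converts to an age through the effective mutation rate:

    age [years] = Var / w * g

with ``w`` the effective per-locus mutation rate per generation
(default 6.9e-4, the Zhivotovsky-style calibration) and ``g`` the generation
length in years (default 25). The across-locus standard error of the mean
variance propagates linearly to an age SD.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import HaplotypeTable

__all__ = [
    "EFFECTIVE_MUTATION_RATE",
    "GENERATION_YEARS",
    "DatingResult",
    "locus_variance",
    "age_estimate",
    "date_haplogroups",
]

EFFECTIVE_MUTATION_RATE = 6.9e-4   # per locus per generation
GENERATION_YEARS = 25.0
MIN_RECORDS = 5


@dataclass(frozen=True)
class DatingResult:
    haplogroup: str
    group: str
    variance: float
    variance_se: float
    age_years: float
    age_sd_years: float
    n: int
    w: float
    g: float


class InsufficientSample(ValueError):
    """Fewer than the minimum number of complete haplotypes."""


def locus_variance(t: HaplotypeTable) -> tuple[float, float, int]:
    """Mean per-locus repeat variance and its across-locus SE.

    The table should already be filtered to one haplogroup (and optionally
    one population group). Per-locus variances use the n-1 denominator;
    samples with any missing allele are excluded; fewer than 5 complete
    haplotypes raises :class:`InsufficientSample`, mirroring the exclusion
    rule of the published table.
    """
    a = t.alleles(complete_only=True)
    if a.shape[0] < MIN_RECORDS:
        raise InsufficientSample(
            f"{a.shape[0]} complete haplotypes (< {MIN_RECORDS})")
    per_locus = a.var(axis=0, ddof=1)
    var = float(per_locus.mean())
    se = float(per_locus.std(ddof=1) / np.sqrt(per_locus.size))
    return var, se, a.shape[0]


def age_estimate(variance: float, variance_se: float = 0.0,
                 w: float = EFFECTIVE_MUTATION_RATE,
                 g: float = GENERATION_YEARS,
                 haplogroup: str = "", group: str = "",
                 n: int = 0) -> DatingResult:
    """Convert a mean STR variance into an age in years (age = Var/w * g)."""
    if w <= 0:
        raise ValueError("mutation rate w must be positive")
    if variance < 0:
        raise ValueError("variance must be non-negative")
    return DatingResult(
        haplogroup=haplogroup, group=group,
        variance=variance, variance_se=variance_se,
        age_years=variance / w * g,
        age_sd_years=variance_se / w * g,
        n=n, w=w, g=g,
    )


def date_haplogroups(t: HaplotypeTable, grouping=None,
                     w: float = EFFECTIVE_MUTATION_RATE,
                     g: float = GENERATION_YEARS) -> list[DatingResult]:
    """Age estimates for every (haplogroup, group) cell with >= 5 haplotypes.

    *grouping* maps population -> group; when omitted, a single pooled
    "all" group is used. Cells below the sample threshold are skipped.
    """
    hgs = sorted({r.haplogroup for r in t.records})
    if grouping is None:
        cells = [("all", None)]
    else:
        cells = [(grp, [p for p in t.populations if grouping[p] == grp])
                 for grp in grouping.groups]
        cells.insert(0, ("all", None))
    out = []
    for hg in hgs:
        for label, pops in cells:
            sub = t.subset(populations=pops, haplogroup=hg)
            try:
                var, se, n = locus_variance(sub)
            except InsufficientSample:
                continue
            out.append(age_estimate(var, se, w=w, g=g, haplogroup=hg,
                                    group=label, n=n))
    return out
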