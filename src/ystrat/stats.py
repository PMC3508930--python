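"""Diversity, lineage-class proportions and haplogroup enrichment tests.

Gene diversity follows Nei's unbiased estimator

    D = n/(n-1) * (1 - sum_i p_i^2)

with its sampling variance (Nei 1987)

    V(D) = 2/(n(n-1)) * [ 2(n-2) (sum p_i^3 - (sum p_i^2)^2)
                          + sum p_i^2 - (sum p_i^2)^2 ].

Enrichment of a haplogroup in a population group uses a Fisher exact test on
the 2x2 table [[hg in group, other in group], [hg outside, other outside]];
a second-level test asks whether the *number of populations* over-represented
in the haplogroup is itself concentrated in the group.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .datamodel import CountMatrix, Grouping

__all__ = [
    "DiversityResult",
    "LineageClassResult",
    "EnrichmentResult",
    "nei_diversity",
    "lineage_class_proportion",
    "hg_enrichment_test",
    "population_overrep_test",
]


@dataclass(frozen=True)
class DiversityResult:
    d: float
    sd: float
    n: int


@dataclass(frozen=True)
class LineageClassResult:
    name: str
    proportion: float
    se: float
    n: int


@dataclass(frozen=True)
class EnrichmentResult:
    haplogroup: str
    group: str
    direction: str          # "over" | "under" | "none"
    p_value: float
    p_value_one_sided: float | None
    table: tuple[tuple[int, int], tuple[int, int]]
    degenerate: bool = False


def nei_diversity(counts: Sequence[int]) -> DiversityResult:
    """Nei gene diversity with its standard deviation.

    *counts* are integer class counts (e.g. haplogroup counts of a pooled
    sample); requires a total of at least 2.
    """
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("negative counts")
    n = c.sum()
    if n < 2:
        raise ValueError("gene diversity undefined for n < 2")
    p = c / n
    ssq = float((p ** 2).sum())
    scu = float((p ** 3).sum())
    d = n / (n - 1.0) * (1.0 - ssq)
    var = 2.0 / (n * (n - 1.0)) * (2.0 * (n - 2.0) * (scu - ssq ** 2)
                                   + ssq - ssq ** 2)
    return DiversityResult(d=float(d), sd=float(np.sqrt(max(var, 0.0))),
                           n=int(n))


def lineage_class_proportion(m: CountMatrix, class_set: Iterable[str],
                             rows: Iterable[str] | None = None,
                             name: str = "class") -> LineageClassResult:
    """Pooled proportion of a haplogroup class with its binomial SE."""
    cls = list(class_set)
    unknown = set(cls) - set(m.haplogroups)
    if unknown:
        raise ValueError(f"haplogroups not in inventory: {sorted(unknown)}")
    sub = m.subset_rows(list(rows)) if rows is not None else m
    if not sub.populations:
        raise ValueError("empty population subset")
    n = int(sub.counts.sum())
    k = int(sum(sub.column(h).sum() for h in cls))
    p = k / n
    se = float(np.sqrt(p * (1.0 - p) / n))
    return LineageClassResult(name=name, proportion=p, se=se, n=n)


def _fisher(table: np.ndarray) -> tuple[str, float, float, bool]:
    """Direction, two-sided p, one-sided p (in the observed direction)."""
    a, b = int(table[0, 0]), int(table[0, 1])
    c, d = int(table[1, 0]), int(table[1, 1])
    if min(a + b, c + d, a + c, b + d) == 0:
        return "none", 1.0, 1.0, True
    # direction from the odds ratio (conditional MLE not needed for sign)
    sample_or = (a * d) / (b * c) if b * c > 0 else np.inf
    direction = "over" if sample_or > 1 else ("under" if sample_or < 1 else "none")
    p_two = float(sps.fisher_exact(table, alternative="two-sided")[1])
    alt = "greater" if sample_or >= 1 else "less"
    p_one = float(sps.fisher_exact(table, alternative=alt)[1])
    return direction, min(p_two, 1.0), min(p_one, 1.0), False


def hg_enrichment_test(m: CountMatrix, g: Grouping, hg: str,
                       group: str) -> EnrichmentResult:
    """Is *hg* over- or under-represented in *group* versus the rest?"""
    in_rows = [p for p in m.populations if g[p] == group]
    out_rows = [p for p in m.populations if g[p] != group]
    if not in_rows:
        raise ValueError(f"group {group!r} has no populations")
    hg_in = int(sum(m.row(p)[m.haplogroups.index(hg)] for p in in_rows))
    n_in = int(sum(m.row(p).sum() for p in in_rows))
    hg_out = int(sum(m.row(p)[m.haplogroups.index(hg)] for p in out_rows))
    n_out = int(sum(m.row(p).sum() for p in out_rows))
    table = np.array([[hg_in, n_in - hg_in], [hg_out, n_out - hg_out]])
    direction, p_two, p_one, degen = _fisher(table)
    return EnrichmentResult(hg, group, direction, p_two, p_one,
                            tuple(map(tuple, table.tolist())), degen)


def population_overrep_test(m: CountMatrix, g: Grouping, hg: str, group: str,
                            criterion: str = "point_estimate_above_overall",
                            alpha: float = 0.05) -> EnrichmentResult:
    """Second-level Fisher test on the *number of populations* enriched.

    Each population is first classified as over-represented in *hg* per the
    chosen criterion; the 2x2 table then crosses that classification with
    membership of *group*. Criteria:

    ``point_estimate_above_overall``
        population frequency strictly above the pooled overall frequency;
    ``per_population_fisher``
        one-sided Fisher test of the population against all others,
        significant at *alpha*.
    """
    j = m.haplogroups.index(hg)
    overall = m.counts[:, j].sum() / m.counts.sum()
    flags: dict[str, bool] = {}
    for i, pop in enumerate(m.populations):
        if criterion == "point_estimate_above_overall":
            flags[pop] = (m.counts[i, j] / m.counts[i].sum()) > overall
        elif criterion == "per_population_fisher":
            a = int(m.counts[i, j]); b = int(m.counts[i].sum() - a)
            c = int(m.counts[:, j].sum() - a)
            d = int(m.counts.sum() - a - b - c)
            p = sps.fisher_exact([[a, b], [c, d]], alternative="greater")[1]
            flags[pop] = p < alpha
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
    in_pops = [p for p in m.populations if g[p] == group]
    out_pops = [p for p in m.populations if g[p] != group]
    table = np.array([
        [sum(flags[p] for p in in_pops), sum(not flags[p] for p in in_pops)],
        [sum(flags[p] for p in out_pops), sum(not flags[p] for p in out_pops)],
    ])
    direction, p_two, p_one, degen = _fisher(table)
    return EnrichmentResult(hg, group, direction, p_two, p_one,
                            tuple(map(tuple, table.tolist())), degen)
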