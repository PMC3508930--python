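"""Population structure: R_ST distances, hierarchical AMOVA, the multinomial
bootstrap for comparing groupings, PCA and non-metric MDS.

AMOVA partitions the total sum of squared inter-individual distances into
among-group, among-population-within-group and within-population components
(Excoffier, Smouse & Quattro 1992). For haplogroup data the inter-individual
distance is 0/1 identity; for STR haplotypes it is the squared repeat-count
difference summed over loci, which makes the two-population fixation index
Slatkin's R_ST. Variance components for unequal sample sizes use the
standard weighted coefficients

    n'   = (N - sum_g sum_{p in g} n_p^2 / n_g) / (P - G)
    n''  = (sum_g sum_{p in g} n_p^2 / n_g - sum_p n_p^2 / N) / (G - 1)
    n''' = (N - sum_g n_g^2 / N) / (G - 1)

and the Phi-statistics are F_CT = Va/V, F_SC = Vb/(Vb+Vc),
F_ST = (Va+Vb)/V with V = Va+Vb+Vc.

Both sums of squares reduce to sufficient statistics: with 0/1 distances the
ordered-pair sum within a set is n^2 - sum_c count_c^2, and with squared STR
differences it is, per locus, 2n*sum(a^2) - 2*(sum a)^2 — so no explicit
pairwise matrix is ever formed except in the brute-force test oracle.
"""
from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import MDS

from .datamodel import CountMatrix, DistanceMatrix, Grouping, HaplotypeTable

__all__ = [
    "AmovaResult",
    "BootstrapCI",
    "OrdinationResult",
    "rst_distance_matrix",
    "amova",
    "amova_permutation_test",
    "bootstrap_fct",
    "compare_groupings",
    "pca",
    "nmds",
]


@dataclass(frozen=True)
class AmovaResult:
    va: float
    vb: float
    vc: float
    fct: float | None
    fsc: float | None
    fst: float
    df: tuple[int, int, int]
    metric: str

    @property
    def total_variance(self) -> float:
        return self.va + self.vb + self.vc


@dataclass(frozen=True)
class BootstrapCI:
    statistic: str
    median: float
    lower: float
    upper: float
    n_replicates: int
    n_degenerate: int
    fingerprint: str


@dataclass(frozen=True)
class OrdinationResult:
    labels: list[str]
    coordinates: np.ndarray
    variance_fractions: np.ndarray | None = None
    loadings: np.ndarray | None = None
    feature_names: list[str] | None = None
    stress_percent: float | None = None
    skree_components: int | None = None


# ---------------------------------------------------------------------------
# sufficient statistics for sums of squared distances

def _ssd_str(alleles: np.ndarray) -> float:
    """SSD within one set under summed squared repeat differences.

    (1/2n) * sum over ordered pairs of d^2  ==  sum_l [sum a^2 - (sum a)^2/n].
    """
    n = alleles.shape[0]
    s1 = (alleles.astype(float) ** 2).sum(axis=0)
    s2 = alleles.astype(float).sum(axis=0)
    return float((s1 - s2 ** 2 / n).sum())


def _ssd_counts(counts: np.ndarray) -> float:
    """SSD within one set under 0/1 haplogroup-identity distance."""
    n = counts.sum()
    return float((n * n - (counts.astype(float) ** 2).sum()) / (2.0 * n))


def _components(ssd_t, ssd_wg, ssd_wp, n_pop, n_group, pop_sizes, group_of_pop):
    """Variance components from hierarchical SSDs with unequal-size weights."""
    N = float(sum(pop_sizes))
    P, G = n_pop, n_group
    ssd_ap = ssd_wg - ssd_wp
    ssd_ag = ssd_t - ssd_wg
    df_ag, df_ap, df_wp = G - 1, P - G, int(N) - P
    if df_wp <= 0:
        raise ValueError("need more individuals than populations")
    vc = ssd_wp / df_wp
    groups = sorted(set(group_of_pop))
    sizes = np.asarray(pop_sizes, dtype=float)
    ng = {g: sizes[[i for i, x in enumerate(group_of_pop) if x == g]].sum()
          for g in groups}
    sum_np2_over_ng = sum(
        (sizes[[i for i, x in enumerate(group_of_pop) if x == g]] ** 2).sum() / ng[g]
        for g in groups)
    sum_np2 = float((sizes ** 2).sum())
    sum_ng2 = sum(v ** 2 for v in ng.values())
    if G == 1:
        # one-level design: among populations vs within
        n_c = (N - sum_np2 / N) / (P - 1)
        vb = (ssd_ap / df_ap - vc) / n_c
        va = 0.0
        fst = (va + vb) / (va + vb + vc)
        return AmovaResult(va, vb, vc, None, None, fst,
                           (0, df_ap, df_wp), "")
    n1 = (N - sum_np2_over_ng) / (P - G)
    n2 = (sum_np2_over_ng - sum_np2 / N) / (G - 1)
    n3 = (N - sum_ng2 / N) / (G - 1)
    vb = (ssd_ap / df_ap - vc) / n1
    va = (ssd_ag / df_ag - vc - n2 * vb) / n3
    tot = va + vb + vc
    return AmovaResult(va, vb, vc, va / tot, vb / (vb + vc),
                       (va + vb) / tot, (df_ag, df_ap, df_wp), "")


def _amova_from_counts(counts: np.ndarray, group_of_pop: Sequence[str]):
    pop_sizes = counts.sum(axis=1)
    groups = sorted(set(group_of_pop))
    ssd_t = _ssd_counts(counts.sum(axis=0))
    ssd_wp = sum(_ssd_counts(row) for row in counts)
    ssd_wg = sum(
        _ssd_counts(counts[[i for i, g in enumerate(group_of_pop) if g == grp]]
                    .sum(axis=0))
        for grp in groups)
    return _components(ssd_t, ssd_wg, ssd_wp, counts.shape[0], len(groups),
                       pop_sizes, group_of_pop)


def _amova_from_alleles(alleles: np.ndarray, pop_of_ind: np.ndarray,
                        group_of_pop: Sequence[str], pops: Sequence[str]):
    ssd_t = _ssd_str(alleles)
    ssd_wp = 0.0
    pop_sizes = []
    for i, p in enumerate(pops):
        a = alleles[pop_of_ind == i]
        pop_sizes.append(a.shape[0])
        ssd_wp += _ssd_str(a)
    groups = sorted(set(group_of_pop))
    ssd_wg = 0.0
    for grp in groups:
        members = [i for i, g in enumerate(group_of_pop) if g == grp]
        mask = np.isin(pop_of_ind, members)
        ssd_wg += _ssd_str(alleles[mask])
    return _components(ssd_t, ssd_wg, ssd_wp, len(pops), len(groups),
                       pop_sizes, group_of_pop)


def amova(data: CountMatrix | HaplotypeTable, grouping: Grouping,
          metric: Literal["auto", "hg01", "str"] = "auto",
          clamp: bool = False) -> AmovaResult:
    """Hierarchical AMOVA (individuals in populations in groups).

    A :class:`CountMatrix` implies haplogroup-identity (0/1) distances; a
    :class:`HaplotypeTable` implies summed squared STR repeat differences
    (records with missing alleles are excluded). A single-group grouping
    yields the one-level design where only F_ST is defined. Negative
    variance components are reported as estimated unless ``clamp=True``.
    """
    if isinstance(data, CountMatrix):
        if metric == "str":
            raise ValueError("STR metric requires a HaplotypeTable")
        group_of_pop = [grouping[p] for p in data.populations]
        res = _amova_from_counts(data.counts, group_of_pop)
        return _retag(res, "hg01", clamp)
    if metric == "hg01":
        cm = data.count_matrix()
        res = _amova_from_counts(cm.counts,
                                 [grouping[p] for p in cm.populations])
        return _retag(res, "hg01", clamp)
    sub = data.subset(complete_only=True)
    pops = sub.populations
    pop_idx = {p: i for i, p in enumerate(pops)}
    pop_of_ind = np.array([pop_idx[r.population] for r in sub.records])
    res = _amova_from_alleles(sub.alleles(), pop_of_ind,
                              [grouping[p] for p in pops], pops)
    return _retag(res, "str", clamp)


def _retag(res: AmovaResult, metric: str, clamp: bool = False) -> AmovaResult:
    va, vb, vc = res.va, res.vb, res.vc
    if clamp:
        va, vb = max(va, 0.0), max(vb, 0.0)
        tot = va + vb + vc
        fct = va / tot if res.fct is not None else None
        fsc = vb / (vb + vc) if res.fsc is not None else None
        return AmovaResult(va, vb, vc, fct, fsc, (va + vb) / tot,
                           res.df, metric)
    return AmovaResult(va, vb, vc, res.fct, res.fsc, res.fst,
                       res.df, metric)


# ---------------------------------------------------------------------------
# R_ST

def rst_distance_matrix(t: HaplotypeTable, clamp_negative: bool = False
                        ) -> DistanceMatrix:
    """Pairwise R_ST between populations from 17-locus STR haplotypes.

    Each pair is a two-population one-level AMOVA on squared repeat
    differences; negative estimates are reported as computed unless
    *clamp_negative*. Populations of size 1 (after excluding incomplete
    records) are rejected by name.
    """
    sub = t.subset(complete_only=True)
    pops = sub.populations
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    mats = {p: sub.subset(populations=[p]).alleles() for p in pops}
    for p, a in mats.items():
        if a.shape[0] < 2:
            raise ValueError(f"population {p!r} has fewer than 2 complete records")
    k = len(pops)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            a, b = mats[pops[i]], mats[pops[j]]
            alleles = np.vstack([a, b])
            pop_of_ind = np.repeat([0, 1], [a.shape[0], b.shape[0]])
            res = _amova_from_alleles(alleles, pop_of_ind, ["g", "g"],
                                      [pops[i], pops[j]])
            rst = res.fst
            if clamp_negative:
                rst = max(rst, 0.0)
            out[i, j] = out[j, i] = rst
    # negative off-diagonal estimates are legitimate AMOVA output and are
    # kept unless clamped above
    return DistanceMatrix(pops, out, metric="rst")


# ---------------------------------------------------------------------------
# permutation tests

def _count_multiset_perms(labels: Sequence) -> int:
    from collections import Counter
    c = Counter(labels)
    total = math.factorial(len(labels))
    for v in c.values():
        total //= math.factorial(v)
    return total


def _enumerate_multiset(labels: Sequence):
    from sympy.utilities.iterables import multiset_permutations
    return multiset_permutations(list(labels))


def amova_permutation_test(data: CountMatrix | HaplotypeTable,
                           grouping: Grouping, n_perm: int = 999,
                           seed: int | None = None) -> dict[str, float]:
    """Permutation p-values for the three Phi-statistics.

    Null schemes: F_CT — permute whole populations among groups; F_SC —
    permute individuals among populations within their group; F_ST — permute
    individuals among all populations. p = (#null >= observed + 1)/(n_perm+1).
    When fewer distinct permutations than *n_perm* exist the null is
    enumerated exhaustively and the p-value is exact.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = np.random.default_rng(seed)
    if isinstance(data, CountMatrix):
        counts = data.counts
        pops = data.populations
    else:
        cm = data.count_matrix()
        counts, pops = cm.counts, cm.populations
    group_of_pop = [grouping[p] for p in pops]
    obs = _amova_from_counts(counts, group_of_pop)
    out: dict[str, float] = {}

    # F_CT: populations among groups
    if obs.fct is not None:
        total = _count_multiset_perms(group_of_pop)
        if total <= n_perm:
            null = [
                _amova_from_counts(counts, perm).fct
                for perm in _enumerate_multiset(group_of_pop)
            ]
            out["fct"] = (sum(v >= obs.fct - 1e-12 for v in null)) / len(null)
        else:
            ge = 0
            labels = np.array(group_of_pop)
            for _ in range(n_perm):
                perm = rng.permutation(labels)
                if _amova_from_counts(counts, list(perm)).fct >= obs.fct - 1e-12:
                    ge += 1
            out["fct"] = (ge + 1) / (n_perm + 1)

    # individual-level schemes operate on the expanded haplogroup labels
    ind_hg = np.repeat(np.arange(counts.shape[1]),
                       counts.sum(axis=0))  # pooled order: by haplogroup
    # rebuild individual list preserving population identity
    ind_hg = np.concatenate([np.repeat(np.arange(counts.shape[1]), row)
                             for row in counts])
    pop_sizes = counts.sum(axis=1)
    pop_of_ind = np.repeat(np.arange(len(pops)), pop_sizes)

    def recount(hg_labels):
        c = np.zeros_like(counts)
        for i in range(len(pops)):
            c[i] = np.bincount(hg_labels[pop_of_ind == i],
                               minlength=counts.shape[1])
        return c

    # F_ST: individuals among populations
    ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(ind_hg)
        if _amova_from_counts(recount(perm), group_of_pop).fst >= obs.fst - 1e-12:
            ge += 1
    out["fst"] = (ge + 1) / (n_perm + 1)

    # F_SC: individuals among populations within groups
    if obs.fsc is not None:
        ge = 0
        groups = sorted(set(group_of_pop))
        masks = {g: np.isin(pop_of_ind,
                            [i for i, x in enumerate(group_of_pop) if x == g])
                 for g in groups}
        for _ in range(n_perm):
            perm = ind_hg.copy()
            for g in groups:
                m = masks[g]
                perm[m] = rng.permutation(perm[m])
            if _amova_from_counts(recount(perm), group_of_pop).fsc >= obs.fsc - 1e-12:
                ge += 1
        out["fsc"] = (ge + 1) / (n_perm + 1)
    return out


# ---------------------------------------------------------------------------
# multinomial bootstrap over groupings

def _fingerprint(arr: np.ndarray, statistic: str) -> str:
    h = hashlib.sha256()
    h.update(arr.tobytes())
    h.update(statistic.encode())
    return h.hexdigest()[:16]


def bootstrap_fct(data: CountMatrix | HaplotypeTable, grouping: Grouping,
                  n_replicates: int = 500, seed: int | None = None,
                  pooled: bool = False) -> BootstrapCI:
    """Bootstrap distribution of F_CT under within-population resampling.

    Each replicate resamples individuals with replacement within every
    population (a multinomial draw over its haplotypes, size preserved) and
    recomputes F_CT. With ``pooled=True`` haplotypes are instead resampled
    across populations (sizes still preserved). Replicates whose resample is
    degenerate (a single haplotype class everywhere) are recorded and
    excluded.
    """
    if n_replicates < 100:
        raise ValueError("need at least 100 replicates")
    rng = np.random.default_rng(seed)
    if isinstance(data, CountMatrix):
        counts, pops = data.counts, data.populations
    else:
        cm = data.count_matrix()
        counts, pops = cm.counts, cm.populations
    if counts.shape[0] < 2:
        raise ValueError("bootstrap requires at least 2 populations")
    group_of_pop = [grouping[p] for p in pops]
    if len(set(group_of_pop)) < 2:
        raise ValueError("F_CT undefined for a single group")
    pop_sizes = counts.sum(axis=1)
    pooled_freq = counts.sum(axis=0) / counts.sum()
    values = []
    degenerate = 0
    for _ in range(n_replicates):
        if pooled:
            boot = np.vstack([rng.multinomial(n, pooled_freq)
                              for n in pop_sizes])
        else:
            boot = np.vstack([
                rng.multinomial(pop_sizes[i], counts[i] / pop_sizes[i])
                for i in range(len(pops))
            ])
        if (boot.sum(axis=0) > 0).sum() < 2:
            degenerate += 1
            continue
        values.append(_amova_from_counts(boot, group_of_pop).fct)
    values = np.array(values)
    lo, med, hi = np.percentile(values, [2.5, 50, 97.5])
    return BootstrapCI("fct", float(med), float(lo), float(hi),
                       len(values), degenerate,
                       _fingerprint(counts, "fct"))


def compare_groupings(a: BootstrapCI, b: BootstrapCI) -> str:
    """Order two grouping schemes by non-overlap of their bootstrap CIs."""
    if a.fingerprint != b.fingerprint:
        raise ValueError("bootstrap CIs computed on different data")
    if a.lower > b.upper:
        return "a>b"
    if b.lower > a.upper:
        return "b>a"
    return "overlap"


# ---------------------------------------------------------------------------
# ordination

def pca(matrix: np.ndarray | CountMatrix, labels: Sequence[str] | None = None,
        feature_names: Sequence[str] | None = None,
        unit: Literal["population", "individual"] = "population"
        ) -> OrdinationResult:
    """Covariance-mode PCA, column-centred without variance normalisation.

    ``unit="population"`` treats each row of a frequency matrix as one
    observation. ``unit="individual"`` (requires a :class:`CountMatrix`)
    expands the counts to per-individual 0/1 haplogroup indicators — the
    genotype-matrix convention — computes the eigenbasis there, and reports
    population coordinates as projections of the population frequency
    vectors; variance fractions then refer to individual-level variance.
    """
    if isinstance(matrix, CountMatrix):
        cm = matrix
        labels = list(cm.populations)
        feature_names = list(cm.haplogroups)
        F = cm.frequencies(percent=False)
        if unit == "individual":
            w = cm.n / cm.total                      # population weights
            mean = cm.counts.sum(axis=0) / cm.total
            # individual-level covariance of 0/1 indicators:
            #   diag(mean) - sum_p w_p f_p f_p^T  + between-population part
            # computed directly from the indicator expansion's moments
            second = np.diag(mean)                   # E[x x^T] for indicators
            cov = second - np.outer(mean, mean)
            evals, evecs = np.linalg.eigh(cov)
            order = np.argsort(evals)[::-1]
            evals, evecs = np.maximum(evals[order], 0), evecs[:, order]
            frac = evals / evals.sum()
            coords = (F - mean) @ evecs
            return OrdinationResult(labels, coords, frac, evecs,
                                    feature_names,
                                    skree_components=_skree(evals))
        matrix = F
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("PCA needs at least 3 observations")
    Xc = X - X.mean(axis=0)
    if not Xc.any():
        raise ValueError("constant matrix has no principal components")
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    evals = s ** 2
    frac = evals / evals.sum()
    coords = u * s
    return OrdinationResult(list(labels) if labels is not None else
                            [str(i) for i in range(X.shape[0])],
                            coords, frac, vt.T,
                            list(feature_names) if feature_names is not None else None,
                            skree_components=_skree(evals))


def _skree(evals: np.ndarray) -> int:
    """Components before the largest successive eigenvalue drop (advisory)."""
    ev = np.asarray(evals, float)
    ev = ev[ev > 1e-12 * max(ev[0], 1.0)]
    if len(ev) < 2:
        return len(ev)
    drops = ev[:-1] - ev[1:]
    return int(np.argmax(drops)) + 1


def kruskal_stress1(dissimilarity: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 (fraction, not percent) of a configuration."""
    n = dissimilarity.shape[0]
    iu = np.triu_indices(n, 1)
    d_conf = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2)
                     .sum(-1))[iu]
    diss = dissimilarity[iu]
    order = np.argsort(diss, kind="stable")
    iso = IsotonicRegression()
    disp = np.empty_like(d_conf)
    disp[order] = iso.fit_transform(np.arange(len(order)), d_conf[order])
    denom = (d_conf ** 2).sum()
    return float(np.sqrt(((d_conf - disp) ** 2).sum() / denom))


def nmds(d: DistanceMatrix, dims: int = 2, restarts: int = 20,
         seed: int | None = None, max_iter: int = 500) -> OrdinationResult:
    """Non-metric MDS by SMACOF majorisation with monotone regression.

    Runs ``restarts`` random initialisations and keeps the configuration
    with the lowest Kruskal stress-1, reported in percent.
    """
    vals = np.asarray(d.values, dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("non-finite distances")
    if len(d.labels) < dims + 1:
        raise ValueError("need at least dims+1 entities")
    # shift any negative estimates (possible for R_ST) to a valid dissimilarity
    off = vals[~np.eye(len(vals), dtype=bool)]
    if off.size and off.min() < 0:
        vals = vals - off.min()
        np.fill_diagonal(vals, 0.0)
    rs = int(np.random.default_rng(seed).integers(2 ** 31))
    try:   # sklearn >= 1.9 naming
        mds = MDS(n_components=dims, metric_mds=False, metric="precomputed",
                  n_init=restarts, max_iter=max_iter, eps=1e-9,
                  init="random", random_state=rs)
    except TypeError:
        mds = MDS(n_components=dims, metric=False,
                  dissimilarity="precomputed", n_init=restarts,
                  max_iter=max_iter, eps=1e-9, random_state=rs,
                  normalized_stress=True)
    coords = mds.fit_transform(vals)
    stress = kruskal_stress1(vals, coords)
    return OrdinationResult(list(d.labels), coords,
                            stress_percent=100.0 * stress)
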