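"""Synthetic Y-STR datasets with known demographic history.

A :class:`PopulationTree` describes demes related by dated splits (a rooted
binary topology with split times in years, per-deme haploid effective sizes
and optional exponential growth). ``simulate_dataset`` draws one genealogy
for the completely linked Y chromosome under the structured coalescent
(via msprime), then evolves 17 STR loci along it under the single-step
stepwise mutation model: the mutation count on a branch of length ``t``
generations is Poisson(mu * t) and every mutation shifts the repeat count by
+/-1 with equal probability. Haplogroup labels are inherited from founder
lineages — the immediate child lineages of the genealogy root.

``apply_scenario`` implements three label perturbations used to probe the
sensitivity of split-time inference to unmodelled admixture: randomly
splitting one deme into two pseudo-demes, symmetrically swapping a fraction
of chromosomes between two demes, and replacing a fraction of two demes with
in-migrants drawn from a third.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import msprime
import numpy as np

from .datamodel import DEFAULT_LOCI, HaplotypeRecord, HaplotypeTable

__all__ = [
    "PopulationTree",
    "SimulationConfig",
    "ScenarioConfig",
    "simulate_dataset",
    "apply_scenario",
]

DEFAULT_MU = 6.9e-4          # per locus per generation
DEFAULT_FOUNDER_ALLELE = 25


@dataclass(frozen=True)
class PopulationTree:
    """Dated rooted binary population topology.

    *topology* is nested tuples: a leaf is a deme label (str); an internal
    node is ``(left, right, split_time_years)``. Split times must decrease
    from root to leaves. *ne* maps each deme label (and optionally the
    ancestral nodes ``"anc0"``, ``"anc1"``, ... numbered in pre-order) to a
    haploid effective size; *growth* maps deme labels to per-generation
    exponential growth rates (default 0).
    """

    topology: tuple | str
    ne: Mapping[str, float]
    growth: Mapping[str, float] = field(default_factory=dict)
    generation_years: float = 25.0
    default_ne: float = 1000.0

    def __post_init__(self):
        for label, n in self.ne.items():
            if n <= 0:
                raise ValueError(f"N_e for {label} must be positive")
        seen = set()
        for leaf in self.leaves():
            if leaf in seen:
                raise ValueError(f"duplicate deme label {leaf!r}")
            seen.add(leaf)
        self._check_times(self.topology, float("inf"))

    def _check_times(self, node, parent_time):
        if isinstance(node, str):
            return
        left, right, t = node
        if not t < parent_time:
            raise ValueError("child split time must be below its parent's")
        self._check_times(left, t)
        self._check_times(right, t)

    def leaves(self) -> list[str]:
        out: list[str] = []

        def walk(node):
            if isinstance(node, str):
                out.append(node)
            else:
                walk(node[0]); walk(node[1])
        walk(self.topology)
        return out

    def size_of(self, label: str) -> float:
        return float(self.ne.get(label, self.default_ne))

    def to_newick(self) -> str:
        """Newick with branch lengths in years."""
        def walk(node, parent_time):
            if isinstance(node, str):
                bl = "" if parent_time is None else f":{parent_time:g}"
                return f"{node}{bl}"
            left, right, t = node
            inner = f"({walk(left, t)},{walk(right, t)})"
            bl = "" if parent_time is None else f":{parent_time - t:g}"
            return inner + bl
        return walk(self.topology, None) + ";"

    @classmethod
    def from_newick(cls, newick: str, ne: Mapping[str, float],
                    growth: Mapping[str, float] | None = None,
                    generation_years: float = 25.0,
                    default_ne: float = 1000.0) -> "PopulationTree":
        """Parse a rooted binary Newick string with branch lengths in years.

        Sizes and growth rates arrive as a sidecar mapping (they are not
        representable in plain Newick).
        """
        import dendropy
        tree = dendropy.Tree.get(data=newick, schema="newick")
        root = tree.seed_node

        def depth_below(node):
            if node.is_leaf():
                return 0.0
            return max(depth_below(c) + (c.edge.length or 0.0)
                       for c in node.child_nodes())

        def walk(node):
            if node.is_leaf():
                return node.taxon.label
            kids = node.child_nodes()
            if len(kids) != 2:
                raise ValueError("population tree must be binary")
            return (walk(kids[0]), walk(kids[1]), depth_below(node))

        return cls(walk(root), ne=ne, growth=growth or {},
                   generation_years=generation_years, default_ne=default_ne)

    def demography(self) -> msprime.Demography:
        """msprime demography with times converted to generations."""
        g = self.generation_years
        dem = msprime.Demography()
        for leaf in self.leaves():
            dem.add_population(
                name=_safe(leaf), initial_size=self.size_of(leaf),
                growth_rate=float(self.growth.get(leaf, 0.0)))
        counter = [0]
        splits = []

        def walk(node):
            if isinstance(node, str):
                return _safe(node)
            name = f"anc{counter[0]}"; counter[0] += 1
            left, right, t = node
            dem.add_population(name=name, initial_size=self.size_of(name))
            splits.append((t / g, [walk(left), walk(right)], name))
            return name
        walk(self.topology)
        for t_gen, derived, anc in sorted(splits, key=lambda s: s[0]):
            dem.add_population_split(time=t_gen, derived=derived, ancestral=anc)
        dem.sort_events()
        return dem


def _safe(label: str) -> str:
    return label.replace(" ", "_")


@dataclass(frozen=True)
class SimulationConfig:
    samples_per_deme: Mapping[str, int] | int
    n_loci: int = 17
    mu: float = DEFAULT_MU
    founder_haplogroups: tuple[str, ...] = ("HG-A",)
    founder_allele: int = DEFAULT_FOUNDER_ALLELE
    seed: int | None = None

    def __post_init__(self):
        if not (0.0 <= self.mu < 0.1):
            raise ValueError("mu must lie in [0, 0.1)")
        if isinstance(self.samples_per_deme, int):
            if self.samples_per_deme < 2:
                raise ValueError("need at least 2 samples per deme")
        else:
            for d, n in self.samples_per_deme.items():
                if n < 2:
                    raise ValueError(f"deme {d}: need at least 2 samples")

    def samples_for(self, demes: Sequence[str]) -> dict[str, int]:
        if isinstance(self.samples_per_deme, int):
            return {d: self.samples_per_deme for d in demes}
        return dict(self.samples_per_deme)


def simulate_dataset(tree: PopulationTree, cfg: SimulationConfig
                     ) -> HaplotypeTable:
    """Simulate a haplotype table under the tree (bit-reproducible by seed)."""
    demes = tree.leaves()
    if not demes:
        raise ValueError("population tree has no demes")
    samples = cfg.samples_for(demes)
    rng = np.random.default_rng(cfg.seed)
    anc_seed = int(rng.integers(1, 2 ** 31))
    ts = msprime.sim_ancestry(
        samples={_safe(d): samples[d] for d in demes},
        demography=tree.demography(), ploidy=1, sequence_length=1,
        random_seed=anc_seed)
    tsk = ts.first()
    alleles, hg_of_sample = _evolve_strs(tsk, ts, cfg, rng)
    id_to_deme = {}
    for pop in ts.populations():
        id_to_deme[pop.id] = pop.metadata.get("name", str(pop.id))
    safe_to_orig = {_safe(d): d for d in demes}
    records = []
    loci = tuple(DEFAULT_LOCI[: cfg.n_loci]) if cfg.n_loci <= len(DEFAULT_LOCI) \
        else tuple(f"L{i+1}" for i in range(cfg.n_loci))
    for k, sample in enumerate(ts.samples()):
        deme = safe_to_orig[id_to_deme[ts.node(sample).population]]
        records.append(HaplotypeRecord(
            sample_id=f"S{k:04d}", population=deme,
            haplogroup=hg_of_sample[sample],
            str_alleles=tuple(int(a) for a in alleles[sample])))
    return HaplotypeTable(records, loci=loci)


def _evolve_strs(tree, ts, cfg: SimulationConfig, rng: np.random.Generator):
    """Random SMM walks for every locus down one tskit tree (times in
    generations already — msprime works in generations)."""
    n_nodes = ts.num_nodes
    alleles = np.zeros((n_nodes, cfg.n_loci), dtype=np.int64)
    root = tree.root
    alleles[root] = cfg.founder_allele
    # founder lineages: children of the genealogy root
    founders = list(tree.children(root))
    hg_of_node = {}
    for i, f in enumerate(founders):
        hg_of_node[f] = cfg.founder_haplogroups[i % len(cfg.founder_haplogroups)]
    order = [root] + [v for v in tree.nodes(order="preorder") if v != root]
    for v in order:
        if v == root:
            continue
        parent = tree.parent(v)
        branch = tree.time(parent) - tree.time(v)
        if cfg.mu > 0 and branch > 0:
            n_mut = rng.poisson(cfg.mu * branch, size=cfg.n_loci)
            steps = np.array([
                rng.integers(0, 2, size=m).sum() * 2 - m if m else 0
                for m in n_mut])
        else:
            steps = np.zeros(cfg.n_loci, dtype=np.int64)
        alleles[v] = alleles[parent] + steps
        if v not in hg_of_node:
            hg_of_node[v] = hg_of_node.get(parent,
                                           cfg.founder_haplogroups[0])
    hg_of_sample = {s: hg_of_node.get(s, cfg.founder_haplogroups[0])
                    for s in ts.samples()}
    return alleles, hg_of_sample


# ---------------------------------------------------------------------------
# admixture perturbation scenarios

@dataclass(frozen=True)
class ScenarioConfig:
    kind: str                     # random_split | symmetric_mixing | in_migration
    target_demes: tuple[str, ...]
    mixing_fraction: float | None = None
    source_deme: str | None = None
    seed: int | None = None

    def __post_init__(self):
        kinds = {"random_split", "symmetric_mixing", "in_migration"}
        if self.kind not in kinds:
            raise ValueError(f"scenario kind must be one of {sorted(kinds)}")
        if self.kind != "random_split":
            m = self.mixing_fraction
            if m is None or not (0.0 <= m <= 1.0):
                raise ValueError("mixing_fraction in [0, 1] required")
        if self.kind == "in_migration" and not self.source_deme:
            raise ValueError("in_migration requires a source deme")


def apply_scenario(t: HaplotypeTable, s: ScenarioConfig) -> HaplotypeTable:
    """Perturb population labels per the scenario; see module docstring."""
    import warnings

    census = t.census
    for d in s.target_demes:
        if d not in census:
            raise ValueError(f"deme {d!r} not present in table")
    rng = np.random.default_rng(s.seed)
    records = list(t.records)

    def idx_of(deme):
        return [i for i, r in enumerate(records) if r.population == deme]

    def relabel(i, new_pop):
        r = records[i]
        records[i] = HaplotypeRecord(r.sample_id, new_pop, r.haplogroup,
                                     r.str_alleles, r.group)

    if s.kind == "random_split":
        (deme,) = s.target_demes
        for i in idx_of(deme):
            side = "a" if rng.integers(0, 2) == 0 else "b"
            relabel(i, f"{deme}_{side}")
    elif s.kind == "symmetric_mixing":
        a, b = s.target_demes
        m = s.mixing_fraction
        if m > 0.5:
            warnings.warn("mixing fraction above 0.5 majority-swaps labels")
        ia, ib = idx_of(a), idx_of(b)
        ka = int(round(m * len(ia)))
        kb = int(round(m * len(ib)))
        swap_a = rng.choice(ia, size=ka, replace=False)
        swap_b = rng.choice(ib, size=kb, replace=False)
        for i in swap_a:
            relabel(i, b)
        for i in swap_b:
            relabel(i, a)
    else:  # in_migration
        src = idx_of(s.source_deme)
        if not src:
            raise ValueError(f"source deme {s.source_deme!r} not in table")
        ks = {d: int(round(s.mixing_fraction * len(idx_of(d))))
              for d in s.target_demes}
        k_total = sum(ks.values())
        # each source individual migrates at most once when possible, so a
        # single donor haplotype is not planted into two demes artificially
        if k_total <= len(src):
            draw = list(rng.choice(src, size=k_total, replace=False))
        else:
            warnings.warn("migrant demand exceeds source size; "
                          "drawing with replacement")
            draw = list(rng.choice(src, size=k_total, replace=True))
        for deme in s.target_demes:
            tgt = idx_of(deme)
            k = ks[deme]
            replace_at = rng.choice(tgt, size=k, replace=False)
            for dst_i in replace_at:
                donor = records[draw.pop()]
                records[dst_i] = HaplotypeRecord(
                    records[dst_i].sample_id, deme, donor.haplogroup,
                    donor.str_alleles, records[dst_i].group)
    return HaplotypeTable(records, loci=t.loci)
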