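import numpy as np
import pytest
from scipy.stats import kstest

import ystrat as y
from ystrat.structure import AmovaResult, kruskal_stress1

from conftest import make_table


def brute_force_amova(d2, pop_of_ind, group_of_pop):
    """Independent oracle: explicit double-loop sums of squared distances
    and the textbook variance-component formulas."""
    n = d2.shape[0]
    pops = sorted(set(pop_of_ind))
    groups = sorted(set(group_of_pop.values()))
    gr_of_ind = [group_of_pop[pop_of_ind[i]] for i in range(n)]

    def ssd(indices):
        s = 0.0
        for i in indices:
            for j in indices:
                s += d2[i, j]
        return s / (2 * len(indices))

    ssd_t = ssd(range(n))
    ssd_wp = sum(ssd([i for i in range(n) if pop_of_ind[i] == p])
                 for p in pops)
    ssd_wg = sum(ssd([i for i in range(n) if gr_of_ind[i] == g])
                 for g in groups)
    P, G = len(pops), len(groups)
    sizes = {p: sum(1 for x in pop_of_ind if x == p) for p in pops}
    ng = {g: sum(sizes[p] for p in pops if group_of_pop[p] == g)
          for g in groups}
    vc = ssd_wp / (n - P)
    s_np2_ng = sum(sum(sizes[p] ** 2 for p in pops if group_of_pop[p] == g)
                   / ng[g] for g in groups)
    s_np2 = sum(v ** 2 for v in sizes.values())
    s_ng2 = sum(v ** 2 for v in ng.values())
    n1 = (n - s_np2_ng) / (P - G)
    n2 = (s_np2_ng - s_np2 / n) / (G - 1)
    n3 = (n - s_ng2 / n) / (G - 1)
    vb = ((ssd_wg - ssd_wp) / (P - G) - vc) / n1
    va = ((ssd_t - ssd_wg) / (G - 1) - vc - n2 * vb) / n3
    return va, vb, vc


def table_with_haplogroups(assignments):
    """Per-individual table with haplogroup labels only (dummy alleles)."""
    records = []
    for k, (pop, hg) in enumerate(assignments):
        records.append(y.HaplotypeRecord(f"S{k}", pop, hg, (14,) * 17))
    return y.HaplotypeTable(records)


class TestAmova:
    def test_matches_brute_force_oracle_str_metric(self):
        rng = np.random.default_rng(7)
        alleles = rng.integers(12, 18, size=(24, 5))
        pops = ["p1"] * 6 + ["p2"] * 7 + ["p3"] * 5 + ["p4"] * 6
        t = make_table({
            p: [alleles[i] for i in range(24) if pops[i] == p]
            for p in ["p1", "p2", "p3", "p4"]}, n_loci=5)
        g = y.Grouping("g", {"p1": "G1", "p2": "G1", "p3": "G2", "p4": "G2"})
        res = y.amova(t, g)
        d2 = ((alleles[:, None, :] - alleles[None, :, :]) ** 2).sum(-1)
        va, vb, vc = brute_force_amova(
            d2, pops, {"p1": "G1", "p2": "G1", "p3": "G2", "p4": "G2"})
        assert res.va == pytest.approx(va, abs=1e-10)
        assert res.vb == pytest.approx(vb, abs=1e-10)
        assert res.vc == pytest.approx(vc, abs=1e-10)

    def test_count_mode_equals_expanded_individual_mode(self, fixture_counts,
                                                        mpg):
        res_counts = y.amova(fixture_counts, mpg)
        assignments = []
        for i, pop in enumerate(fixture_counts.populations):
            for j, hg in enumerate(fixture_counts.haplogroups):
                assignments += [(pop, hg)] * fixture_counts.counts[i, j]
        res_ind = y.amova(table_with_haplogroups(assignments), mpg,
                          metric="hg01")
        assert res_ind.fct == pytest.approx(res_counts.fct, abs=1e-12)
        assert res_ind.fsc == pytest.approx(res_counts.fsc, abs=1e-12)
        assert res_ind.fst == pytest.approx(res_counts.fst, abs=1e-12)

    def test_identical_populations_give_zero_when_clamped(self):
        """Identical count vectors: the unbiased estimator yields small
        negative among components (among MSD < within MSD), so the zero
        answer is recovered under clamping while the default reports the
        raw negative estimates."""
        m = y.CountMatrix(["a", "b", "c", "d"], ["x", "y"],
                          np.array([[5, 5]] * 4))
        g = y.Grouping("g", {"a": "G1", "b": "G1", "c": "G2", "d": "G2"})
        raw = y.amova(m, g)
        assert raw.va <= 0 and raw.vb <= 0
        res = y.amova(m, g, clamp=True)
        assert res.fct == pytest.approx(0.0, abs=1e-12)
        assert res.fsc == pytest.approx(0.0, abs=1e-12)
        assert res.fst == pytest.approx(0.0, abs=1e-12)

    def test_phi_ratios_recompute_from_components(self, fixture_counts, mpg):
        r = y.amova(fixture_counts, mpg)
        tot = r.va + r.vb + r.vc
        assert r.fct == pytest.approx(r.va / tot, abs=1e-12)
        assert r.fsc == pytest.approx(r.vb / (r.vb + r.vc), abs=1e-12)
        assert r.fst == pytest.approx((r.va + r.vb) / tot, abs=1e-12)

    def test_single_group_returns_only_fst(self, fixture_counts):
        g = y.Grouping("one", {p: "ALL" for p in fixture_counts.populations})
        r = y.amova(fixture_counts, g)
        assert r.fct is None and r.fsc is None
        assert 0 < r.fst < 1


class TestAmovaPermutations:
    def test_structured_toy_significant(self):
        m = y.CountMatrix(["a", "b", "c", "d"], ["x", "y"],
                          np.array([[20, 0], [19, 1], [0, 20], [1, 19]]))
        g = y.Grouping("g", {"a": "G1", "b": "G1", "c": "G2", "d": "G2"})
        p = y.amova_permutation_test(m, g, n_perm=999, seed=1)
        assert p["fct"] <= 0.05 or p["fst"] <= 0.05

    def test_exhaustive_enumeration_for_few_populations(self):
        # 3 populations in 2 groups: only 3 distinct assignments
        m = y.CountMatrix(["a", "b", "c"], ["x", "y"],
                          np.array([[9, 1], [8, 2], [1, 9]]))
        g = y.Grouping("g", {"a": "G1", "b": "G1", "c": "G2"})
        p = y.amova_permutation_test(m, g, n_perm=999, seed=1)
        assert p["fct"] == pytest.approx(1 / 3)

    def test_null_p_values_uniform_under_shuffled_labels(self):
        """Calibration: with exchangeable labels the permutation p-value is
        uniform; a KS test over repeated datasets must not reject."""
        rng = np.random.default_rng(3)
        pvals = []
        for _ in range(120):
            counts = rng.multinomial(12, [0.4, 0.3, 0.3], size=4)
            m = y.CountMatrix(["a", "b", "c", "d"], ["x", "y", "z"], counts)
            g = y.Grouping("g", {"a": "G1", "b": "G1",
                                 "c": "G2", "d": "G2"})
            pvals.append(y.amova_permutation_test(
                m, g, n_perm=99, seed=int(rng.integers(2**31)))["fst"])
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestRst:
    def test_no_differentiation_near_zero(self):
        tree = y.PopulationTree(("A", "B", 1e-6),
                                ne={"A": 1000, "B": 1000, "anc0": 1000})
        t = y.simulate_dataset(
            tree, y.SimulationConfig(samples_per_deme=200, seed=9))
        d = y.rst_distance_matrix(t)
        assert abs(d.values[0, 1]) < 0.02

    def test_monomorphic_demes_one_step_apart(self):
        t = make_table({"A": [[14] * 17] * 5,
                        "B": [[14] * 16 + [15]] * 5})
        d = y.rst_distance_matrix(t)
        assert d.values[0, 1] == pytest.approx(1.0)

    def test_six_individual_toy_matches_oracle(self):
        alleles = np.array([[14, 10], [15, 10], [14, 11],
                            [18, 13], [19, 13], [18, 14]])
        t = make_table({"A": alleles[:3], "B": alleles[3:]}, n_loci=2)
        d = y.rst_distance_matrix(t)
        d2 = ((alleles[:, None, :] - alleles[None, :, :]) ** 2).sum(-1)
        # two-population, one-level design: Fst from the brute-force SSDs
        def ssd(idx):
            return sum(d2[i, j] for i in idx for j in idx) / (2 * len(idx))
        ssd_t = ssd(range(6))
        ssd_w = ssd([0, 1, 2]) + ssd([3, 4, 5])
        vc = ssd_w / 4
        n_c = (6 - (9 + 9) / 6) / 1
        va = ((ssd_t - ssd_w) / 1 - vc) / n_c
        assert d.values[0, 1] == pytest.approx(va / (va + vc), abs=1e-12)

    def test_invariant_to_constant_allele_shift(self):
        rng = np.random.default_rng(0)
        a = rng.integers(10, 16, (6, 3))
        t1 = make_table({"A": a[:3], "B": a[3:]}, n_loci=3)
        shifted = a.copy()
        shifted[:, 1] += 7
        t2 = make_table({"A": shifted[:3], "B": shifted[3:]}, n_loci=3)
        r1 = y.rst_distance_matrix(t1).values[0, 1]
        r2 = y.rst_distance_matrix(t2).values[0, 1]
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_singleton_population_named(self):
        t = make_table({"A": [[14] * 17] * 3, "B": [[15] * 17]})
        with pytest.raises(ValueError, match="B"):
            y.rst_distance_matrix(t)


class TestBootstrap:
    def test_reproducible_given_seed(self, fixture_counts, mpg):
        a = y.bootstrap_fct(fixture_counts, mpg, n_replicates=120, seed=5)
        b = y.bootstrap_fct(fixture_counts, mpg, n_replicates=120, seed=5)
        assert (a.median, a.lower, a.upper) == (b.median, b.lower, b.upper)

    def test_median_close_to_point_estimate(self):
        counts = np.array([[120, 0, 8], [112, 8, 8],
                           [8, 120, 0], [0, 112, 16]])
        m = y.CountMatrix(["a", "b", "c", "d"], ["x", "y", "z"], counts)
        g = y.Grouping("g", {"a": "G1", "b": "G1", "c": "G2", "d": "G2"})
        point = y.amova(m, g).fct
        ci = y.bootstrap_fct(m, g, n_replicates=500, seed=11)
        assert abs(ci.median - point) < 0.01

    def test_single_population_rejected(self):
        m = y.CountMatrix(["a"], ["x", "y"], np.array([[5, 5]]))
        g = y.Grouping("g", {"a": "G1"})
        with pytest.raises(ValueError):
            y.bootstrap_fct(m, g, n_replicates=100, seed=0)


class TestCompareGroupings:
    def _ci(self, lo, med, hi, fp="f"):
        from ystrat.structure import BootstrapCI
        return BootstrapCI("fct", med, lo, hi, 500, 0, fp)

    def test_disjoint_intervals_ordered(self):
        assert y.compare_groupings(self._ci(0.052, 0.064, 0.078),
                                   self._ci(0.01, 0.02, 0.04)) == "a>b"

    def test_identical_intervals_overlap(self):
        assert y.compare_groupings(self._ci(0.1, 0.2, 0.3),
                                   self._ci(0.1, 0.2, 0.3)) == "overlap"

    def test_touching_bounds_count_as_overlap(self):
        assert y.compare_groupings(self._ci(0.04, 0.05, 0.06),
                                   self._ci(0.02, 0.03, 0.04)) == "overlap"

    def test_mismatched_data_rejected(self):
        with pytest.raises(ValueError):
            y.compare_groupings(self._ci(0, 1, 2, "x"), self._ci(0, 1, 2, "y"))


class TestPca:
    def test_rank_one_matrix_single_component(self):
        x = np.outer([1, 2, 3, 4.0], [1, 0, 1.0])
        res = y.pca(x)
        assert res.variance_fractions[0] == pytest.approx(1.0)

    def test_fractions_sum_to_one(self, fixture_counts):
        res = y.pca(fixture_counts.frequencies())
        assert res.variance_fractions.sum() == pytest.approx(1.0)

    def test_scale_invariant_fractions(self, fixture_counts):
        f = fixture_counts.frequencies()
        a = y.pca(f).variance_fractions
        b = y.pca(f / 100.0).variance_fractions
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            y.pca(np.ones((5, 3)))

    def test_individual_unit_equals_indicator_expansion(self, fixture_counts):
        res = y.pca(fixture_counts, unit="individual")
        expanded = np.repeat(np.eye(21), fixture_counts.counts.sum(0), axis=0)
        sv = np.linalg.svd(expanded - expanded.mean(0), compute_uv=False)
        frac = sv ** 2 / (sv ** 2).sum()
        np.testing.assert_allclose(res.variance_fractions[:5], frac[:5],
                                   atol=1e-9)


class TestNmds:
    def test_perfect_euclidean_embedding(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(9, 2))
        dd = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        d = y.DistanceMatrix([f"e{i}" for i in range(9)], dd)
        res = y.nmds(d, dims=2, restarts=8, seed=0)
        assert res.stress_percent < 0.5

    def test_equal_distances_do_not_crash(self):
        n = 5
        dd = np.ones((n, n)) - np.eye(n)
        d = y.DistanceMatrix([f"e{i}" for i in range(n)], dd)
        res = y.nmds(d, dims=2, restarts=4, seed=0)
        assert res.stress_percent >= 0.0

    def test_stress_non_increasing_in_dims(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(10, 3))
        dd = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        d = y.DistanceMatrix([f"e{i}" for i in range(10)], dd)
        stresses = [y.nmds(d, dims=k, restarts=6, seed=1).stress_percent
                    for k in (1, 2, 3)]
        assert stresses[0] >= stresses[1] - 0.3
        assert stresses[1] >= stresses[2] - 0.3
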