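import math

import numpy as np
import pytest
from scipy.stats import poisson

import ystrat as y
from ystrat._smm import prune_loglik, smm_step_probabilities, \
    smm_transition_matrix
from ystrat.coalescent import (ChainConfig, PosteriorSummary, PriorSet,
                               _initial_state, _Schedule, _State, modal_tree,
                               sample_posterior, tmrca_cluster)


def branch_probability_oracle(delta, theta, max_mut=40):
    """P(net repeat change = delta) by explicit summation over mutation
    paths: m total mutations, u up-steps with u - (m - u) = delta."""
    p = 0.0
    for m in range(abs(delta), max_mut + 1):
        if (m - delta) % 2:
            continue
        u = (m + delta) // 2
        p += poisson.pmf(m, theta) * math.comb(m, u) / 2 ** m
    return p


class TestSmmLikelihood:
    @pytest.mark.parametrize("theta", [0.0, 0.01, 0.5, 3.0])
    def test_step_probabilities_match_path_enumeration(self, theta):
        probs = smm_step_probabilities(theta, 6)
        for k in range(7):
            assert probs[k] == pytest.approx(
                branch_probability_oracle(k, theta, max_mut=60), abs=1e-12)

    def test_transition_matrix_rows_sum_below_one(self):
        m = smm_transition_matrix(0.8, 30)
        # band truncation loses only far-tail mass
        assert np.all(m.sum(axis=1) <= 1.0 + 1e-12)
        assert m.sum(axis=1)[15] == pytest.approx(1.0, abs=1e-10)

    def test_pruning_matches_brute_force_on_four_tips(self):
        """Sum over all internal allele states on a fixed 4-tip genealogy
        equals the pruning likelihood to 1e-8."""
        parent = np.array([4, 4, 5, 6, 5, 6, -1])
        time = np.array([0, 0, 0, 0, 50.0, 120.0, 300.0])
        mu = 2e-3
        W = 9
        tips = np.array([0, 1, 2, 3])
        tip_states = np.array([[3], [4], [4], [5]])
        total = 0.0
        for s4 in range(W):
            for s5 in range(W):
                for s6 in range(W):
                    states = {0: 3, 1: 4, 2: 4, 3: 5, 4: s4, 5: s5, 6: s6}
                    p = 1.0 / W
                    for v in range(6):
                        pr = parent[v]
                        p *= branch_probability_oracle(
                            states[v] - states[pr], mu * (time[pr] - time[v]))
                    total += p
        got = prune_loglik(parent, time, tips, tip_states, mu, W)
        assert got == pytest.approx(math.log(total), abs=1e-8)


def build_two_deme_state(seed=0, n_per=6, tau_gen=200.0):
    tree = y.PopulationTree(("A", "B", tau_gen * 25.0),
                            ne={"A": 800, "B": 800, "anc0": 800})
    tab = y.simulate_dataset(tree, y.SimulationConfig(n_per, seed=seed))
    sub = tab.subset(complete_only=True)
    demes = sub.populations
    idx = {d: i for i, d in enumerate(demes)}
    tip_deme = np.array([idx[r.population] for r in sub.records])
    rng = np.random.default_rng(seed)
    return _initial_state(sub.alleles(), tip_deme, demes, PriorSet(), rng)


class TestStateInternals:
    def test_incremental_likelihood_equals_pruning(self):
        st = build_two_deme_state()
        full = prune_loglik(st.parent, st.time, np.arange(st.n),
                            st.tip_states, st.mu, st.W)
        assert st.loglik() == pytest.approx(full, rel=1e-10)

    def test_coalescent_prior_closed_form(self):
        """Hand-computable case: one coalescence per deme below the split
        and the root in the ancestral deme."""
        parent = np.array([4, 4, 5, 5, 6, 6, -1])
        c1 = np.array([-1, -1, -1, -1, 0, 2, 4])
        c2 = np.array([-1, -1, -1, -1, 1, 3, 5])
        time = np.array([0, 0, 0, 0, 30.0, 60.0, 150.0])
        sch = _Schedule([(100.0, 1, 2)], 2)
        sizes = {1: 500.0, 2: 800.0, 3: 1200.0}
        alleles = np.array([[10], [10], [11], [11]])
        st = _State(alleles, np.array([0, 0, 1, 1]), 2, sch, sizes, 1e-3,
                    parent, c1, c2, time)
        expected = (-30 / 500 - math.log(500)
                    - 60 / 800 - math.log(800)
                    - 50 / 1200 - math.log(1200))
        assert st.coal_logprior() == pytest.approx(expected, rel=1e-12)

    def test_prior_invariant_to_deme_relabeling(self):
        st = build_two_deme_state(seed=3)
        mirrored = _State(
            st.tip_states + st.offset[None, :], 1 - st.tip_deme, st.k,
            _Schedule([(t, 2, 1) for t, a, b in st.schedule.events], 2),
            {1: st.sizes[2], 2: st.sizes[1], 3: st.sizes[3]}, st.mu,
            st.parent, st.c1, st.c2, st.time)
        assert mirrored.coal_logprior() == pytest.approx(
            st.coal_logprior(), rel=1e-12)
        assert mirrored.loglik() == pytest.approx(st.loglik(), rel=1e-12)

    def test_validity_respects_split_time(self):
        st = build_two_deme_state(seed=1)
        assert st.valid()
        # pushing the split above every cross-deme node breaks validity
        cross = st.time[st.n:][st.mask[st.n:] == 3]
        st.schedule = _Schedule([(float(cross.max()) + 1.0, 1, 2)], 2)
        assert not st.valid()


class TestSampler:
    def test_chain_internally_consistent_and_reproducible(self,
                                                          two_deme_table):
        cc = ChainConfig(n_samples=1500, burn_in=300, thinning=10, seed=5)
        a = sample_posterior(two_deme_table, PriorSet(), cc, check_every=500)
        b = sample_posterior(two_deme_table, PriorSet(), cc)
        assert a.root_split_years == b.root_split_years
        assert a.split_times.keys() == b.split_times.keys()

    def test_split_time_recovery_ci_covers_truth(self):
        """Reduced-scale parameter recovery: the 95% credible interval of
        the root split covers the simulated 10 Kya truth."""
        tree = y.PopulationTree(("A", "B", 10000.0),
                                ne={"A": 2000, "B": 2000, "anc0": 2000})
        tab = y.simulate_dataset(tree, y.SimulationConfig(20, seed=6))
        res = sample_posterior(tab, PriorSet(),
                               ChainConfig(n_samples=20000, burn_in=6000,
                                           thinning=20, seed=2))
        assert res.root_split_years["lower"] <= 10000.0 <= \
            res.root_split_years["upper"]

    def test_two_deme_topology_frequency_is_one(self, two_deme_table):
        res = sample_posterior(two_deme_table, PriorSet(),
                               ChainConfig(n_samples=1200, burn_in=300,
                                           thinning=10, seed=1))
        assert res.topology_frequencies == {"(A,B)": 1.0}

    def test_rejects_too_few_demes_or_records(self, panmictic_table):
        with pytest.raises(ValueError, match="at least 2"):
            sample_posterior(panmictic_table)


class TestModalTree:
    def _summary(self, freqs, ll):
        return PosteriorSummary(
            demes=["A", "B", "C"], topology_frequencies=freqs,
            split_times={"root": {"median": 1.0, "lower": 0.5, "upper": 2.0}},
            mu={}, ne={}, ess_root_split=100.0, acceptance={},
            converged=True, mean_loglik_by_topology=ll)

    def test_single_topology(self):
        res = modal_tree(self._summary({"((A,B),C)": 1.0},
                                       {"((A,B),C)": -10.0}))
        assert res["topology"] == "((A,B),C)"
        assert not res["tie_broken_by_likelihood"]

    def test_tie_broken_by_mean_likelihood(self):
        res = modal_tree(self._summary(
            {"((A,B),C)": 0.5, "((A,C),B)": 0.5},
            {"((A,B),C)": -20.0, "((A,C),B)": -10.0}))
        assert res["topology"] == "((A,C),B)"
        assert res["tie_broken_by_likelihood"]


class TestTmrca:
    def test_identical_haplotypes_age_zero(self):
        assert tmrca_cluster(np.full((4, 17), 14)) == 0.0

    def test_star_closed_form(self):
        center = np.full(17, 14)
        haps = np.tile(center, (3, 1))
        for i, locus in enumerate((0, 5, 9)):
            haps[i, locus] += 1
        age = tmrca_cluster(haps, mode="asd")
        assert age == pytest.approx((1 / 17) / 6.9e-4 * 25, rel=1e-9)

    def test_linearity_in_step_distance(self):
        center = np.full(17, 20)
        haps = np.tile(center, (3, 1))
        haps[:, 0] += 2
        one = np.tile(center, (3, 1))
        one[:, 0] += 1
        assert tmrca_cluster(haps, mode="rho", ancestral=center) == \
            pytest.approx(2 * tmrca_cluster(one, mode="rho",
                                            ancestral=center))

    def test_requires_three_haplotypes(self):
        with pytest.raises(ValueError):
            tmrca_cluster(np.full((2, 17), 14))


class TestScenarioRunner:
    def test_grid_report_structure(self):
        """Smoke run at micro scale: one perturbation plus the reference,
        with seeds logged per row."""
        tree = y.PopulationTree(("A", "B", 8000.0),
                                ne={"A": 800, "B": 800, "anc0": 800})
        rows = y.run_admixture_scenarios(
            tree, y.SimulationConfig(samples_per_deme=8, seed=3),
            [y.ScenarioConfig(kind="symmetric_mixing",
                              target_demes=("A", "B"),
                              mixing_fraction=0.25, seed=5)],
            PriorSet(), ChainConfig(n_samples=1500, burn_in=400,
                                    thinning=10, seed=9))
        assert [r["scenario"] for r in rows] == ["unperturbed",
                                                 "symmetric_mixing"]
        assert rows[0]["relative_change"] == 0.0
        for r in rows:
            assert "chain_seed" in r and "median_split_years" in r


class TestThreeDemeTopology:
    def test_modal_topology_recovers_strong_structure(self):
        """Three demes with strong simulated structure ((A,B),C): the modal
        ranked topology matches the truth at high posterior frequency."""
        tree = y.PopulationTree((("A", "B", 5000.0), "C", 25000.0),
                                ne={"A": 500, "B": 500, "C": 500,
                                    "anc0": 500, "anc1": 500})
        tab = y.simulate_dataset(tree, y.SimulationConfig(
            samples_per_deme=12, seed=13))
        res = sample_posterior(tab, PriorSet(), ChainConfig(
            n_samples=20000, burn_in=6000, thinning=20, seed=4))
        mt = modal_tree(res)
        assert mt["topology"] == "((A,B),C)"
        assert mt["frequency"] >= 0.8
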