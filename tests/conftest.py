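import numpy as np
import pytest

import ystrat as y


@pytest.fixture(scope="session")
def fixture_counts():
    return y.table2_fixture()


@pytest.fixture(scope="session")
def mpg():
    return y.mpg_grouping()


@pytest.fixture(scope="session")
def tribe_caste():
    return y.tribe_caste_grouping()


def make_table(alleles_by_pop, haplogroup="HG-A", n_loci=None):
    """Build a HaplotypeTable from {population: [allele tuples]}."""
    records = []
    k = 0
    for pop, rows in alleles_by_pop.items():
        for row in rows:
            records.append(y.HaplotypeRecord(
                sample_id=f"S{k:03d}", population=pop,
                haplogroup=haplogroup, str_alleles=tuple(row)))
            k += 1
    n_loci = n_loci or len(next(iter(alleles_by_pop.values()))[0])
    loci = tuple(y.DEFAULT_LOCI[:n_loci]) if n_loci <= 17 else \
        tuple(f"L{i}" for i in range(n_loci))
    return y.HaplotypeTable(records, loci=loci)


@pytest.fixture(scope="session")
def two_deme_table():
    """Two demes split 10 Kya, moderate drift — shared across tests."""
    tree = y.PopulationTree(("A", "B", 10000.0),
                            ne={"A": 1000, "B": 1000, "anc0": 1000})
    return y.simulate_dataset(
        tree, y.SimulationConfig(samples_per_deme=20, seed=42))


@pytest.fixture(scope="session")
def panmictic_table():
    tree = y.PopulationTree("A", ne={"A": 2000.0})
    return y.simulate_dataset(
        tree, y.SimulationConfig(samples_per_deme=60, seed=11))
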