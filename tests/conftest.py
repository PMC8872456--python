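import numpy as np
import pytest

from sympop.genotypes import GenotypeTable, allele_frequencies
from sympop.simulate import make_radiation_fixture


@pytest.fixture(scope="session")
def radiation():
    """Whole-study synthetic dataset (33 populations, 6 taxa, 19 loci)."""
    return make_radiation_fixture(seed=1)


@pytest.fixture(scope="session")
def radiation_freqs(radiation):
    fr = allele_frequencies(radiation.table, grouping="population")
    fr.validate()
    return fr


@pytest.fixture(scope="session")
def taxon_of(radiation):
    return {m.population: m.taxon for m in radiation.table.populations}


def hwe_table(n: int, loci: int, seed: int, p: float = 0.5) -> GenotypeTable:
    """Random-mating diploid population: biallelic loci at frequency p."""
    rng = np.random.default_rng(seed)
    draws = rng.random((n, loci, 2)) < p
    calls = np.where(draws, 100, 102)
    return GenotypeTable(
        individual_ids=[f"i{k}" for k in range(n)],
        population_ids=["pop1"] * n,
        loci=[f"L{j}" for j in range(loci)],
        calls=calls,
    )
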