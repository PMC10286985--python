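import numpy as np
import pytest

from lunaqtl import qtlscan, synthdata


@pytest.fixture(scope="session")
def bc_sim():
    """Backcross with one recessive locus on chr2 at 55 cM, n=150."""
    return synthdata.simulate_cross(
        synthdata.ArchitectureConfig(loci=[synthdata.Locus("chr2", 55.0)]),
        "BC",
        150,
        seed=424242,
        with_emergence=False,
    )


@pytest.fixture(scope="session")
def bc_grid(bc_sim):
    return qtlscan.genotype_probabilities(bc_sim.matrix, step_cM=None)


@pytest.fixture(scope="session")
def f2_sim():
    """Intercross with the same architecture plus a sex locus on chr1."""
    return synthdata.simulate_cross(
        synthdata.ArchitectureConfig(loci=[synthdata.Locus("chr2", 55.0)]),
        "F2",
        150,
        seed=515151,
        with_emergence=False,
        sex_locus=("chr1", 40.0),
    )


@pytest.fixture(scope="session")
def f2_grid(f2_sim):
    return qtlscan.genotype_probabilities(f2_sim.matrix, step_cM=None)


@pytest.fixture(scope="session")
def bc_phenotype(bc_sim):
    rng = np.random.default_rng(7)
    return bc_sim.true_insensitive.astype(float) + rng.normal(0, 0.5, len(bc_sim.true_insensitive))
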