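import numpy as np
import pytest

from magicpop import magicsim, mixedgwas, synthpop


@pytest.fixture(scope="session")
def panel():
    """Default 16-founder panel: 3 chromosomes x 2000 sites, 1 Morgan each."""
    return synthpop.gen_founder_panel(seed=1)


@pytest.fixture(scope="session")
def pop500(panel):
    """500 RILs bred through independent 16-way funnels on the panel's map."""
    return magicsim.simulate_population(
        panel.chrom_lengths_morgans(), 500, n_selfing=7, seed=11
    )


@pytest.fixture(scope="session")
def G500(panel, pop500):
    return np.array(
        [magicsim.mosaic_to_genotypes(m, panel) for m in pop500], dtype=float
    )


@pytest.fixture(scope="session")
def pruned500(G500):
    kept, Gz = mixedgwas.standardize_and_prune(G500)
    return kept, Gz


@pytest.fixture(scope="session")
def grm500(pruned500):
    _, Gz = pruned500
    return mixedgwas.grm(Gz)
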