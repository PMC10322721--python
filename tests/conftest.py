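import numpy as np
import pandas as pd
import pytest

from cortexgrad import synthetic_data as syn


@pytest.fixture(scope="session")
def small_cortex():
    """8 areas on a small sphere; fastest fixture."""
    return syn.generate_toy_cortex(8, 2, seed=1)


@pytest.fixture(scope="session")
def cortex20():
    """20 areas, 642 vertices."""
    return syn.generate_toy_cortex(20, 3, seed=1)


@pytest.fixture(scope="session")
def cortex60():
    """60 areas, 2562 vertices; used for planted-gradient recovery."""
    return syn.generate_toy_cortex(60, 4, seed=1)


@pytest.fixture(scope="session")
def cortex109():
    """Study-sized parcellation (109 areas) for spatial statistics."""
    return syn.generate_toy_cortex(109, 4, seed=1)


@pytest.fixture(scope="session")
def planted60(cortex60):
    """Ground truth + matrices at the study noise level on 60 areas."""
    truth = syn.make_ground_truth(cortex60, noise_sd=0.2, seed=3)
    per, raw = syn.generate_receptor_matrix(cortex60, truth)
    return truth, per, raw


def make_sampleset(cortex, seed=11, coord_noise_sd=0.5, call_rate=0.9, **kw):
    gene_maps = syn.planted_gene_maps(cortex, 20, 15.0, seed=seed)
    sset = syn.generate_sample_set(cortex, 6, 100, 40, 20, gene_maps,
                                   call_rate=call_rate,
                                   coord_noise_sd=coord_noise_sd, seed=seed, **kw)
    return gene_maps, sset


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
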