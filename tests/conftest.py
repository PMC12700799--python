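import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from mirswitch.core import Assay, CountMatrix, Genotype, SampleMeta
from mirswitch.simulate import SimulationParams, generate_catalog, hairpin_latents


@pytest.fixture(scope="session")
def small_catalog():
    return generate_catalog(20, seed=7)


@pytest.fixture(scope="session")
def catalog200():
    return generate_catalog(200, seed=2)


@pytest.fixture(scope="session")
def params2():
    return SimulationParams(seed=2)


@pytest.fixture(scope="session")
def latents200(catalog200, params2):
    return hairpin_latents(catalog200, params2)


def make_matrix(values: dict, genotype=Genotype.WT, assay=Assay.total, spikes=None):
    """Tiny CountMatrix helper: values is {sample_id: {species: count}}."""
    data = pd.DataFrame(values).fillna(0)
    samples = {
        sid: SampleMeta(sid, genotype, assay, i + 1, spikes.get(sid, {}) if spikes else {})
        for i, sid in enumerate(data.columns)
    }
    return CountMatrix(data, samples)
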