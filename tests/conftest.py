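import numpy as np
import pytest
from hypothesis import settings

import decade_enm as de

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

UNIT = (0.0, 0.0, 1.0, 1.0)


@pytest.fixture(scope="session")
def landscape():
    return de.generate_landscape(UNIT, 100, 100, 4, seed=1)


@pytest.fixture(scope="session")
def truth(landscape):
    return de.define_virtual_species(
        landscape, np.array([2.0, -1.5, 1.0, -0.5]), 0.0
    )


@pytest.fixture(scope="session")
def centers():
    return de.place_research_centers(UNIT, 5, seed=7)


@pytest.fixture(scope="session")
def occurrences(truth, centers):
    plan = de.SamplingPlan(bias_strength=2.0, seed=3)
    return de.sample_occurrences(truth, centers, plan)


@pytest.fixture(scope="session")
def score_stack(landscape):
    scores, _ = de.pca_transform(landscape.raster_stack)
    return scores


@pytest.fixture(scope="session")
def study_bundle(truth, centers, occurrences, landscape):
    """One full cumulative-window run at study scale, shared across tests."""
    cfg = de.RunConfig(
        occurrences="", rasters=[], centers="", seed=11, write_rasters=False
    )
    return de.run_from_stack(landscape.raster_stack, occurrences, centers, cfg)
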