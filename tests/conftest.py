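import numpy as np
import pytest

from retrohtt import pipeline, simulate


@pytest.fixture(scope="session")
def query_model():
    return simulate.make_query_model("Ty4L", ltr_len=200, internal_len=2000, seed=0)


@pytest.fixture(scope="session")
def sister_model(query_model):
    return simulate.diverged_subfamily(query_model, "Tsu4L", divergence=0.25, seed=1)


@pytest.fixture
def rng():
    # function-scoped so every test sees the same deterministic stream
    # regardless of execution order
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def htt_run():
    """One htt_plus_recombinant end-to-end run shared across tests."""
    return pipeline.run_with_artifacts({"scenario": "htt_plus_recombinant", "seed": 1})


@pytest.fixture(scope="session")
def vertical_run():
    return pipeline.run_with_artifacts({"scenario": "vertical_only", "seed": 1})
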