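import numpy as np
import pytest

import raavmet as rm
from raavmet.synthetic import NoiseModel, generate

TOY_AB = {
    "name": "toy_ab",
    "species": [
        {"id": "A", "c0": 10.0},
        {"id": "B", "c0": 0.0},
    ],
    "observation_order": ["A", "B"],
    "parameters": {"km": {"Km_A": 1.0}, "vmax": {"vmax_AB": 0.5}},
    "flux_laws": [
        {"id": "AB", "forward": {"vmax": "vmax_AB", "terms": [["A", "Km_A"]]}}
    ],
    "reactions": [{"flux": "AB", "stoich": {"A": -1, "B": 1}}],
}

# linear chain A -> B -> C with two MM steps (4 kinetic parameters)
TOY_CHAIN = {
    "name": "toy_chain",
    "species": [
        {"id": "A", "c0": 10.0},
        {"id": "B", "c0": 0.5},
        {"id": "C", "c0": 0.0},
    ],
    "observation_order": ["A", "B", "C"],
    "parameters": {
        "km": {"Km_A": 1.0, "Km_B": 2.0},
        "vmax": {"vmax_AB": 0.5, "vmax_BC": 0.3},
    },
    "flux_laws": [
        {"id": "AB", "forward": {"vmax": "vmax_AB", "terms": [["A", "Km_A"]]}},
        {"id": "BC", "forward": {"vmax": "vmax_BC", "terms": [["B", "Km_B"]]}},
    ],
    "reactions": [
        {"flux": "AB", "stoich": {"A": -1, "B": 1}},
        {"flux": "BC", "stoich": {"B": -1, "C": 1}},
    ],
}


@pytest.fixture(scope="session")
def shipped_model():
    return rm.load_model()


@pytest.fixture(scope="session")
def shipped_params(shipped_model):
    return shipped_model.parameter_set()


@pytest.fixture()
def toy_model():
    return rm.load_model(TOY_AB)


@pytest.fixture()
def chain_model():
    return rm.load_model(TOY_CHAIN)


@pytest.fixture(scope="session")
def clean_dataset(shipped_model, shipped_params):
    """Noiseless synthetic culture dataset from the shipped parameters."""
    return generate(
        shipped_model,
        shipped_params,
        noise=NoiseModel(relative_sd=0.0, absolute_sd_floor=0.0, seed=1),
    )


@pytest.fixture(scope="session")
def shipped_trajectory(shipped_model, shipped_params):
    return rm.simulate(shipped_model, shipped_params)
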