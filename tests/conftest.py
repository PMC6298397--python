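import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from epsflux.synthetic import ToyModelSpec, generate_toy_model


@pytest.fixture(scope="session")
def toy():
    """Default toy model with EPS branch, amino acids and planted truths."""
    return generate_toy_model(ToyModelSpec(seed=0))


@pytest.fixture(scope="session")
def toy_model(toy):
    return toy[0]


@pytest.fixture(scope="session")
def toy_truth(toy):
    return toy[1]


def tiny_spec(seed: int) -> ToyModelSpec:
    """Smallest topology: 10 reactions, enumerable by the LP oracle."""
    return ToyModelSpec(
        n_carbon_sources=1,
        include_eps_pathway=False,
        n_isozyme_pairs=0,
        n_planted_essential=0,
        include_amino_acids=False,
        seed=seed,
    )


@pytest.fixture(scope="session")
def tiny():
    return generate_toy_model(tiny_spec(0))
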