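import numpy as np
import pytest

import wetlandbn as w
from wetlandbn.network import (
    NetworkArc,
    NetworkNode,
    NetworkStructure,
    implied_correlation_matrix,
)
from wetlandbn.synthetic import MarginSpec, SyntheticSpec


@pytest.fixture(scope="session")
def default_spec():
    return w.default_spec(n_wetlands=22, seed=11)


@pytest.fixture(scope="session")
def table22(default_spec):
    """A 22-wetland synthetic table with the study's dependence signs."""
    return w.generate(default_spec)


@pytest.fixture(scope="session")
def model22(table22):
    """Default-structure bn_constrained fit on the 22-row table."""
    return w.fit(table22)


@pytest.fixture(scope="session")
def chain_structure():
    """Three-node chain a -> b -> c with c as target."""
    return NetworkStructure(
        (
            NetworkNode("a", "spatial"),
            NetworkNode("b", "hydrological"),
            NetworkNode("c", "target"),
        ),
        (NetworkArc("a", "b"), NetworkArc("b", "c")),
    )


@pytest.fixture(scope="session")
def dag4():
    """Known 4-node DAG with mixed margins and its ground-truth model.

    Arc partials: salinity -> water level 0.30, size -> species 0.50,
    salinity -> species -0.55, water level -> species -0.35; the true
    joint matrix is the DAG-implied one, so conditional independencies
    hold exactly.
    """
    structure = NetworkStructure(
        (
            NetworkNode("wetland size", "spatial"),
            NetworkNode("water salinity", "hydrological"),
            NetworkNode("mean water level", "hydrological"),
            NetworkNode("number of species", "target"),
        ),
        (
            NetworkArc("water salinity", "mean water level", "+"),
            NetworkArc("wetland size", "number of species", "+"),
            NetworkArc("water salinity", "number of species", "-"),
            NetworkArc("mean water level", "number of species", "-"),
        ),
    )
    truth = {
        ("water salinity", "mean water level"): 0.30,
        ("wetland size", "number of species"): 0.50,
        ("water salinity", "number of species"): -0.55,
        ("mean water level", "number of species"): -0.35,
    }
    R = implied_correlation_matrix(structure, truth)
    margins = {
        "wetland size": MarginSpec("continuous", 13.3, 2048.0, "loguniform"),
        "water salinity": MarginSpec("ordinal", 0, 3, cutpoints=(0.40, 0.65, 0.82)),
        "mean water level": MarginSpec("count", 1, 11),
        "number of species": MarginSpec("count", 2, 32),
    }
    spec = SyntheticSpec(22, R, margins, seed=0)
    return structure, truth, spec


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Deterministic child seeds below 2**31."""
    return [int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(seed).spawn(n)]
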