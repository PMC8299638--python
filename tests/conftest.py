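import numpy as np
import pytest

from factorlmm import RelationshipMatrix, TraitMatrix, simulate_kinship


@pytest.fixture(scope="session")
def kinship25() -> RelationshipMatrix:
    return simulate_kinship(25, seed=101)


@pytest.fixture()
def small_traits() -> TraitMatrix:
    rng = np.random.default_rng(7)
    vals = rng.standard_normal((8, 4))
    return TraitMatrix(
        vals,
        np.ones_like(vals, dtype=bool),
        [f"u{i}" for i in range(8)],
        [f"y{j}" for j in range(4)],
    )
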