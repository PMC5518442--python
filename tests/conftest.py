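import dataclasses

import numpy as np
import pytest

import tractlink as tl


@pytest.fixture(scope="session")
def default_config() -> tl.SyntheticConfig:
    return tl.SyntheticConfig()


@pytest.fixture(scope="session")
def cohort43(default_config) -> "object":
    """One default synthetic cohort (n = 43, fixed seed)."""
    return tl.generate_cohort(dataclasses.replace(default_config, seed=7))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(99)


def centered(rng: np.random.Generator, n: int, p: int) -> np.ndarray:
    """Random column-centered matrix with non-degenerate columns."""
    M = rng.standard_normal((n, p))
    return M - M.mean(axis=0)
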