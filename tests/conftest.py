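import numpy as np
import pytest

from rbsenrich.library import UTRLibrary
from rbsenrich.synthetic import GeneratorConfig, generate_naive_library


@pytest.fixture(scope="session")
def naive_500() -> UTRLibrary:
    """Small uniform naive library for fast tests."""
    return generate_naive_library(GeneratorConfig(library_size=500, seed=42))


@pytest.fixture(scope="session")
def naive_4863() -> UTRLibrary:
    """Naive library at the size of the analyzed round-3 pool."""
    return generate_naive_library(GeneratorConfig(library_size=4863, seed=7))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
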