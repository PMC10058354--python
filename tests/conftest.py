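import numpy as np
import pytest

from armuse.synthetic import GeneratorConfig, generate_cohort, generate_subject


@pytest.fixture(scope="session")
def default_cohort():
    """Four subjects under the default study conditions (10 min each, seed 42)."""
    return generate_cohort(GeneratorConfig(), 4, 42)


@pytest.fixture(scope="session")
def short_subject():
    """A single cheap 2-minute subject for structural tests."""
    return generate_subject(GeneratorConfig(duration_s=120.0), 7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
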