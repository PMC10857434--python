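import numpy as np
import pytest

from midgutlam import SynthConfig, analyze_sample, generate_sample


@pytest.fixture(scope="session")
def default_config():
    return SynthConfig()


@pytest.fixture(scope="session")
def starved_sample(default_config):
    """One default starved sample plus its ground truth."""
    return generate_sample(default_config, "starved", 10)


@pytest.fixture(scope="session")
def starved_analysis(starved_sample):
    """(axis, projected, profile) of the shared starved sample."""
    table, _ = starved_sample
    return analyze_sample(table, type_col="true_type")


@pytest.fixture(scope="session")
def cohort_profiles(default_config):
    """Eight starved profiles (seed family fixed) for border scoring."""
    rng = np.random.default_rng(7)
    profiles = []
    for s in rng.integers(0, 2**31 - 1, 8):
        table, _ = generate_sample(default_config, "starved", int(s))
        profiles.append(analyze_sample(table)[2])
    return profiles
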