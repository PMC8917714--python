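import numpy as np
import pytest
from hypothesis import settings

from gbb8.simulate import GeneratorConfig, generate_dataset

settings.register_profile(
    "default", max_examples=25, deadline=None, derandomize=True
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_data():
    """One default-configuration synthetic sample (study-sized, 2.5% MCAR)."""
    return generate_dataset(GeneratorConfig(seed=1234))


@pytest.fixture(scope="session")
def complete_single_group():
    """Complete single-group sample for oracle comparisons (no missingness)."""
    cfg = GeneratorConfig(
        group_sizes={"all": 400}, group_var="grp", missing_rate=0.0,
        covariate_spec=(), extra_labels={}, seed=42,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def complete_two_group():
    """Complete two-group sample with a latent mean shift in group b."""
    cfg = GeneratorConfig(
        group_sizes={"a": 600, "b": 600}, group_var="grp",
        latent_mean_offsets={"b": 0.5}, missing_rate=0.0,
        covariate_spec=(), extra_labels={}, seed=77,
    )
    return generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
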