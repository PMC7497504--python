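import numpy as np
import pytest

from volatilo import synthetic_data as sd


@pytest.fixture(scope="session")
def tiny_config() -> sd.SimConfig:
    """Small grids for fast unit tests: 400 RT points x 128 DT points."""
    return sd.SimConfig(n_samples=3, n_replicates=2, rt_step=0.04, n_dt=128, seed=11)


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    samples, ims, ms = sd.simulate_study(tiny_config)
    return samples, ims, ms


@pytest.fixture()
def quiet_config() -> sd.SimConfig:
    """Noise- and jitter-free configuration for exact structural checks."""
    return sd.SimConfig(
        n_samples=2, n_replicates=1, rt_step=0.04, n_dt=128,
        noise_sd_additive=0.0, noise_sd_multiplicative=0.0,
        rt_jitter_sd=0.0, dt_jitter_sd=0.0, seed=5,
    )


def exact_concentrations(samples, library=None):
    """Noise-free concentrations (the generator's configured means)."""
    library = library if library is not None else sd.DEFAULT_COMPOUNDS
    return {
        m.sample_id: {
            spec.name: sd.expected_concentration(m.alpha_acid, spec)
            for spec in library if spec.class_tag != "marker"
        }
        for m in samples
    }
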