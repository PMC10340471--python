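import numpy as np
import pytest

from agarispec import GeneratorConfig, SpectrumSet, WavelengthGrid, generate_spectra


@pytest.fixture(scope="session")
def grid() -> WavelengthGrid:
    return WavelengthGrid()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def clean_config() -> GeneratorConfig:
    """All stochastic terms off: observed spectra equal the clean model."""
    return GeneratorConfig(n_samples=40, scatter_slope_sd=0.0,
                           scatter_offset_sd=0.0, noise_sd=0.0,
                           nuisance_sd=0.0, seed=7)


@pytest.fixture(scope="session")
def clean_set(clean_config):
    return generate_spectra(clean_config)


@pytest.fixture()
def random_set(grid, rng) -> SpectrumSet:
    values = 0.5 + 0.3 * rng.random((5, grid.n_bands))
    return SpectrumSet(grid, values)
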