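import numpy as np
import pytest

from mitomorph import GeneratorConfig, PipelineConfig, analyze_field, generate_field


def noiseless(config: GeneratorConfig) -> GeneratorConfig:
    """Same condition with blur and both noise sources disabled."""
    return config.replace(blur_sigma_px=0.0, noise_gain=0.0, noise_read_sd=0.0)


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """Three-cell field small enough for fast tests, realistic enough for
    the default segmentation parameters (nuclei well above the 20 µm²
    debris floor)."""
    return GeneratorConfig(
        field_shape=(320, 320),
        n_cells=3,
        cell_radius_px=(52.0, 3.0),
        nucleus_radius_px=(30.0, 2.0),
        n_mito_per_cell=8.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_field(small_config):
    """Small field rendered with default blur and noise."""
    return generate_field(small_config, field_id="small_noisy")


@pytest.fixture(scope="session")
def noiseless_field(small_config):
    """Same field geometry without blur or noise (truth-exact render)."""
    return generate_field(noiseless(small_config), field_id="small_clean")


@pytest.fixture(scope="session")
def pipeline_config() -> PipelineConfig:
    return PipelineConfig(pixel_size_um=0.1)


@pytest.fixture(scope="session")
def small_result(small_field, pipeline_config):
    field, _ = small_field
    return analyze_field(field, pipeline_config)


@pytest.fixture(scope="session")
def noiseless_result(noiseless_field, pipeline_config):
    field, _ = noiseless_field
    return analyze_field(field, pipeline_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
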