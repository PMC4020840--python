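import numpy as np
import pytest

from ergoquant.synthetic import (
    GeneratorConfig,
    default_pathway_panel,
    scenario_profiles,
)


@pytest.fixture(scope="session")
def panel():
    return default_pathway_panel()


@pytest.fixture(scope="session")
def panel_by_name(panel):
    return {s.name: s for s in panel}


@pytest.fixture
def noiseless_cfg():
    """Generator settings with every stochastic effect switched off."""
    return GeneratorConfig(
        seed=0, ppm_jitter=0.0, baseline_noise=0.0, noise_peak_rate=0.0,
        response_cv=0.0, run_scale_cv=0.0,
    )


@pytest.fixture
def default_cfg():
    return GeneratorConfig(seed=0)


@pytest.fixture(scope="session")
def deletion_profiles():
    return scenario_profiles("deletion_panel")
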