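import numpy as np
import pytest
from dataclasses import replace

import strexpert as sx

try:
    from hypothesis import settings
    settings.register_profile("ci", derandomize=True, max_examples=30,
                              deadline=None)
    settings.load_profile("ci")
except ImportError:
    pass


@pytest.fixture(scope="session")
def panel():
    return sx.default_panel()


@pytest.fixture(scope="session")
def quiet_params():
    """Noise-free, artifact-free simulation: the end-to-end oracle regime."""
    return replace(sx.SimulationParams(), noise_sd=0.0, baseline_amplitude=0.0,
                   stutter_mean=0.0, stutter_sd=0.0, stutter_mean_penta=0.0,
                   stutter_sd_penta=0.0, imbalance_dispersion=0.0,
                   dropout_m50=0.0, crosstalk=np.eye(4), seed=0)


@pytest.fixture(scope="session")
def quiet_bins(panel, quiet_params):
    ladder = sx.simulate_ladder_run(panel, quiet_params)
    return sx.calibrate_from_ladder(ladder, panel)


@pytest.fixture(scope="session")
def default_bins(panel):
    ladder = sx.simulate_ladder_run(panel, sx.SimulationParams(seed=42))
    return sx.calibrate_from_ladder(ladder, panel)
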