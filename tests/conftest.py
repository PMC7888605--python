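"""Shared fixtures: the default synthetic sheet and derived recordings.

Heavy simulations are session-scoped so the whole suite reuses them.
"""

import numpy as np
import pytest

import visparc as vp


@pytest.fixture(scope="session")
def area_map64():
    return vp.generate_area_map(64, 64, seed=7)


@pytest.fixture(scope="session")
def rec_default(area_map64):
    """Default strong-signal wide-field sheet (all sigmas 1, 10 trials x 8 stimuli)."""
    return vp.simulate_widefield(area_map64, vp.SimulationParams(seed=7))


@pytest.fixture(scope="session")
def rec_zero_noise(area_map64):
    """Noise-free sheet: each area carries a distinct exact signal."""
    params = vp.SimulationParams(
        seed=7, sigma_noise=0.0, sigma_global=0.0, sigma_area=1.0, spatial_smooth_px=0.0
    )
    return vp.simulate_widefield(area_map64, params)


@pytest.fixture(scope="session")
def rec_twophoton():
    counts = {c: 40 for c in vp.AREA_CODES}
    params = vp.SimulationParams(n_stimuli=4, n_trials=5, resting_duration_s=60.0, seed=11)
    return vp.simulate_twophoton(counts, params)


@pytest.fixture(scope="session")
def in_map_features(rec_default):
    """Trial-averaged responses of in-map units with their labels."""
    X = vp.trial_average(rec_default)
    keep = rec_default.unit_labels > 0
    return X[keep], rec_default.unit_labels[keep]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
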