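"""Shared fixtures: small synthetic sessions, reused across modules.

Session fixtures are module-scoped and deliberately small (tens of
seconds, a handful of ROIs) so the whole unit suite stays fast; the
full-scale study conditions live in test_acceptance.py.
"""

import numpy as np
import pytest

from bimodal.synthetic import SessionConfig, coupled_config, generate_session


@pytest.fixture(scope="session")
def null_session_small():
    """Zero-coupling session: 8 ROIs, 4 electrodes, 60 s."""
    cfg = SessionConfig(
        n_rois=8, n_electrodes=4, duration_s=60.0, seed=11
    )
    return cfg, generate_session(cfg)


@pytest.fixture(scope="session")
def coupled_session_small():
    """First 4 of 8 ROIs coupled to theta at weight 0.8; 120 s."""
    cfg = coupled_config(
        coupled_fraction=0.5,
        weight=0.8,
        band=0,
        n_rois=8,
        n_electrodes=4,
        duration_s=120.0,
        seed=21,
    )
    return cfg, generate_session(cfg)


@pytest.fixture(scope="session")
def place_session_small():
    """Place-modulated ROIs in a 400x400 px arena; 120 s."""
    rng = np.random.default_rng(5)
    n_rois = 4
    centers = np.array([[80.0, 80.0], [320.0, 80.0], [80.0, 320.0], [320.0, 320.0]])
    cfg = SessionConfig(
        n_rois=n_rois,
        n_electrodes=4,
        duration_s=120.0,
        arena_px=(400, 400),
        place_field_centers=centers,
        baseline_rate_hz=4.0,
        noise_sd=0.05,
        seed=31,
    )
    return cfg, generate_session(cfg)
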