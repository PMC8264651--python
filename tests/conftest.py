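"""Shared fixtures.

The heavy 10-seed planted-signal cohorts are session-scoped and shared
between the robustness-filter and model-recovery acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from fltrad.experiments import cohort_pct_changes, planted_cohort_config
from fltrad.io import SuvVolume, VoiMask

TRIAL_SEEDS = tuple(range(101, 111))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def ball_mask():
    """A ~7 mm radius sphere mask on a 1 mm grid with room around it."""
    shape = (24, 24, 24)
    center = np.array([12.0, 12.0, 12.0])
    idx = np.indices(shape).reshape(3, -1).T
    data = (((idx - center) ** 2).sum(axis=1) <= 7.0**2).reshape(shape)
    return VoiMask(data, (1.0, 1.0, 1.0))


@pytest.fixture()
def textured_lesion(rng, ball_mask):
    """A smooth positive field inside the ball mask, background 0.5."""
    from scipy.ndimage import gaussian_filter

    noise = gaussian_filter(rng.standard_normal(ball_mask.shape), 2.0)
    noise = (noise - noise.min()) / (noise.max() - noise.min())
    data = 0.5 + np.where(ball_mask.data, 2.0 + 6.0 * noise, 0.0)
    return SuvVolume(data, (1.0, 1.0, 1.0)), ball_mask


@pytest.fixture(scope="session")
def planted_trials():
    """(pct_change table, truth table) for the 10 planted-signal cohorts."""
    out = []
    for seed in TRIAL_SEEDS:
        out.append(cohort_pct_changes(planted_cohort_config(seed)))
    return out
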