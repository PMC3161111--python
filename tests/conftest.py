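"""Shared fixtures and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

from rbcflow import LineScanImage, StreakSceneParams, make_linescan


def centroid_slope_speed(img: LineScanImage, background: float = 1.0) -> float:
    """Independent speed oracle: least-squares slope of the streak centroid.

    For a scene with a single dark streak crossing the window, the
    intensity-weighted centroid of the darkening in each time column
    tracks the streak position x0 + v·t; a straight-line fit of centroid
    against time gives the speed directly, without any transform.
    """
    dip = np.clip(background - img.intensity, 0.0, None)
    x_um = np.arange(img.n_space) * img.dx_um
    t_ms = np.arange(img.n_time) * img.dt_ms
    weights = dip.sum(axis=0)
    keep = weights > 0.25 * weights.max()
    centroids = (x_um[:, None] * dip).sum(axis=0)[keep] / weights[keep]
    slope_um_per_ms = np.polyfit(t_ms[keep], centroids, 1)[0]
    return abs(slope_um_per_ms)  # µm/ms == mm/s


@pytest.fixture
def single_streak_scene():
    """One isolated streak crossing a clean 256x256 window."""
    params = StreakSceneParams(
        speed_mm_s=1.0,
        dx_um=0.2,
        dt_ms=0.25,
        n_space=256,
        n_time=256,
        noise_sd=0.0,
        streak_offsets_um=(10.0,),
        seed=0,
    )
    return make_linescan(params)


@pytest.fixture
def clean_streaks_512():
    """Dense noise-free streaks at 1.0 mm/s on the 512x512 reference grid."""
    params = StreakSceneParams(speed_mm_s=1.0, noise_sd=0.0, seed=3)
    return make_linescan(params)
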