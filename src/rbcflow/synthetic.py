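"""Synthetic line-scan images and bolus stacks with known ground truth.

These generators provide the controlled inputs against which every
estimator in the package is validated: kymographs whose dark-streak slope
(and hence RBC speed) is known exactly, and bolus time-lapse stacks whose
per-pixel dye arrival times are drawn from stated distributions.

Line-scan model
---------------
Plasma background of unit intensity; each unlabelled cell at position
x(t) = x0 + v·t carves a multiplicative Gaussian-profile dark streak of
given full width at half maximum and fractional contrast. Streak seed
positions follow a Poisson process of the stated linear density along the
vessel (streaks entering or leaving the window are clipped, as in real
acquisitions). Optional additions: additive Gaussian noise, Poisson shot
noise, and a band of non-vascular rows containing spatiotemporally smooth
background structure plus noise in place of the vessel signal.

Bolus model
-----------
Per-pixel intensity = baseline + amplitude·logistic wash-in + noise, with
the arrival time of each vessel pixel drawn from a segment-specific
normal distribution truncated at zero. Non-vessel pixels receive baseline
and noise only and must never cross the appearance-time threshold.

Identical parameters and seed give bit-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.special import expit
from scipy.stats import truncnorm

from .types import LineScanImage, TimeLapseStack

__all__ = [
    "StreakSceneParams",
    "StreakGroundTruth",
    "make_linescan",
    "BolusSceneParams",
    "BolusGroundTruth",
    "make_bolus_stack",
    "default_segment_masks",
]


# --------------------------------------------------------------------------
# line-scan scenes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StreakSceneParams:
    """Conditions of a synthetic line-scan acquisition.

    Defaults mirror a representative capillary acquisition: 512x512
    pixels, Δx = 0.20 µm/pixel, Δt = 1 ms/pixel, ~4 µm wide RBC streaks at
    half contrast on a unit plasma background with mild detector noise.
    """

    speed_mm_s: float = 1.0
    dx_um: float = 0.20
    dt_ms: float = 1.0
    n_space: int = 512
    n_time: int = 512
    streak_width_um: float = 4.0
    linear_density_per_mm: float = 100.0
    contrast: float = 0.5
    noise_sd: float = 0.05
    nonvascular_fraction: float = 0.0
    nonvascular_sd: float = 0.4
    nonvascular_struct_sd: float = 0.0
    nonvascular_corr_space_px: float = 15.0
    nonvascular_corr_time_px: float = 32.0
    flow_sign: int = 1
    shot_noise: bool = False
    photons_per_unit: float = 100.0
    streak_offsets_um: Optional[tuple[float, ...]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.speed_mm_s < 0:
            raise ValueError("speed_mm_s must be >= 0")
        if not (0 < self.contrast <= 1):
            raise ValueError("contrast must lie in (0, 1]")
        if not (0 <= self.nonvascular_fraction < 1):
            raise ValueError("nonvascular_fraction must lie in [0, 1)")
        if self.flow_sign not in (-1, 1):
            raise ValueError("flow_sign must be +1 or -1")
        if not (self.dx_um > 0 and self.dt_ms > 0):
            raise ValueError("dx_um and dt_ms must be positive")


@dataclass(frozen=True)
class StreakGroundTruth:
    """Exact scene geometry in both image and spectral conventions."""

    speed_mm_s: float
    slope_px_per_px: float      # signed streak slope, rows per column
    phi_image_rad: float        # streak angle from the time axis, image space
    theta_spectral_rad: float   # spectral peak angle in [-π/2, π/2)
    streak_positions_um: np.ndarray  # streak positions at t = 0
    vessel_rows: np.ndarray     # bool mask of rows containing vessel signal
    params: StreakSceneParams


def _spectral_angle(slope_px: float) -> float:
    """Spectral peak angle for a streak of given pixel slope.

    Streak energy lies on the frequency-space line perpendicular to the
    streak direction: θ = φ - π/2 for φ >= 0, θ = φ + π/2 for φ < 0, with
    φ = arctan(slope). Stationary streaks (slope 0) map to θ = -π/2.
    """
    phi = float(np.arctan(slope_px))
    return phi - np.pi / 2 if phi >= 0 else phi + np.pi / 2


def make_linescan(params: StreakSceneParams) -> tuple[LineScanImage, StreakGroundTruth]:
    """Render a streak scene and report its exact geometry."""
    p = params
    rng = np.random.default_rng(p.seed)
    v = p.flow_sign * p.speed_mm_s          # µm/ms, signed
    sigma = p.streak_width_um / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # FWHM -> SD
    length_um = p.n_space * p.dx_um
    duration_ms = p.n_time * p.dt_ms

    slope_px = v * p.dt_ms / p.dx_um
    if p.speed_mm_s > 0 and abs(slope_px) * p.n_time < 1.0:
        warnings.warn(
            "total streak displacement across the window is below one pixel; "
            "the streak angle is degenerate near ±π/2",
            UserWarning,
            stacklevel=2,
        )

    # Streak seed positions at t=0, wide enough that streaks entering or
    # leaving during the window are included (then clipped by the frame).
    margin = 3.0 * sigma
    drift = -v * duration_ms
    lo = min(0.0, drift) - margin
    hi = length_um + max(0.0, drift) + margin
    if p.streak_offsets_um is not None:
        x0 = np.asarray(p.streak_offsets_um, dtype=float)
    else:
        n_cells = rng.poisson(p.linear_density_per_mm * (hi - lo) / 1000.0)
        x0 = np.sort(rng.uniform(lo, hi, size=n_cells))

    x_um = np.arange(p.n_space) * p.dx_um
    t_ms = np.arange(p.n_time) * p.dt_ms
    att = np.ones((p.n_space, p.n_time))
    for xi in x0:
        d = x_um[:, None] - (xi + v * t_ms[None, :])
        att *= 1.0 - p.contrast * np.exp(-0.5 * (d / sigma) ** 2)
    img = att  # unit plasma background

    vessel_rows = np.ones(p.n_space, dtype=bool)
    if p.nonvascular_fraction > 0:
        n_nv = int(round(p.nonvascular_fraction * p.n_space))
        n_vessel = p.n_space - n_nv
        start = (p.n_space - n_vessel) // 2
        vessel_rows[:] = False
        vessel_rows[start : start + n_vessel] = True
        # Non-vascular surround: out-of-focus background of comparable
        # mean brightness with uncorrelated detector noise, optionally
        # carrying quasi-static tissue structure (µm-scale spatially,
        # drifting slowly over the window). The surround level is matched
        # to the vessel's time-averaged brightness: a large static
        # brightness step concentrates spectral energy on the
        # spatial-frequency axis, a documented limitation of the
        # orientation estimator.
        level = img[vessel_rows].mean()
        img = img.copy()
        nv = level + p.nonvascular_sd * rng.standard_normal((n_nv, p.n_time))
        if p.nonvascular_struct_sd > 0:
            smooth = ndimage.gaussian_filter(
                rng.standard_normal((p.n_space, p.n_time)),
                (p.nonvascular_corr_space_px, p.nonvascular_corr_time_px),
            )
            smooth /= smooth.std()
            nv += p.nonvascular_struct_sd * smooth[~vessel_rows]
        img[~vessel_rows] = nv

    if p.noise_sd > 0:
        img = img + rng.normal(0.0, p.noise_sd, size=img.shape)
    if p.shot_noise:
        img = rng.poisson(np.clip(img, 0.0, None) * p.photons_per_unit) / p.photons_per_unit

    gt = StreakGroundTruth(
        speed_mm_s=p.speed_mm_s,
        slope_px_per_px=slope_px,
        phi_image_rad=float(np.arctan(slope_px)),
        theta_spectral_rad=_spectral_angle(slope_px),
        streak_positions_um=x0,
        vessel_rows=vessel_rows,
        params=p,
    )
    return LineScanImage(img, p.dx_um, p.dt_ms), gt


# --------------------------------------------------------------------------
# bolus scenes
# --------------------------------------------------------------------------

def default_segment_masks(height: int, width: int) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint arterial/venous bands used when no masks are supplied.

    Vertical bands on the left (arterial) and right (venous) sides of the
    field, each a few thousand pixels for a 96x96 frame.
    """
    arterial = np.zeros((height, width), dtype=bool)
    venous = np.zeros((height, width), dtype=bool)
    r0, r1 = height // 24, height - height // 24
    arterial[r0:r1, width // 12 : width // 3] = True
    venous[r0:r1, 5 * width // 8 : 11 * width // 12] = True
    return arterial, venous


@dataclass(frozen=True)
class BolusSceneParams:
    """Conditions of a synthetic bolus time-lapse acquisition.

    Defaults reproduce a representative cortical-surface protocol: 14.2
    frames/s, 10 pre-injection baseline frames, arterial arrivals
    N(0.29, 0.28²) s and venous arrivals N(1.43, 0.48²) s truncated at
    zero, a fast logistic dye wash-in and mild detector noise.
    """

    frame_rate_hz: float = 14.2
    n_frames: int = 75
    height: int = 96
    width: int = 96
    baseline_frames: int = 10
    arterial_mask: Optional[np.ndarray] = None
    venous_mask: Optional[np.ndarray] = None
    arterial_arrival_mean_s: float = 0.29
    arterial_arrival_sd_s: float = 0.28
    venous_arrival_mean_s: float = 1.43
    venous_arrival_sd_s: float = 0.48
    rise_time_s: float = 0.05
    baseline_level: float = 0.1
    amplitude: float = 1.0
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.baseline_frames < 5:
            raise ValueError("baseline_frames must be >= 5")
        if self.baseline_frames >= self.n_frames:
            raise ValueError("baseline_frames must be < n_frames")

    def masks(self) -> tuple[np.ndarray, np.ndarray]:
        if (self.arterial_mask is None) != (self.venous_mask is None):
            raise ValueError("supply both masks or neither")
        if self.arterial_mask is None:
            art, ven = default_segment_masks(self.height, self.width)
        else:
            art = np.asarray(self.arterial_mask, dtype=bool)
            ven = np.asarray(self.venous_mask, dtype=bool)
            if art.shape != (self.height, self.width) or ven.shape != art.shape:
                raise ValueError("mask shapes must match (height, width)")
        if np.any(art & ven):
            raise ValueError("arterial and venous masks must be disjoint")
        return art, ven


@dataclass(frozen=True)
class BolusGroundTruth:
    """True per-pixel arrival times and the segment masks used."""

    arrival_s: np.ndarray       # NaN outside vessels
    unreachable: np.ndarray     # arrival beyond the post-baseline duration
    arterial_mask: np.ndarray
    venous_mask: np.ndarray
    params: BolusSceneParams


def _truncated_normal(rng, mean: float, sd: float, size: int) -> np.ndarray:
    a = (0.0 - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def make_bolus_stack(params: BolusSceneParams) -> tuple[TimeLapseStack, BolusGroundTruth]:
    """Render a bolus wash-in movie and report its true arrival map."""
    p = params
    rng = np.random.default_rng(p.seed)
    art, ven = p.masks()
    dt = 1.0 / p.frame_rate_hz

    arrival = np.full((p.height, p.width), np.nan)
    arrival[art] = _truncated_normal(rng, p.arterial_arrival_mean_s, p.arterial_arrival_sd_s, int(art.sum()))
    arrival[ven] = _truncated_normal(rng, p.venous_arrival_mean_s, p.venous_arrival_sd_s, int(ven.sum()))

    # Frame times relative to the first post-baseline frame.
    t = (np.arange(p.n_frames) - p.baseline_frames) * dt
    frames = np.full((p.n_frames, p.height, p.width), p.baseline_level)
    vessel = art | ven
    t_arr = arrival[vessel]
    if p.rise_time_s > 0:
        # Wash-in centred 3 rise times after arrival so the pre-arrival
        # logistic tail stays below baseline-noise thresholds.
        sig = expit((t[:, None] - (t_arr + 3.0 * p.rise_time_s)[None, :]) / p.rise_time_s)
    else:
        sig = (t[:, None] >= t_arr[None, :]).astype(float)
    frames[:, vessel] += p.amplitude * sig

    if p.noise_sd > 0:
        frames = frames + rng.normal(0.0, p.noise_sd, size=frames.shape)
    frames = np.clip(frames, 0.0, None)

    post_duration = (p.n_frames - p.baseline_frames - 1) * dt
    unreachable = np.zeros((p.height, p.width), dtype=bool)
    unreachable[vessel] = arrival[vessel] > post_duration

    stack = TimeLapseStack(frames, frame_interval_s=dt, baseline_frames=p.baseline_frames)
    gt = BolusGroundTruth(
        arrival_s=arrival,
        unreachable=unreachable,
        arterial_mask=art,
        venous_mask=ven,
        params=p,
    )
    return stack, gt
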