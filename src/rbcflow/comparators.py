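"""Radon- and SVD-based streak-angle estimators.

Two widely used alternatives to the frequency-domain estimator, provided
as behavioural reimplementations for cross-validation and robustness
experiments. Both search the same π/180 angle grid as the spectral
method and convert the recovered image-space streak angle φ (measured
from the time axis) to a speed through the shared geometry
v = (Δx/Δt)·|tan φ|, equivalently the spectral angle θ = φ ∓ π/2.

* Radon: project the mean-subtracted image along every candidate
  direction (sinogram of the Radon transform) and measure the variance
  of each projection; integrating along the streaks gives the most
  sharply structured profile, so the variance is maximal at the true
  angle.

* SVD: the rotation that aligns the streaks with an image axis makes the
  image closest to separable (rank-1), concentrating energy in the
  leading singular value. Axis alignment is ambiguous between horizontal
  and vertical; the orientation is disambiguated by asking whether the
  leading left (row) or right (column) singular vector carries the
  structure.

Rotations use bilinear interpolation with zero fill, matching the polar
resampling of the spectral path.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.transform import radon as _radon_transform

from .spectral import speed_from_angle
from .types import (
    LineScanImage,
    NoOrientationSignalError,
    RadonProfile,
    SpeedEstimate,
    SvdResult,
)

__all__ = [
    "radon_variance_profile",
    "radon_speed",
    "svd_separability",
    "svd_speed",
]


def _pad_square(arr: np.ndarray) -> np.ndarray:
    """Embed centrally in a zero square canvas covering every rotation.

    Without this, rotating an elongated window clips most of its content
    at steep angles and the projections lose the streak signal.
    """
    h, w = arr.shape
    side = int(np.ceil(np.hypot(h, w)))
    canvas = np.zeros((side, side), dtype=arr.dtype)
    r0, c0 = (side - h) // 2, (side - w) // 2
    canvas[r0 : r0 + h, c0 : c0 + w] = arr
    return canvas


def _rotate_to_horizontal(arr: np.ndarray, phi_rad: float) -> np.ndarray:
    """Rotate so streaks at image angle ``phi_rad`` become horizontal."""
    return ndimage.rotate(
        arr, np.degrees(phi_rad), reshape=False, order=1, mode="constant", cval=0.0
    )


def _angle_grid(step_deg: float) -> np.ndarray:
    return np.deg2rad(np.arange(-90.0, 90.0, step_deg))


def _check_not_flat(img: LineScanImage) -> np.ndarray:
    if np.ptp(img.intensity) == 0:
        raise NoOrientationSignalError(
            "no orientation signal: image intensity is constant"
        )
    return img.intensity - img.intensity.mean()


def _phi_to_theta(phi: float) -> float:
    """Image-space streak angle to spectral angle in [-π/2, π/2)."""
    return phi - np.pi / 2 if phi >= 0 else phi + np.pi / 2


def radon_variance_profile(
    img: LineScanImage, angle_step_deg: float = 1.0
) -> RadonProfile:
    """Variance of the directional projection per candidate streak angle."""
    arr = _check_not_flat(img)
    phis = _angle_grid(angle_step_deg)
    # Projection at Radon angle α integrates along lines at image angle
    # 90° - α, so a streak at angle φ from the time axis is integrated
    # coherently (maximal projection variance) at α = 90° - φ.
    alpha = 90.0 - np.degrees(phis)
    sino = _radon_transform(arr, theta=alpha, circle=False)
    var = sino.var(axis=0)
    return RadonProfile(theta_grid=phis, variance_per_angle=var)


def radon_speed(img: LineScanImage, angle_step_deg: float = 1.0) -> SpeedEstimate:
    """Speed from the projection angle of maximum variance."""
    profile = radon_variance_profile(img, angle_step_deg)
    var = profile.variance_per_angle
    if var.max() <= 0:
        raise NoOrientationSignalError(
            "no orientation signal: projection variance is identically zero"
        )
    k = int(np.argmax(var))
    phi = float(profile.theta_grid[k])
    med = float(np.median(var))
    prominence = np.inf if med == 0 else float(var.max() / med)
    theta = _phi_to_theta(phi)
    speed = speed_from_angle(theta, img.dx_um, img.dt_ms)
    direction = 0 if speed == 0.0 else (1 if theta < 0 else -1)
    return SpeedEstimate(
        speed_mm_s=speed,
        theta_rad=theta,
        peak_prominence=prominence,
        window_pixels=img.n_time,
        method="radon",
        direction=direction,
    )


def svd_separability(
    img: LineScanImage, angle_step_deg: float = 1.0
) -> tuple[SvdResult, np.ndarray, np.ndarray]:
    """Separability of the image over candidate rotations.

    Returns the best result together with the full angle grid and
    per-angle separability (leading singular value over the sum), for
    diagnostic use.
    """
    arr = _pad_square(_check_not_flat(img))
    if not np.any(arr):
        raise NoOrientationSignalError("no orientation signal: zero image")
    arr = arr.astype(np.float32)  # halves the per-rotation SVD cost
    phis = _angle_grid(angle_step_deg)
    sep = np.empty(phis.shape)
    for i, phi in enumerate(phis):
        s = np.linalg.svd(_rotate_to_horizontal(arr, phi), compute_uv=False)
        total = s.sum()
        sep[i] = s[0] / total if total > 0 else 0.0
    k = int(np.argmax(sep))
    return SvdResult(best_angle=float(phis[k]), separability=float(sep[k])), phis, sep


def svd_speed(img: LineScanImage, angle_step_deg: float = 1.0) -> SpeedEstimate:
    """Speed from the rotation maximising singular-value concentration."""
    result, _, sep = svd_separability(img, angle_step_deg)
    arr = _pad_square(img.intensity - img.intensity.mean())
    phi = result.best_angle

    # Horizontal/vertical ambiguity: at the best rotation, decide which
    # axis the rank-1 structure varies along. Horizontal streaks put the
    # structure in the leading row vector u1; vertical streaks in v1.
    rot = _rotate_to_horizontal(arr, phi)
    u, s, vt = np.linalg.svd(rot, full_matrices=False)
    if np.var(vt[0]) > np.var(u[:, 0]):
        phi = phi - np.pi / 2 if phi >= 0 else phi + np.pi / 2

    theta = _phi_to_theta(phi)
    speed = speed_from_angle(theta, img.dx_um, img.dt_ms)
    direction = 0 if speed == 0.0 else (1 if theta < 0 else -1)
    return SpeedEstimate(
        speed_mm_s=speed,
        theta_rad=theta,
        peak_prominence=float(result.separability),
        window_pixels=img.n_time,
        method="svd",
        direction=direction,
    )
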