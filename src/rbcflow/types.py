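"""Core containers for line-scan velocimetry and bolus transit-time mapping.

The two acquisition geometries handled by this package are

* **line-scan (kymograph) images** — a single scan line placed along the
  axis of a microvessel and acquired repeatedly, giving a 2D array whose
  rows are positions along the vessel and whose columns are scan times.
  Unlabelled red blood cells moving through fluorescently labelled plasma
  appear as slanted dark streaks; the streak slope encodes their speed.

* **time-lapse stacks** — full-frame movies of the cortical surface
  acquired around an intravenous dye bolus, from which per-pixel dye
  appearance times and the arteriovenous transit time (AVTT) are derived.

All containers validate their invariants on construction and are
immutable; functions return new objects rather than mutating inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "MIN_IMAGE_DIM",
    "NoOrientationSignalError",
    "SpeedOutOfRangeError",
    "EmptySegmentError",
    "LineScanImage",
    "PowerSpectrum",
    "AngularPowerProfile",
    "SpeedEstimate",
    "RadonProfile",
    "SvdResult",
    "TimeLapseStack",
    "AppearanceTimeMap",
    "SegmentStats",
    "AVTTResult",
]

#: Smallest admissible extent (pixels) of either axis of a line-scan image.
MIN_IMAGE_DIM = 8


class NoOrientationSignalError(ValueError):
    """The image carries no directional information (e.g. constant input)."""


class SpeedOutOfRangeError(ValueError):
    """A spectral angle maps to a speed outside the measurable range."""


class EmptySegmentError(ValueError):
    """A vessel segment contains no valid appearance-time pixels."""


def _require_finite(arr: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(arr)):
        bad = np.argwhere(~np.isfinite(arr))[0]
        idx = tuple(int(i) for i in bad)
        raise ValueError(f"{name} contains a non-finite value at index {idx}")


@dataclass(frozen=True)
class LineScanImage:
    """Space x time intensity image of a repeatedly scanned vessel axis.

    Parameters
    ----------
    intensity
        2D array; axis 0 is position along the vessel (pixels), axis 1 is
        scan time (pixels).
    dx_um
        Spatial sampling interval Δx in µm/pixel.
    dt_ms
        Temporal sampling interval Δt in ms/pixel.
    """

    intensity: np.ndarray
    dx_um: float
    dt_ms: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensity, dtype=float)
        if arr.ndim != 2:
            raise ValueError(f"intensity must be 2D, got shape {arr.shape}")
        if min(arr.shape) < MIN_IMAGE_DIM:
            raise ValueError(
                f"both image dimensions must be >= {MIN_IMAGE_DIM} pixels, "
                f"got shape {arr.shape}"
            )
        _require_finite(arr, "intensity")
        if not (self.dx_um > 0 and self.dt_ms > 0):
            raise ValueError(
                f"sampling intervals must be positive: dx_um={self.dx_um}, "
                f"dt_ms={self.dt_ms}"
            )
        arr.flags.writeable = False
        object.__setattr__(self, "intensity", arr)

    @property
    def n_space(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_time(self) -> int:
        return self.intensity.shape[1]

    @property
    def length_um(self) -> float:
        """Scanned vessel length covered by the image."""
        return self.n_space * self.dx_um

    @property
    def duration_ms(self) -> float:
        """Temporal window covered by the image."""
        return self.n_time * self.dt_ms

    def crop_time(self, start: int, stop: int) -> "LineScanImage":
        """Temporal sub-window [start, stop) with the same sampling."""
        return LineScanImage(self.intensity[:, start:stop], self.dx_um, self.dt_ms)

    def transposed(self) -> "LineScanImage":
        """Swap the space and time axes (and the roles of Δx and Δt)."""
        return LineScanImage(self.intensity.T.copy(), self.dt_ms, self.dx_um)


@dataclass(frozen=True)
class PowerSpectrum:
    """Centred 2D power spectrum of a mean-subtracted line-scan image.

    ``power`` has the zero-frequency bin at index ``(n0//2, n1//2)``;
    ``freq_space`` / ``freq_time`` give the per-axis frequency coordinates
    in cycles/pixel after the same centring shift.
    """

    power: np.ndarray
    freq_space: np.ndarray
    freq_time: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.power, dtype=float)
        if p.ndim != 2:
            raise ValueError("power must be 2D")
        if np.any(p < 0):
            raise ValueError("power values must be non-negative")
        object.__setattr__(self, "power", p)

    @property
    def center(self) -> tuple[int, int]:
        return (self.power.shape[0] // 2, self.power.shape[1] // 2)


@dataclass(frozen=True)
class AngularPowerProfile:
    """Summed spectral power per direction, g(θ).

    ``theta_grid`` spans [-π/2, π/2) measured from the temporal-frequency
    axis; ``g[k]`` is the radial sum of the power spectrum along the ray at
    ``theta_grid[k]`` out to ``radius`` pixels (the antipodal ray is
    redundant for real input).
    """

    theta_grid: np.ndarray
    g: np.ndarray
    radius: int

    def __post_init__(self) -> None:
        th = np.asarray(self.theta_grid, dtype=float)
        gg = np.asarray(self.g, dtype=float)
        if th.shape != gg.shape or th.ndim != 1:
            raise ValueError("theta_grid and g must be matching 1D arrays")
        _require_finite(gg, "g")
        if np.any(gg < 0):
            raise ValueError("g must be non-negative")
        object.__setattr__(self, "theta_grid", th)
        object.__setattr__(self, "g", gg)


@dataclass(frozen=True)
class SpeedEstimate:
    """Mean RBC speed recovered from one line-scan image (or window).

    ``theta_rad`` is the peak angle of the angular power profile, measured
    from the temporal-frequency axis; ``peak_prominence`` is the ratio of
    the peak value of g to its median (a unitless quality diagnostic);
    ``direction`` is +1/-1 for flow toward increasing/decreasing scan
    position, 0 when stationary.
    """

    speed_mm_s: float
    theta_rad: float
    peak_prominence: float
    window_pixels: int
    method: str = "fft"
    direction: int = 0
    window_start: Optional[int] = None

    def __post_init__(self) -> None:
        if self.speed_mm_s < 0:
            raise ValueError("speed_mm_s must be non-negative")
        if not (-np.pi / 2 - 1e-12 <= self.theta_rad <= np.pi / 2 + 1e-12):
            raise ValueError("theta_rad must lie in [-π/2, π/2]")

    def to_dict(self) -> dict:
        return {
            "speed_mm_s": float(self.speed_mm_s),
            "theta_rad": float(self.theta_rad),
            "peak_prominence": float(self.peak_prominence),
            "window_pixels": int(self.window_pixels),
            "method": self.method,
            "direction": int(self.direction),
            "window_start": None if self.window_start is None else int(self.window_start),
        }


@dataclass(frozen=True)
class RadonProfile:
    """Projection variance per candidate streak angle (Radon comparator)."""

    theta_grid: np.ndarray
    variance_per_angle: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.variance_per_angle, dtype=float)
        if np.any(v < 0):
            raise ValueError("variance_per_angle must be non-negative")
        object.__setattr__(self, "variance_per_angle", v)


@dataclass(frozen=True)
class SvdResult:
    """Best rotation of the SVD comparator and its energy concentration."""

    best_angle: float
    separability: float

    def __post_init__(self) -> None:
        if not (0.0 < self.separability <= 1.0 + 1e-12):
            raise ValueError("separability must lie in (0, 1]")


@dataclass(frozen=True)
class TimeLapseStack:
    """Bolus time-lapse movie with its pre-injection baseline window."""

    frames: np.ndarray
    frame_interval_s: float
    baseline_frames: int

    def __post_init__(self) -> None:
        arr = np.asarray(self.frames, dtype=float)
        if arr.ndim != 3:
            raise ValueError(f"frames must be 3D (frame, row, col), got {arr.shape}")
        _require_finite(arr, "frames")
        if not self.frame_interval_s > 0:
            raise ValueError("frame_interval_s must be positive")
        if not (2 <= self.baseline_frames < arr.shape[0]):
            raise ValueError(
                f"baseline_frames must satisfy 2 <= baseline < {arr.shape[0]}, "
                f"got {self.baseline_frames}"
            )
        arr.flags.writeable = False
        object.__setattr__(self, "frames", arr)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def frame_rate_hz(self) -> float:
        return 1.0 / self.frame_interval_s

    @property
    def post_duration_s(self) -> float:
        """Time spanned by the post-baseline frames."""
        return (self.n_frames - self.baseline_frames) * self.frame_interval_s


@dataclass(frozen=True)
class AppearanceTimeMap:
    """Per-pixel dye appearance time.

    ``t_appear`` is in seconds relative to the first post-baseline frame
    and is NaN wherever ``valid`` is False (pixels that never sustained a
    supra-threshold run).
    """

    t_appear: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t_appear, dtype=float)
        v = np.asarray(self.valid, dtype=bool)
        if t.shape != v.shape or t.ndim != 2:
            raise ValueError("t_appear and valid must be matching 2D arrays")
        if np.any(~np.isfinite(t[v])) or np.any(t[v] < 0):
            raise ValueError("valid appearance times must be finite and >= 0")
        object.__setattr__(self, "t_appear", t)
        object.__setattr__(self, "valid", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.t_appear.shape


@dataclass(frozen=True)
class SegmentStats:
    """Appearance-time statistics of one vascular segment."""

    label: str
    pixel_count: int
    mean_s: float
    sd_s: float
    median_s: float
    area_fraction: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.area_fraction <= 1.0):
            raise ValueError("area_fraction must lie in [0, 1]")

    @property
    def area_percent(self) -> int:
        """Area fraction rounded to the nearest integer percent."""
        return int(round(100.0 * self.area_fraction))


@dataclass(frozen=True)
class AVTTResult:
    """Arteriovenous transit time: venous minus arterial appearance time."""

    arterial: SegmentStats
    venous: SegmentStats
    avtt_mean_s: float
    avtt_median_s: float

    def to_dict(self) -> dict:
        return {
            "avtt_mean_s": float(self.avtt_mean_s),
            "avtt_median_s": float(self.avtt_median_s),
            "arterial": {
                "pixel_count": self.arterial.pixel_count,
                "mean_s": self.arterial.mean_s,
                "sd_s": self.arterial.sd_s,
                "median_s": self.arterial.median_s,
                "area_fraction": self.arterial.area_fraction,
            },
            "venous": {
                "pixel_count": self.venous.pixel_count,
                "mean_s": self.venous.mean_s,
                "sd_s": self.venous.sd_s,
                "median_s": self.venous.median_s,
                "area_fraction": self.venous.area_fraction,
            },
        }
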