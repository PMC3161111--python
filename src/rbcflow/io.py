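"""Reading and writing of images, stacks, masks and result files.

Line-scan images are single-page grayscale TIFF (8/16-bit or float) or
delimited text matrices; sampling metadata (Δx, Δt) comes from explicit
arguments or a JSON sidecar ``{"dx_um": ..., "dt_ms": ...}`` next to the
image. Time-lapse stacks are multi-page grayscale TIFF. Appearance-time
maps are written as 32-bit float TIFF with NaN marking excluded pixels.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .types import AppearanceTimeMap, AVTTResult, LineScanImage, SegmentStats, TimeLapseStack

__all__ = [
    "read_image_array",
    "read_linescan",
    "write_linescan",
    "read_stack",
    "write_stack",
    "read_mask",
    "write_appearance_map",
    "read_appearance_map",
    "write_segment_csv",
    "write_avtt_json",
]

_TIFF_SUFFIXES = {".tif", ".tiff"}


def read_image_array(path: str | Path) -> np.ndarray:
    """Read a 2D grayscale array from TIFF or delimited text."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cannot read image: {path}")
    if path.suffix.lower() in _TIFF_SUFFIXES:
        arr = tifffile.imread(path)
    else:
        try:
            arr = np.loadtxt(path)
        except ValueError:
            arr = np.loadtxt(path, delimiter=",")
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{path} is not a single 2D image (shape {arr.shape})")
    return arr


def _sidecar_metadata(path: Path) -> dict:
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        with open(sidecar) as fh:
            return json.load(fh)
    return {}


def read_linescan(
    path: str | Path,
    dx_um: Optional[float] = None,
    dt_ms: Optional[float] = None,
) -> LineScanImage:
    """Read a line-scan image, taking Δx/Δt from arguments or a sidecar.

    Explicit arguments win over sidecar values; a missing interval is an
    error naming the missing field.
    """
    path = Path(path)
    arr = read_image_array(path)
    meta = _sidecar_metadata(path)
    if dx_um is None:
        dx_um = meta.get("dx_um")
    if dt_ms is None:
        dt_ms = meta.get("dt_ms")
    if dx_um is None:
        raise ValueError(f"missing metadata 'dx_um' for {path} (flag or sidecar JSON)")
    if dt_ms is None:
        raise ValueError(f"missing metadata 'dt_ms' for {path} (flag or sidecar JSON)")
    return LineScanImage(arr, float(dx_um), float(dt_ms))


def write_linescan(path: str | Path, img: LineScanImage) -> None:
    """Write the image as float32 TIFF plus a Δx/Δt sidecar JSON."""
    path = Path(path)
    tifffile.imwrite(path, img.intensity.astype(np.float32))
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump({"dx_um": img.dx_um, "dt_ms": img.dt_ms}, fh, indent=2)


def read_stack(
    path: str | Path, frame_rate_hz: float, baseline_frames: int
) -> TimeLapseStack:
    """Read a multi-page TIFF time-lapse stack."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cannot read stack: {path}")
    arr = np.asarray(tifffile.imread(path), dtype=float)
    if arr.ndim != 3:
        raise ValueError(f"{path} is not a multi-page stack (shape {arr.shape})")
    return TimeLapseStack(arr, 1.0 / frame_rate_hz, baseline_frames)


def write_stack(path: str | Path, stack: TimeLapseStack) -> None:
    tifffile.imwrite(Path(path), stack.frames.astype(np.float32))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask image; any value > 0 counts as inside."""
    return read_image_array(path) > 0


def write_appearance_map(path: str | Path, amap: AppearanceTimeMap) -> None:
    """32-bit float TIFF, NaN where no appearance was detected."""
    tifffile.imwrite(Path(path), amap.t_appear.astype(np.float32))


def read_appearance_map(path: str | Path) -> AppearanceTimeMap:
    t = np.asarray(tifffile.imread(Path(path)), dtype=float)
    return AppearanceTimeMap(t_appear=t, valid=np.isfinite(t))


def write_segment_csv(path: str | Path, segments: list[SegmentStats]) -> None:
    df = pd.DataFrame(
        [
            {
                "label": s.label,
                "pixel_count": s.pixel_count,
                "area_fraction": s.area_fraction,
                "area_percent": s.area_percent,
                "mean_s": s.mean_s,
                "sd_s": s.sd_s,
                "median_s": s.median_s,
            }
            for s in segments
        ]
    )
    df.to_csv(path, index=False)


def write_avtt_json(path: str | Path, result: AVTTResult) -> None:
    with open(path, "w") as fh:
        json.dump(result.to_dict(), fh, indent=2)
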