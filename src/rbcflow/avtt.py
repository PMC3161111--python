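"""Dye appearance-time mapping and arteriovenous transit time (AVTT).

After an intravenous dye bolus, each vascular pixel of a cortical
time-lapse movie brightens when the dye front reaches it. The pipeline:

1. per-frame 2D median filter against photomultiplier shot noise,
2. per-pixel baseline mean and SD over the pre-injection frames,
3. appearance time: the earliest post-baseline frame at which the pixel
   and a required run of subsequent frames all strictly exceed
   baseline mean + k·SD (defaults k = 2 and a 5-frame persistence, i.e.
   a 6-frame supra-threshold run); pixels that never qualify are excluded,
4. per-segment statistics over externally supplied (typically manually
   drawn) artery/vein masks,
5. AVTT = venous appearance time minus arterial appearance time.

The AVTT is a whole-cortex surrogate of capillary perfusion: its inverse
tracks mean capillary blood speed when vascular volume is comparable
between groups.
"""

from __future__ import annotations

import warnings
from collections import deque
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .types import (
    AppearanceTimeMap,
    AVTTResult,
    EmptySegmentError,
    SegmentStats,
    TimeLapseStack,
)

__all__ = [
    "denoise_stack",
    "baseline_stats",
    "appearance_time",
    "segment_stats",
    "compute_avtt",
    "segment_assist",
    "run_pipeline",
]


def denoise_stack(stack: TimeLapseStack, kernel: int = 3) -> TimeLapseStack:
    """Per-frame 2D median filter of odd kernel size; kernel 1 is identity."""
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError(f"median kernel must be odd and >= 1, got {kernel}")
    if kernel == 1:
        return stack
    filtered = ndimage.median_filter(stack.frames, size=(1, kernel, kernel))
    return TimeLapseStack(filtered, stack.frame_interval_s, stack.baseline_frames)


def baseline_stats(stack: TimeLapseStack) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel mean and sample SD (n-1) over the pre-injection frames."""
    base = stack.frames[: stack.baseline_frames]
    return base.mean(axis=0), base.std(axis=0, ddof=1)


def appearance_time(
    stack: TimeLapseStack,
    baseline: tuple[np.ndarray, np.ndarray],
    k_sd: float = 2.0,
    persistence: int = 5,
) -> AppearanceTimeMap:
    """Earliest sustained threshold crossing per pixel.

    A pixel's appearance frame is the earliest post-baseline frame f such
    that frames f, f+1, ..., f+persistence all strictly exceed
    ``baseline mean + k_sd * SD``. Runs that would extend past the last
    frame do not qualify. Pixels with no qualifying frame are excluded
    (``valid`` False, time NaN). Times are reported in seconds from the
    first post-baseline frame.
    """
    if persistence < 0:
        raise ValueError("persistence must be >= 0")
    n_post = stack.n_frames - stack.baseline_frames
    if persistence >= n_post:
        raise ValueError(
            f"persistence of {persistence} frames requires more than the "
            f"{n_post} available post-baseline frames"
        )
    mean, sd = baseline
    if mean.shape != stack.frame_shape or sd.shape != stack.frame_shape:
        raise ValueError("baseline statistics must match the frame shape")
    threshold = mean + k_sd * sd
    above = stack.frames[stack.baseline_frames :] > threshold  # strict

    run = persistence + 1
    counts = np.cumsum(above, axis=0, dtype=np.int32)
    counts = np.concatenate([np.zeros((1,) + stack.frame_shape, np.int32), counts])
    window_full = (counts[run:] - counts[:-run]) == run  # run starting at f

    valid = window_full.any(axis=0)
    first = np.argmax(window_full, axis=0)
    t = np.full(stack.frame_shape, np.nan)
    t[valid] = first[valid] * stack.frame_interval_s
    return AppearanceTimeMap(t_appear=t, valid=valid)


def segment_stats(
    amap: AppearanceTimeMap, mask: np.ndarray, label: str
) -> SegmentStats:
    """Appearance-time statistics over the valid pixels of one segment.

    ``area_fraction`` is relative to the total pixel count of the image,
    matching how segment areas are reported against the full field of
    view.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != amap.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match map shape {amap.shape}"
        )
    sel = mask & amap.valid
    n = int(sel.sum())
    if n == 0:
        raise EmptySegmentError(f"segment '{label}' has no valid pixels")
    vals = amap.t_appear[sel]
    sd = float(vals.std(ddof=1)) if n > 1 else 0.0
    return SegmentStats(
        label=label,
        pixel_count=n,
        mean_s=float(vals.mean()),
        sd_s=sd,
        median_s=float(np.median(vals)),
        area_fraction=n / amap.t_appear.size,
    )


def compute_avtt(arterial: SegmentStats, venous: SegmentStats) -> AVTTResult:
    """AVTT as venous minus arterial appearance time (mean and median)."""
    if arterial.pixel_count == 0 or venous.pixel_count == 0:
        raise EmptySegmentError("both segments must be non-empty")
    avtt_mean = venous.mean_s - arterial.mean_s
    avtt_median = venous.median_s - arterial.median_s
    if avtt_mean < 0:
        warnings.warn(
            f"negative mean AVTT ({avtt_mean:.3f} s): venous dye arrival "
            "precedes arterial, which is physiologically unexpected",
            UserWarning,
            stacklevel=2,
        )
    return AVTTResult(
        arterial=arterial,
        venous=venous,
        avtt_mean_s=avtt_mean,
        avtt_median_s=avtt_median,
    )


def run_pipeline(
    stack: TimeLapseStack,
    arterial_mask: np.ndarray,
    venous_mask: np.ndarray,
    *,
    median_kernel: int = 3,
    k_sd: float = 2.0,
    persistence: int = 5,
) -> tuple[AVTTResult, AppearanceTimeMap]:
    """Full stack-to-AVTT pipeline with the default processing chain."""
    den = denoise_stack(stack, kernel=median_kernel)
    amap = appearance_time(den, baseline_stats(den), k_sd=k_sd, persistence=persistence)
    art = segment_stats(amap, arterial_mask, "arterial")
    ven = segment_stats(amap, venous_mask, "venous")
    return compute_avtt(art, ven), amap


def segment_assist(
    amap: AppearanceTimeMap,
    seeds: Mapping[str, Sequence[tuple[int, int]]],
    tolerance_s: float,
) -> dict[str, np.ndarray]:
    """Region-growing helper for segment masks.

    Vascular segmentation is normally drawn by hand from the spatial
    continuity of the appearance time along each vessel; this helper
    automates that criterion. Starting from the given seed pixels, each
    label grows over 4-connected valid pixels whose appearance time
    differs from the region's running mean by at most ``tolerance_s``.
    Labels grow in the order given; a pixel claimed by an earlier label
    is never reassigned (conflicts are reported via a warning).
    """
    if tolerance_s < 0:
        raise ValueError("tolerance_s must be >= 0")
    h, w = amap.shape
    taken = np.zeros((h, w), dtype=bool)
    masks: dict[str, np.ndarray] = {}
    conflicts = 0
    for label, pts in seeds.items():
        if len(pts) == 0:
            raise ValueError(f"label '{label}' needs at least one seed pixel")
        mask = np.zeros((h, w), dtype=bool)
        total = 0.0
        count = 0
        frontier: deque[tuple[int, int]] = deque()
        for r, c in pts:
            if not amap.valid[r, c]:
                raise ValueError(
                    f"seed ({r}, {c}) for label '{label}' is not a valid pixel"
                )
            if taken[r, c]:
                conflicts += 1
                continue
            taken[r, c] = mask[r, c] = True
            total += amap.t_appear[r, c]
            count += 1
            frontier.append((r, c))
        while frontier:
            r, c = frontier.popleft()
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < h and 0 <= cc < w):
                    continue
                if taken[rr, cc] or not amap.valid[rr, cc]:
                    continue
                if abs(amap.t_appear[rr, cc] - total / count) <= tolerance_s:
                    taken[rr, cc] = mask[rr, cc] = True
                    total += amap.t_appear[rr, cc]
                    count += 1
                    frontier.append((rr, cc))
        masks[label] = mask
    if conflicts:
        warnings.warn(
            f"{conflicts} seed pixel(s) were already claimed by an earlier "
            "label and kept their first assignment",
            UserWarning,
            stacklevel=2,
        )
    return masks
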