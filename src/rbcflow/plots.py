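"""Diagnostic figures: raw image, power spectrum and angular profile."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .spectral import compute_power_spectrum, polar_sum
from .types import AppearanceTimeMap, LineScanImage, SpeedEstimate

__all__ = ["speed_panels", "appearance_map_figure"]


def speed_panels(
    img: LineScanImage, estimate: SpeedEstimate, path: str | Path
) -> None:
    """Three-panel summary: kymograph, centred spectrum, g(θ) profile."""
    ps = compute_power_spectrum(img)
    profile = polar_sum(ps)
    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    axes[0].imshow(img.intensity, cmap="Greens_r", aspect="auto")
    axes[0].set_xlabel(f"time (Δt = {img.dt_ms} ms/px)")
    axes[0].set_ylabel(f"space (Δx = {img.dx_um} µm/px)")
    axes[0].set_title("line-scan image")
    axes[1].imshow(np.log1p(ps.power), cmap="magma", aspect="auto")
    axes[1].set_title("power spectrum (log)")
    axes[2].plot(np.degrees(profile.theta_grid), profile.g)
    axes[2].axvline(np.degrees(estimate.theta_rad), color="r", ls="--")
    axes[2].set_xlabel("θ (deg)")
    axes[2].set_ylabel("g(θ)")
    axes[2].set_title(f"peak → {estimate.speed_mm_s:.2f} mm/s")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def appearance_map_figure(amap: AppearanceTimeMap, path: str | Path) -> None:
    """Colour-coded appearance-time map; excluded pixels are blank."""
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(amap.t_appear, cmap="jet_r", interpolation="nearest")
    fig.colorbar(im, ax=ax, label="appearance time (s)")
    ax.set_title("dye appearance time")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
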