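"""Plotting hooks: condition waveforms with significance extents, and scalp
difference topographies at the maximal-difference latency."""

from __future__ import annotations

import numpy as np

from .containers import Montage
from .erp_stats import ERP, PermTestResult

__all__ = ["plot_erp_contrast", "plot_topography"]


def plot_erp_contrast(
    erp_a: ERP,
    erp_b: ERP,
    result: PermTestResult | None = None,
    electrode: str = "Fz",
    window_ms: tuple[float, float] = (250.0, 400.0),
    ax=None,
):
    """Grand-average waveforms at one electrode, the scoring window box and
    (optionally) the significant temporal extents as a horizontal bar."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.plot(erp_a.times, erp_a.channel(electrode), label=erp_a.condition, color="crimson")
    ax.plot(erp_b.times, erp_b.channel(electrode), label=erp_b.condition, color="navy")
    ax.axvspan(*window_ms, color="0.85", zorder=0)
    if result is not None:
        y = ax.get_ylim()[0] * 0.95
        for t0, t1 in result.extents_ms:
            ax.hlines(y, t0, t1, color="k", lw=3)
    ax.axhline(0, color="0.5", lw=0.5)
    ax.axvline(0, color="0.5", lw=0.5)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("amplitude (µV)")
    ax.legend(frameon=False)
    return ax


def plot_topography(values: np.ndarray, montage: Montage, ax=None, cmap="RdBu_r"):
    """Top-down scalp map of a per-channel scalar (azimuthal projection)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    pos = montage.positions
    r = np.linalg.norm(pos, axis=1)
    theta = np.arccos(np.clip(pos[:, 2] / r, -1, 1))
    phi = np.arctan2(pos[:, 1], pos[:, 0])
    x, y = theta * np.cos(phi), theta * np.sin(phi)
    vmax = np.abs(values).max() or 1.0
    sc = ax.scatter(x, y, c=values, cmap=cmap, vmin=-vmax, vmax=vmax, s=60)
    ax.set_aspect("equal")
    ax.axis("off")
    plt.colorbar(sc, ax=ax, shrink=0.7, label="µV")
    return ax
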