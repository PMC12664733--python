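"""Matplotlib views of the analysis objects (KM curves, annulus profiles,
density heatmaps). Each function draws on a provided or fresh Axes and
returns it, so figures compose."""

from __future__ import annotations

import numpy as np

from .distance import DistanceProfile
from .hotspot import DensityGrid
from .survival import KmCurve


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt
        _, ax = plt.subplots()
    return ax


def plot_km(curves: dict[str, KmCurve], ax=None):
    """Step plot of one or more Kaplan-Meier curves (time in months)."""
    ax = _ax(ax)
    for label, km in curves.items():
        t = np.concatenate([[0.0], km.times])
        s = np.concatenate([[1.0], km.survival])
        ax.step(t, s, where="post", label=label)
    ax.set_xlabel("months")
    ax.set_ylabel("recurrence-free fraction")
    ax.set_ylim(0, 1.02)
    ax.legend()
    return ax


def plot_annulus_profile(profiles: dict[str, DistanceProfile], ax=None):
    """Mean target count per 10-µm annulus for each index class."""
    ax = _ax(ax)
    for label, prof in profiles.items():
        edges = np.arange(len(prof.annulus_counts)) * prof.bin_um
        ax.bar(edges, prof.annulus_counts, width=prof.bin_um * 0.9,
               align="edge", alpha=0.5, label=label)
    ax.set_xlabel("distance from index cell (µm)")
    ax.set_ylabel("mean target cells per annulus")
    ax.legend()
    return ax


def plot_density_heatmap(grid: DensityGrid, ax=None):
    """Heatmap of per-bin cell counts (x right, y up, µm)."""
    ax = _ax(ax)
    nx, ny = grid.counts.shape
    extent = (grid.origin[0], grid.origin[0] + nx * grid.bin_um,
              grid.origin[1], grid.origin[1] + ny * grid.bin_um)
    im = ax.imshow(grid.counts.T, origin="lower", extent=extent, aspect="equal")
    ax.figure.colorbar(im, ax=ax, label="cells per bin")
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    return ax
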