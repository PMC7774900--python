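"""Matplotlib helpers for profiles and kymographs."""

from __future__ import annotations

from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .profiles import AuxinProfile, MaximaRecord


def plot_profile(profile: AuxinProfile,
                 maxima: Optional[Sequence[tuple]] = None, ax=None):
    """One spatial auxin profile with optional detected maxima."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    ax.plot(profile.x, profile.v, lw=1.5)
    if maxima:
        xs = [m[0] for m in maxima]
        vs = [m[1] for m in maxima]
        ax.plot(xs, vs, "rv", ms=8)
    ax.set_xlabel("position along placenta [cell lengths]")
    ax.set_ylabel("auxin")
    ax.set_title(f"t = {profile.t:g}")
    return ax


def plot_kymograph(profiles: Sequence[AuxinProfile],
                   records: Optional[Sequence[MaximaRecord]] = None,
                   ax=None, cmap: str = "viridis"):
    """Time x position heatmap of the auxin field with the length envelope.

    Each frame's profile is resampled onto a common spatial grid; positions
    beyond that frame's tissue length are masked, so the growing placenta
    appears as a widening wedge.  Tracked maxima are overlaid coloured by
    group (group 1 red, group 2 blue, later groups grey), echoing the usual
    first/second-group colour convention.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    times = np.array([p.t for p in profiles])
    Lmax = max(p.L for p in profiles)
    nx = max(len(p.x) for p in profiles)
    grid = np.linspace(0.0, Lmax, nx)
    img = np.full((len(profiles), nx), np.nan)
    for i, p in enumerate(profiles):
        inside = grid <= p.L
        img[i, inside] = np.interp(grid[inside], p.x, p.v)
    masked = np.ma.masked_invalid(img)
    mesh = ax.pcolormesh(grid, times, masked, shading="nearest", cmap=cmap)
    plt.colorbar(mesh, ax=ax, label="auxin")
    ax.plot([p.L for p in profiles], times, "k-", lw=1,
            label="placenta length")
    if records:
        colors = {1: "red", 2: "blue"}
        for rec in records:
            xs = [f[2] for f in rec.frames]
            ts = [f[1] for f in rec.frames]
            ax.plot(xs, ts, ".", ms=2.5,
                    color=colors.get(rec.group, "lightgrey"))
    ax.set_xlabel("position along placenta [cell lengths]")
    ax.set_ylabel("time")
    ax.legend(loc="upper left", fontsize=8)
    return ax
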