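"""Interpolated disc surfaces from per-slice subregion means."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

ANCHOR_POSITIONS = (np.arange(5) + 0.5) / 5.0  # subregion centers, AP fraction


@dataclass
class DiscSurfaceGrid:
    """Values over (slice position, normalized anteroposterior position)."""

    values: np.ndarray          # (n_slices, n_points)
    axis_positions: np.ndarray  # (n_points,) in [0, 1]
    anchors: np.ndarray         # (n_slices, 5) input subregion means
    slices: Tuple[int, ...]


def build_surface(
    per_slice_subregion_means: np.ndarray,
    slices: Optional[Sequence[int]] = None,
    n_points: int = 101,
) -> DiscSurfaceGrid:
    """Piecewise-linear interpolation between subregion-center anchors.

    Each row of the input holds the five subregion means of one slice
    (NaN = missing).  Positions outside the outer anchors are clamped to the
    nearest anchor value, so the interpolant never exceeds the anchor range.
    """
    anchors = np.asarray(per_slice_subregion_means, dtype=float)
    if anchors.ndim == 1:
        anchors = anchors[None, :]
    if anchors.shape[1] != 5:
        raise ValueError("expected five subregion means per slice")
    if not np.any(np.isfinite(anchors)):
        raise ValueError("all subregion means are missing")
    if slices is None:
        slices = tuple(range(anchors.shape[0]))
    x = np.linspace(0.0, 1.0, n_points)
    xa = np.asarray(ANCHOR_POSITIONS)
    values = np.full((anchors.shape[0], n_points), np.nan)
    for i, row in enumerate(anchors):
        ok = np.isfinite(row)
        if ok.sum() == 0:
            continue
        if ok.sum() == 1:
            values[i] = row[ok][0]
            continue
        values[i] = np.interp(x, xa[ok], row[ok])
    return DiscSurfaceGrid(values, x, anchors, tuple(int(s) for s in slices))


def surface_frame(grid: DiscSurfaceGrid):
    """Tidy (slice, position, value) frame for CSV export."""
    import pandas as pd

    n_slices, n_points = grid.values.shape
    return pd.DataFrame(
        {
            "slice": np.repeat(grid.slices, n_points),
            "position": np.tile(grid.axis_positions, n_slices),
            "value": grid.values.ravel(),
        }
    )


def render_surface(grid: DiscSurfaceGrid, path, title: str = "") -> None:
    """Optional 3D rendering of the numeric grid (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(6, 4))
    ax = fig.add_subplot(111, projection="3d")
    xx, yy = np.meshgrid(grid.axis_positions, np.asarray(grid.slices, dtype=float))
    ax.plot_surface(xx, yy, np.nan_to_num(grid.values), cmap="viridis")
    ax.set_xlabel("anterior-posterior position")
    ax.set_ylabel("slice")
    if title:
        ax.set_title(title)
    fig.savefig(path, dpi=120)
    plt.close(fig)
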