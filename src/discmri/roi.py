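"""Disc ROI geometry: five anteroposterior subregions and region statistics.

A disc ROI is a per-slice closed polygon in pixel coordinates (0-based,
axis order ``(row, column)``, anterior = lower column index, integer
coordinates at pixel centers).  Each slice polygon is split into five
equal-length bins along its principal (longest) axis, ordered
1 (anterior) to 5 (posterior).  The central bin (3) operationalizes the
nucleus pulposus; the pooled end bins (1 and 5) the annulus fibrosus.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import shapely
from shapely.geometry import Polygon, box

logger = logging.getLogger(__name__)

N_SUBREGIONS = 5
NUCLEUS_INDEX = 2           # 0-based: subregion 3
ANNULUS_INDICES = (0, 4)    # 0-based: subregions 1 and 5


@dataclass
class DiscROI:
    """Closed polygon per slice for one disc.

    ``slices`` maps slice index -> (N, 2) float array of vertices in
    (row, col) order, anterior-most vertex listed first.
    """

    disc_id: str
    slices: Dict[int, np.ndarray]

    def __post_init__(self) -> None:
        self.slices = {int(k): np.asarray(v, dtype=float) for k, v in self.slices.items()}
        for idx, verts in self.slices.items():
            if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
                raise ValueError(f"slice {idx}: vertices must be (N>=3, 2)")

    @property
    def slice_indices(self) -> Tuple[int, ...]:
        return tuple(sorted(self.slices))


@dataclass
class SubregionSet:
    """Five subregion polygons of one ROI slice, anterior to posterior."""

    polygons: Tuple[Polygon, ...]
    parent: Polygon
    axis_origin: np.ndarray      # (x, y) = (col, row) of anterior axis end
    axis_direction: np.ndarray   # unit (x, y), points anterior -> posterior
    bin_edges: np.ndarray        # 6 projections along the axis

    @property
    def areas(self) -> np.ndarray:
        return np.array([p.area for p in self.polygons])


@dataclass
class RegionStats:
    """Voxel statistics per subregion and for the whole disc."""

    subregion_mean: np.ndarray   # (5,) NaN where empty
    subregion_sd: np.ndarray
    subregion_count: np.ndarray  # (5,) int
    whole_mean: float
    whole_sd: float
    whole_count: int
    slices: Tuple[int, ...]

    @property
    def missing(self) -> np.ndarray:
        return self.subregion_count == 0


class ROIError(ValueError):
    """Invalid ROI geometry or inputs."""


# ---------------------------------------------------------------------------
# geometry helpers


def _to_polygon(vertices: np.ndarray) -> Polygon:
    verts = np.asarray(vertices, dtype=float)
    # shapely works in (x, y); our vertices are (row, col) -> (x=col, y=row)
    poly = Polygon([(c, r) for r, c in verts])
    if not poly.is_valid:
        raise ROIError("polygon is not simple (self-intersecting or degenerate)")
    if poly.area <= 0:
        raise ROIError("polygon has zero area")
    return poly


def _principal_axis(poly: Polygon) -> np.ndarray:
    """Unit direction of the longest side of the minimum rotated rectangle.

    Oriented so that projection increases toward higher column (posterior).
    """
    rect = poly.minimum_rotated_rectangle
    if rect.geom_type != "Polygon":  # degenerate (line-like) parents
        raise ROIError("degenerate polygon: cannot determine principal axis")
    coords = np.asarray(rect.exterior.coords)[:4]
    edges = np.diff(np.vstack([coords, coords[:1]]), axis=0)
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    u = edges[np.argmax(lengths)]
    u = u / np.linalg.norm(u)
    if u[0] < 0 or (u[0] == 0 and u[1] < 0):
        u = -u
    return u


def split_subregions(vertices: np.ndarray, n: int = N_SUBREGIONS) -> SubregionSet:
    """Clip a simple polygon into ``n`` equal-length bins along its long axis."""
    poly = _to_polygon(vertices)
    u = _principal_axis(poly)
    pts = np.asarray(poly.exterior.coords)
    t = pts @ u
    t_min, t_max = float(t.min()), float(t.max())
    if t_max <= t_min:
        raise ROIError("polygon collapses along its principal axis")
    edges = np.linspace(t_min, t_max, n + 1)
    v = np.array([-u[1], u[0]])
    s = pts @ v
    s_lo, s_hi = s.min() - 1.0, s.max() + 1.0

    polys = []
    for k in range(n):
        lo, hi = edges[k], edges[k + 1]
        corners = [
            lo * u + s_lo * v,
            hi * u + s_lo * v,
            hi * u + s_hi * v,
            lo * u + s_hi * v,
        ]
        strip = Polygon(corners)
        clipped = poly.intersection(strip)
        if clipped.geom_type not in ("Polygon", "MultiPolygon"):
            clipped = Polygon()
        polys.append(clipped)
    origin = t_min * u
    return SubregionSet(tuple(polys), poly, origin, u, edges)


def rasterize_polygon(poly: Polygon, shape: Tuple[int, int]) -> np.ndarray:
    """Boolean (rows, cols) mask of pixels whose centers fall inside ``poly``."""
    mask = np.zeros(shape, dtype=bool)
    minx, miny, maxx, maxy = poly.bounds
    c0 = max(int(np.floor(minx)), 0)
    c1 = min(int(np.ceil(maxx)), shape[1] - 1)
    r0 = max(int(np.floor(miny)), 0)
    r1 = min(int(np.ceil(maxy)), shape[0] - 1)
    if c1 < c0 or r1 < r0:
        return mask
    cc, rr = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
    inside = shapely.contains_xy(poly, cc.ravel().astype(float), rr.ravel().astype(float))
    mask[r0:r1 + 1, c0:c1 + 1] = inside.reshape(rr.shape)
    return mask


def _bin_pixels(sub: SubregionSet, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Assign rasterized parent pixels to subregion bins by axis projection.

    Binning by projection (rather than re-rasterizing each strip) guarantees
    that the subregions partition the parent raster exactly, so the whole-disc
    mean equals the count-weighted mean of subregion means by construction.
    """
    u = sub.axis_direction
    t = cols * u[0] + rows * u[1]
    edges = sub.bin_edges
    width = (edges[-1] - edges[0]) / (len(edges) - 1)
    idx = np.floor((t - edges[0]) / width).astype(int)
    return np.clip(idx, 0, len(edges) - 2)


# ---------------------------------------------------------------------------
# slice selection and metric extraction


def select_central_slices(roi: DiscROI, k: int = 3) -> Tuple[int, ...]:
    """The ``k`` ROI slices nearest the median of the slice range.

    Ties are broken toward the lower index.  If the ROI spans fewer than
    ``k`` slices, all available slices are returned with a warning.
    """
    indices = sorted(roi.slices)
    if len(indices) < k:
        logger.warning("ROI %s spans %d < %d slices; using all", roi.disc_id, len(indices), k)
        return tuple(indices)
    median = (indices[0] + indices[-1]) / 2.0
    ranked = sorted(indices, key=lambda i: (abs(i - median), i))
    return tuple(sorted(ranked[:k]))


def extract_metrics(
    values: np.ndarray,
    roi: DiscROI,
    valid: Optional[np.ndarray] = None,
    slices: Optional[Sequence[int]] = None,
    k: int = 3,
    all_slices: bool = False,
) -> RegionStats:
    """Pool voxel means per subregion and for the whole disc.

    ``values`` is a (slices, rows, cols) map; only voxels where ``valid``
    (and finite) enter the means.  By default the central ``k`` slices of
    the ROI are pooled; ``all_slices=True`` pools every ROI slice.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 3:
        raise ROIError("values must be a 3D (slice, row, col) array")
    if valid is None:
        valid = np.isfinite(values)
    else:
        valid = np.asarray(valid, dtype=bool) & np.isfinite(values)
    if valid.shape != values.shape:
        raise ROIError("valid mask shape mismatch")

    if slices is None:
        slices = tuple(sorted(roi.slices)) if all_slices else select_central_slices(roi, k)
    slices = tuple(int(s) for s in slices)

    n = N_SUBREGIONS
    sums = np.zeros(n)
    sumsq = np.zeros(n)
    counts = np.zeros(n, dtype=int)
    for z in slices:
        if z not in roi.slices or z < 0 or z >= values.shape[0]:
            continue
        sub = split_subregions(roi.slices[z])
        mask = rasterize_polygon(sub.parent, values.shape[1:])
        rows, cols = np.nonzero(mask)
        if rows.size == 0:
            continue
        ok = valid[z, rows, cols]
        rows, cols = rows[ok], cols[ok]
        if rows.size == 0:
            continue
        bins = _bin_pixels(sub, rows.astype(float), cols.astype(float))
        vals = values[z, rows, cols]
        sums += np.bincount(bins, weights=vals, minlength=n)
        sumsq += np.bincount(bins, weights=vals * vals, minlength=n)
        counts += np.bincount(bins, minlength=n)

    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        var = np.where(counts > 0, sumsq / np.maximum(counts, 1) - means**2, np.nan)
        sds = np.sqrt(np.maximum(var, 0.0))
    total = counts.sum()
    if total > 0:
        whole_mean = float(sums.sum() / total)
        whole_var = max(sumsq.sum() / total - whole_mean**2, 0.0)
        whole_sd = float(np.sqrt(whole_var))
    else:
        whole_mean, whole_sd = float("nan"), float("nan")
    return RegionStats(means, sds, counts, whole_mean, whole_sd, int(total), slices)


def slice_subregion_profile(
    values: np.ndarray,
    roi: DiscROI,
    valid: Optional[np.ndarray] = None,
    slices: Optional[Sequence[int]] = None,
) -> Tuple[np.ndarray, Tuple[int, ...]]:
    """Per-slice subregion means, shape (n_slices, 5); NaN where empty."""
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.isfinite(values)
    else:
        valid = np.asarray(valid, dtype=bool) & np.isfinite(values)
    if slices is None:
        slices = tuple(sorted(roi.slices))
    slices = tuple(int(s) for s in slices)
    out = np.full((len(slices), N_SUBREGIONS), np.nan)
    for i, z in enumerate(slices):
        if z not in roi.slices or z < 0 or z >= values.shape[0]:
            continue
        sub = split_subregions(roi.slices[z])
        mask = rasterize_polygon(sub.parent, values.shape[1:])
        rows, cols = np.nonzero(mask)
        if rows.size == 0:
            continue
        ok = valid[z, rows, cols]
        rows, cols = rows[ok], cols[ok]
        if rows.size == 0:
            continue
        bins = _bin_pixels(sub, rows.astype(float), cols.astype(float))
        vals = values[z, rows, cols]
        sums = np.bincount(bins, weights=vals, minlength=N_SUBREGIONS)
        counts = np.bincount(bins, minlength=N_SUBREGIONS)
        with np.errstate(invalid="ignore"):
            out[i] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return out, slices


def nucleus_annulus_ratio(
    stats: RegionStats,
    nucleus_index: int = NUCLEUS_INDEX,
    annulus_indices: Sequence[int] = ANNULUS_INDICES,
) -> float:
    """mean(subregion 3) / pooled-voxel mean of subregions 1 and 5.

    Returns NaN when the nucleus or both annulus subregions are empty, or
    when the pooled annulus mean is zero.
    """
    if stats.subregion_count[nucleus_index] == 0:
        return float("nan")
    counts = stats.subregion_count[list(annulus_indices)]
    means = stats.subregion_mean[list(annulus_indices)]
    if counts.sum() == 0:
        return float("nan")
    pooled = float(np.nansum(means * counts) / counts.sum())
    if pooled == 0 or not np.isfinite(pooled):
        return float("nan")
    return float(stats.subregion_mean[nucleus_index] / pooled)


# ---------------------------------------------------------------------------
# JSON I/O


def save_rois(rois: Iterable[DiscROI], path) -> None:
    payload = [
        {
            "disc_id": roi.disc_id,
            "slices": [
                {"index": int(z), "vertices": roi.slices[z].tolist()}
                for z in sorted(roi.slices)
            ],
        }
        for roi in rois
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_rois(path) -> list:
    with open(path) as fh:
        payload = json.load(fh)
    return [
        DiscROI(
            entry["disc_id"],
            {int(s["index"]): np.asarray(s["vertices"], dtype=float) for s in entry["slices"]},
        )
        for entry in payload
    ]
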