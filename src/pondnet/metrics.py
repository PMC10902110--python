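"""Per-pond connectivity predictors at taxon-specific spatial scales.

Around each pond three predictors are measured inside a circular zone:
the mean and standard deviation of current density, and the number of
neighbouring habitat patches (wetland/water centroids plus stormwater
facility points). The zone radius is taxon-specific and derived from a
literature table of daily flight distances: the maximum mean distance,
rounded to the nearest 100 m (900 m for dragonflies, 300 m for
damselflies in the flight data shipped with the synthetic module).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .circuit import CurrentMap
from .raster import Raster

__all__ = [
    "extract_buffer_stats",
    "count_neighbours",
    "polygon_centroids",
    "merge_habitat_points",
    "select_scale",
    "site_metrics_table",
]


def _as_raster(current_map) -> Raster:
    if isinstance(current_map, CurrentMap):
        return current_map.to_raster()
    return current_map


def extract_buffer_stats(
    current_map, x: float, y: float, radius_m: float, ddof: int = 1
) -> tuple[float, float]:
    """Mean and SD of map values whose cell centre lies within radius of (x, y).

    A cell belongs to the zone when its centre is at Euclidean distance
    <= radius (inclusive boundary). The SD is the sample SD (ddof=1) by
    default; with a single qualifying cell the SD is 0.
    """
    if radius_m <= 0:
        raise ValueError("radius must be > 0")
    ras = _as_raster(current_map)
    cx, cy = ras.cell_centers()
    sel = (cx - x) ** 2 + (cy - y) ** 2 <= radius_m**2
    vals = ras.values[sel]
    if vals.size == 0:
        raise ValueError(f"no cell centre within {radius_m} m of ({x}, {y})")
    mean = float(vals.mean())
    sd = 0.0 if vals.size < 2 else float(vals.std(ddof=ddof))
    return mean, sd


def count_neighbours(
    site_xy: tuple[float, float],
    radius_m: float,
    habitat_points: np.ndarray,
    self_exclusion_m: float = 5.0,
) -> int:
    """Number of habitat points within radius of the site (inclusive).

    Points closer than ``self_exclusion_m`` (default: half a 10 m cell)
    are treated as the focal pond itself and not counted.
    """
    if radius_m <= 0:
        raise ValueError("radius must be > 0")
    pts = np.asarray(habitat_points, dtype=float).reshape(-1, 2)
    if pts.size == 0:
        return 0
    d = np.hypot(pts[:, 0] - site_xy[0], pts[:, 1] - site_xy[1])
    return int(np.count_nonzero((d <= radius_m) & (d >= self_exclusion_m)))


def polygon_centroids(polygons, classes=None, exclude_classes=("large_rivers",)) -> np.ndarray:
    """Area-weighted centroids of habitat polygons, excluding listed classes.

    ``polygons`` is a sequence of shapely polygons; ``classes`` an
    optional parallel sequence of land-cover class names. Rivers are
    excluded by default because pond-breeding odonates do not use them
    as habitat. Degenerate zero-area polygons are dropped with a
    warning.
    """
    exclude = set(exclude_classes or ())
    out = []
    for i, poly in enumerate(polygons):
        cls = classes[i] if classes is not None else None
        if cls in exclude:
            continue
        if poly.area == 0:
            warnings.warn(f"dropping zero-area polygon at index {i}", stacklevel=2)
            continue
        c = poly.centroid
        out.append((c.x, c.y))
    return np.asarray(out, dtype=float).reshape(-1, 2)


def merge_habitat_points(
    centroids: np.ndarray,
    facility_points: pd.DataFrame | np.ndarray | None = None,
    status_col: str = "status",
    active_value: str = "active",
    dedup_m: float = 5.0,
) -> np.ndarray:
    """Merge habitat centroids with (active) stormwater facility points.

    Facility tables may carry a status column; only rows matching
    ``active_value`` are kept. Points closer than ``dedup_m`` to an
    earlier point are dropped as duplicates.
    """
    pts = [np.asarray(centroids, dtype=float).reshape(-1, 2)]
    if facility_points is not None:
        if isinstance(facility_points, pd.DataFrame):
            fac = facility_points
            if status_col in fac.columns:
                fac = fac[fac[status_col] == active_value]
            pts.append(fac[["x", "y"]].to_numpy(dtype=float))
        else:
            pts.append(np.asarray(facility_points, dtype=float).reshape(-1, 2))
    allpts = np.concatenate(pts, axis=0)
    keep = []
    for p in allpts:
        if all(np.hypot(p[0] - q[0], p[1] - q[1]) >= dedup_m for q in keep):
            keep.append(p)
    return np.asarray(keep).reshape(-1, 2)


def raster_habitat_centroids(
    landcover, habitat_classes=("wetlands", "water"), exclude_classes=("large_rivers",)
) -> np.ndarray:
    """Centroids of contiguous habitat patches on a categorical raster.

    The raster analogue of :func:`polygon_centroids`: connected
    components (8-connectivity) of cells in ``habitat_classes`` are
    treated as patches and their cell-centre means returned as points.
    """
    from scipy import ndimage

    from .raster import CLASS_CODES

    grid = landcover.values
    keep = np.isin(
        grid,
        [CLASS_CODES[c] for c in habitat_classes if c not in set(exclude_classes or ())],
    )
    labels, n = ndimage.label(keep, structure=np.ones((3, 3), int))
    if n == 0:
        return np.empty((0, 2))
    cx, cy = landcover.cell_centers()
    index = np.arange(1, n + 1)
    return np.column_stack(
        [ndimage.mean(cx, labels, index), ndimage.mean(cy, labels, index)]
    )


def select_scale(flights: pd.DataFrame, suborder: str) -> float:
    """Analysis radius for a suborder: max mean flight distance, rounded to 100 m.

    Rounding is half-up to the nearest 100 m.
    """
    sub = flights[flights["suborder"] == suborder]
    means = sub["mean_daily_distance_m"].dropna()
    if means.empty:
        raise ValueError(f"no flight-distance records for suborder {suborder!r}")
    best = float(means.max())
    return float(np.floor(best / 100.0 + 0.5) * 100.0)


def site_metrics_table(
    current_map,
    sites: pd.DataFrame,
    habitat_points: np.ndarray,
    scales: dict[str, float] | list[float] = (900.0, 300.0),
    self_exclusion_m: float = 5.0,
) -> pd.DataFrame:
    """Tidy per-(pond, scale) table of connectivity predictors.

    Columns: pond_id, scale_m, mean_current, sd_current, n_neighbours.
    """
    radii = sorted(set(scales.values())) if isinstance(scales, dict) else sorted(set(scales))
    rows = []
    for _, site in sites.iterrows():
        for radius in radii:
            mean, sd = extract_buffer_stats(current_map, site["x"], site["y"], radius)
            n_nb = count_neighbours(
                (site["x"], site["y"]), radius, habitat_points, self_exclusion_m=self_exclusion_m
            )
            rows.append(
                {
                    "pond_id": site["id"],
                    "scale_m": radius,
                    "mean_current": mean,
                    "sd_current": sd,
                    "n_neighbours": n_nb,
                }
            )
    return pd.DataFrame(rows)
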