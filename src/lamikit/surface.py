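"""Sample-surface interpolation and shape feature extraction.

The sample surface is a single-valued height map z(x, y) built by piecewise
linear (Delaunay) interpolation of picked 3D surface points, defined inside
the convex hull of their XY projections and undefined outside it.  Shape
features for a focal point are the in-tissue propagation distances of 12 rays
inclined at 20 degrees to the optical axis, measured by binary search against
the interpolated surface and binned into a nonlinear histogram with edges
``f(x) = x**1.5 * 350`` um over 13 equally spaced arguments on [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator, RegularGridInterpolator
from scipy.spatial import QhullError

__all__ = [
    "SurfaceMap",
    "ShapeFeatureConfig",
    "build_surface",
    "bin_edges",
    "ray_directions",
    "distance_to_surface",
    "distances_to_surface",
    "shape_histogram",
    "featurize",
    "featurize_points",
    "feature_names",
]


class SurfaceMap:
    """Piecewise-linear interpolant of picked surface points.

    Height queries return NaN outside the convex hull of the XY projections
    ("undefined"); the interpolant reproduces the input points exactly.  A
    cached regular-grid evaluation (bilinear lookup) accelerates the many
    height queries made during ray searches; it can be disabled for exact
    evaluation everywhere.
    """

    def __init__(self, points: np.ndarray, cache_spacing: float | None = 2.0):
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
            raise ValueError("need an (n >= 3, 3) array of surface points")
        xy = pts[:, :2]
        # vertical overhangs (duplicate XY with distinct z) break z(x, y)
        order = np.lexsort((xy[:, 1], xy[:, 0]))
        s = xy[order]
        dup = np.all(np.abs(np.diff(s, axis=0)) < 1e-9, axis=1)
        if np.any(dup):
            zdiff = np.abs(np.diff(pts[order][:, 2]))[dup]
            if np.any(zdiff > 1e-9):
                raise ValueError("surface points create a vertical overhang (duplicate XY, distinct z)")
        try:
            self._interp = LinearNDInterpolator(xy, pts[:, 2])
        except QhullError as err:  # collinear / degenerate
            raise ValueError("degenerate surface points (collinear or duplicated)") from err
        if self._interp.tri.npoints < 3 or len(self._interp.tri.simplices) == 0:
            raise ValueError("degenerate surface points (no triangulation)")
        self.points = pts
        self._cache = None
        if cache_spacing is not None:
            self._build_cache(cache_spacing)

    def _build_cache(self, spacing: float):
        lo = self.points[:, :2].min(axis=0)
        hi = self.points[:, :2].max(axis=0)
        xs = np.arange(lo[0], hi[0] + spacing, spacing)
        ys = np.arange(lo[1], hi[1] + spacing, spacing)
        if len(xs) < 2 or len(ys) < 2:
            return
        xg, yg = np.meshgrid(xs, ys, indexing="ij")
        vals = self._interp(np.column_stack([xg.ravel(), yg.ravel()])).reshape(xg.shape)
        self._cache = RegularGridInterpolator(
            (xs, ys), vals, method="linear", bounds_error=False, fill_value=np.nan
        )

    def height(self, x, y, exact: bool = False) -> np.ndarray:
        """Surface height z(x, y); NaN where undefined (outside the hull)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        q = np.column_stack([np.ravel(x), np.ravel(y)])
        if self._cache is not None and not exact:
            out = self._cache(q)
        else:
            out = self._interp(q)
        return out.reshape(np.broadcast(x, y).shape) if x.ndim else float(out[0])

    def above_or_undefined(self, points: np.ndarray) -> np.ndarray:
        """True where a 3D point is above the surface or outside the hull."""
        p = np.atleast_2d(points)
        h = self.height(p[:, 0], p[:, 1])
        h = np.atleast_1d(h)
        return np.isnan(h) | (p[:, 2] < h)


def build_surface(points: np.ndarray, cache_spacing: float | None = 2.0) -> SurfaceMap:
    return SurfaceMap(points, cache_spacing=cache_spacing)


@dataclass(frozen=True)
class ShapeFeatureConfig:
    """Parameters of the ray-distance shape descriptor."""

    phi_deg: float = 20.0     # inclination of all rays to the optical axis
    n_rays: int = 12
    n_edges: int = 13         # histogram edge count (n_rays + 1 bins edges)
    exponent: float = 1.5
    d_max: float = 350.0      # propagation distance beyond which no excitation is expected
    search_start: float = 2000.0
    search_tol: float = 1.0
    azimuth_phase: float = 0.0

    def __post_init__(self):
        if not 0.0 < self.phi_deg < 90.0:
            raise ValueError("phi must be in (0, 90) degrees")
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")


def bin_edges(config: ShapeFeatureConfig | None = None) -> np.ndarray:
    """Nonlinear histogram edges ``(k/(n_edges-1))**exponent * d_max``."""
    config = config or ShapeFeatureConfig()
    x = np.linspace(0.0, 1.0, config.n_edges)
    return x**config.exponent * config.d_max


def ray_directions(config: ShapeFeatureConfig | None = None) -> np.ndarray:
    """Unit ray directions: upward, inclined phi to the axis, equal azimuth steps."""
    config = config or ShapeFeatureConfig()
    phi = np.deg2rad(config.phi_deg)
    az = config.azimuth_phase + 2 * np.pi * np.arange(config.n_rays) / config.n_rays
    return np.column_stack(
        [np.sin(phi) * np.cos(az), np.sin(phi) * np.sin(az), -np.cos(phi) * np.ones_like(az)]
    )


def distances_to_surface(
    surface: SurfaceMap,
    points: np.ndarray,
    directions: np.ndarray,
    start: float = 2000.0,
    tol: float = 1.0,
) -> np.ndarray:
    """Binary-search distance from each point to the surface along each direction.

    For each (point, direction) pair the search brackets the smallest t such
    that ``point + t * direction`` is above the surface or undefined, starting
    from ``start`` and halving until within ``tol``.  Points already above the
    surface return 0 (with a warning); rays that never cross within ``start``
    return ``start``.
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    d = np.asarray(directions, dtype=float)
    if d.ndim == 1:
        d = np.tile(d, (len(p), 1))
    if len(d) != len(p):
        raise ValueError("points and directions must pair one-to-one")
    out = np.empty(len(p))
    already_above = surface.above_or_undefined(p)
    if np.any(already_above):
        warnings.warn("focal point already above the surface; distance set to 0")
    hi = np.full(len(p), float(start))
    lo = np.zeros(len(p))
    # ray end at `start` not yet above -> flagged at start
    end_above = surface.above_or_undefined(p + hi[:, None] * d)
    no_cross = ~end_above & ~already_above
    n_steps = int(np.ceil(np.log2(start / tol)))
    for _ in range(n_steps):
        mid = 0.5 * (lo + hi)
        above = surface.above_or_undefined(p + mid[:, None] * d)
        hi = np.where(above, mid, hi)
        lo = np.where(above, lo, mid)
    out[:] = hi
    out[already_above] = 0.0
    out[no_cross] = start
    return out


def distance_to_surface(
    surface: SurfaceMap,
    point,
    direction,
    start: float = 2000.0,
    tol: float = 1.0,
) -> float:
    return float(
        distances_to_surface(surface, np.atleast_2d(point), np.asarray(direction), start, tol)[0]
    )


def shape_histogram(
    surface: SurfaceMap,
    point,
    config: ShapeFeatureConfig | None = None,
) -> np.ndarray:
    """Histogram of ray distances for one focal point (counts sum to n_rays)."""
    config = config or ShapeFeatureConfig()
    dirs = ray_directions(config)
    p = np.tile(np.asarray(point, dtype=float), (config.n_rays, 1))
    dist = distances_to_surface(surface, p, dirs, config.search_start, config.search_tol)
    return _bin(dist[None, :], config)[0]


def _bin(distances: np.ndarray, config: ShapeFeatureConfig) -> np.ndarray:
    edges = bin_edges(config)
    # distances beyond d_max clamp into the last bin so counts always sum to n_rays
    d = np.clip(distances, 0.0, config.d_max)
    idx = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, len(edges) - 2)
    counts = np.zeros((len(distances), len(edges) - 1), dtype=int)
    for k in range(len(edges) - 1):
        counts[:, k] = (idx == k).sum(axis=1)
    return counts


def featurize(
    surface: SurfaceMap,
    point,
    brightness: float,
    field_xy,
    config: ShapeFeatureConfig | None = None,
) -> np.ndarray:
    """Feature vector [brightness, field_x, field_y, histogram counts...]."""
    config = config or ShapeFeatureConfig()
    counts = shape_histogram(surface, point, config)
    return np.concatenate([[brightness], np.asarray(field_xy, dtype=float), counts])


def featurize_points(
    surface: SurfaceMap,
    points: np.ndarray,
    brightness: np.ndarray,
    field_xy: np.ndarray,
    config: ShapeFeatureConfig | None = None,
) -> np.ndarray:
    """Vectorized featurization of many focal points -> (n, 3 + bins) array."""
    config = config or ShapeFeatureConfig()
    p = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(p)
    dirs = ray_directions(config)
    rep_p = np.repeat(p, config.n_rays, axis=0)
    rep_d = np.tile(dirs, (n, 1))
    dist = distances_to_surface(surface, rep_p, rep_d, config.search_start, config.search_tol)
    counts = _bin(dist.reshape(n, config.n_rays), config)
    return np.column_stack([np.asarray(brightness, dtype=float), np.asarray(field_xy, dtype=float), counts])


def feature_names(config: ShapeFeatureConfig | None = None) -> list[str]:
    config = config or ShapeFeatureConfig()
    return ["brightness", "field_x", "field_y"] + [
        f"dist_bin_{k}" for k in range(config.n_edges - 1)
    ]


def features_frame(features: np.ndarray, config: ShapeFeatureConfig | None = None) -> pd.DataFrame:
    return pd.DataFrame(np.atleast_2d(features), columns=feature_names(config))
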