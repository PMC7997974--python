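"""Closed convex sample geometries with analytic ray/surface queries.

Coordinate convention: right-handed, units are micrometers, and ``z``
increases with depth into the tissue (the objective sits at z = -inf).
A point is "below the surface" when its z exceeds the local top-surface
height ``surface_z(x, y)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FlatSlab", "Sphere", "Ellipsoid", "TwoLobe", "Geometry"]

_BIG = 1e9


class Geometry:
    """Interface for closed sample shapes (convex per lobe)."""

    def inside(self, points: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def path_lengths(self, points: np.ndarray, directions: np.ndarray) -> np.ndarray:
        """In-tissue path length from each interior point along each direction.

        Parameters
        ----------
        points : (n, 3) array
        directions : (m, 3) array of unit vectors

        Returns
        -------
        (n, m) array of path lengths (um).
        """
        raise NotImplementedError

    def surface_z(self, x, y):
        """Top-surface depth z(x, y); NaN outside the lateral footprint."""
        raise NotImplementedError

    def sample_surface(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Random points on the upper (objective-facing) surface."""
        raise NotImplementedError

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        raise NotImplementedError


@dataclass(frozen=True)
class FlatSlab(Geometry):
    """Semi-infinite flat sample with top surface at ``z0``."""

    z0: float = 0.0
    half_extent: float = 5000.0

    def inside(self, points):
        p = np.atleast_2d(points)
        lateral = (np.abs(p[:, 0]) <= self.half_extent) & (np.abs(p[:, 1]) <= self.half_extent)
        return (p[:, 2] >= self.z0) & lateral

    def path_lengths(self, points, directions):
        p = np.atleast_2d(points)
        d = np.atleast_2d(directions)
        dz = np.broadcast_to(d[:, 2][None, :], (p.shape[0], d.shape[0]))
        depth = (p[:, 2] - self.z0)[:, None]
        out = np.full(dz.shape, _BIG)
        up = dz < 0
        out[up] = np.broadcast_to(depth, dz.shape)[up] / (-dz[up])
        return out

    def surface_z(self, x, y):
        x = np.asarray(x, dtype=float)
        return np.broadcast_to(np.float64(self.z0), x.shape).copy() if x.shape else np.float64(self.z0)

    def sample_surface(self, n, rng):
        xy = rng.uniform(-self.half_extent, self.half_extent, size=(n, 2))
        return np.column_stack([xy, np.full(n, self.z0)])

    def bounding_box(self):
        lo = np.array([-self.half_extent, -self.half_extent, self.z0])
        hi = np.array([self.half_extent, self.half_extent, self.z0 + 2 * self.half_extent])
        return lo, hi


@dataclass(frozen=True)
class Ellipsoid(Geometry):
    """Axis-aligned ellipsoid with semi-axes (a, b, c) in (x, y, z)."""

    center: tuple[float, float, float] = (0.0, 0.0, 510.0)
    semiaxes: tuple[float, float, float] = (510.0, 510.0, 510.0)

    def __post_init__(self):
        if min(self.semiaxes) <= 0:
            raise ValueError("semiaxes must be positive")

    def _to_unit(self, points):
        return (np.atleast_2d(points) - np.asarray(self.center)) / np.asarray(self.semiaxes)

    def inside(self, points):
        q = self._to_unit(points)
        return np.einsum("ij,ij->i", q, q) <= 1.0

    def path_lengths(self, points, directions):
        q = self._to_unit(points)  # (n, 3)
        dd = np.atleast_2d(directions) / np.asarray(self.semiaxes)  # (m, 3)
        # |q + t d|^2 = 1  ->  (d.d) t^2 + 2 (q.d) t + (q.q - 1) = 0
        a = np.einsum("mj,mj->m", dd, dd)[None, :]
        b = np.einsum("nj,mj->nm", q, dd)
        c = (np.einsum("nj,nj->n", q, q) - 1.0)[:, None]
        disc = np.maximum(b * b - a * c, 0.0)
        t = (-b + np.sqrt(disc)) / a  # exit root (t >= 0 for interior points)
        return np.maximum(t, 0.0)

    def surface_z(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        cx, cy, cz = self.center
        a, b, c = self.semiaxes
        s = 1.0 - ((x - cx) / a) ** 2 - ((y - cy) / b) ** 2
        with np.errstate(invalid="ignore"):
            z = cz - c * np.sqrt(np.where(s >= 0, s, np.nan))
        return z

    def sample_surface(self, n, rng):
        # uniform on the upper half in parameter space (adequate for picking
        # interpolation points; exact area weighting is not required)
        v = rng.normal(size=(n, 3))
        v[:, 2] = -np.abs(v[:, 2])
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        return np.asarray(self.center) + v * np.asarray(self.semiaxes)

    def bounding_box(self):
        c = np.asarray(self.center)
        s = np.asarray(self.semiaxes)
        return c - s, c + s


def Sphere(center=(0.0, 0.0, 510.0), radius: float = 510.0) -> Ellipsoid:
    """Sphere as an ellipsoid with equal semi-axes."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    return Ellipsoid(center=tuple(center), semiaxes=(radius, radius, radius))


@dataclass(frozen=True)
class TwoLobe(Geometry):
    """Union of two spheres (a simple multi-lobed sample)."""

    centers: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        (-300.0, 0.0, 400.0),
        (300.0, 0.0, 400.0),
    )
    radii: tuple[float, float] = (400.0, 400.0)
    lobes: tuple[Ellipsoid, ...] = field(init=False)

    def __post_init__(self):
        if min(self.radii) <= 0:
            raise ValueError("radii must be positive")
        object.__setattr__(
            self,
            "lobes",
            tuple(Sphere(c, r) for c, r in zip(self.centers, self.radii)),
        )

    def inside(self, points):
        return np.logical_or.reduce([lb.inside(points) for lb in self.lobes])

    def path_lengths(self, points, directions):
        """Total in-tissue length = measure of the union of per-lobe intervals."""
        p = np.atleast_2d(points)
        d = np.atleast_2d(directions)
        intervals = []
        for lb in self.lobes:
            q = (p - np.asarray(lb.center)) / np.asarray(lb.semiaxes)
            dd = d / np.asarray(lb.semiaxes)
            a = np.einsum("mj,mj->m", dd, dd)[None, :]
            b = np.einsum("nj,mj->nm", q, dd)
            c = (np.einsum("nj,nj->n", q, q) - 1.0)[:, None]
            disc = b * b - a * c
            hit = disc > 0
            sq = np.sqrt(np.where(hit, disc, 0.0))
            t0 = np.where(hit, (-b - sq) / a, 0.0)
            t1 = np.where(hit, (-b + sq) / a, 0.0)
            t0 = np.clip(t0, 0.0, None)
            t1 = np.clip(t1, 0.0, None)
            intervals.append((t0, t1))
        (a0, a1), (b0, b1) = intervals
        # union length of [a0,a1] and [b0,b1]
        total = (a1 - a0) + (b1 - b0)
        lo = np.maximum(a0, b0)
        hi = np.minimum(a1, b1)
        overlap = np.maximum(hi - lo, 0.0)
        return total - overlap

    def surface_z(self, x, y):
        zs = np.stack([lb.surface_z(x, y) for lb in self.lobes])
        with np.errstate(invalid="ignore"):
            out = np.where(
                np.all(np.isnan(zs), axis=0), np.nan, np.nanmin(zs, axis=0)
            )
        return out

    def sample_surface(self, n, rng):
        pts = np.concatenate(
            [lb.sample_surface(n, rng) for lb in self.lobes], axis=0
        )
        # keep only points on the visible (upper) union surface
        z_top = self.surface_z(pts[:, 0], pts[:, 1])
        keep = np.abs(pts[:, 2] - z_top) < 1e-6
        pts = pts[keep]
        idx = rng.permutation(len(pts))[:n]
        return pts[idx]

    def bounding_box(self):
        los, his = zip(*(lb.bounding_box() for lb in self.lobes))
        return np.min(los, axis=0), np.max(his, axis=0)
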