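"""Synthetic scattering phantoms and the two-photon forward model.

This module generates the study conditions used throughout the package:
convex scattering samples (flat slab, sphere, ellipsoid, two-lobe) with a
homogeneous scattering mean free path ``ls``, "standard candle" cells with
lognormal labeling noise, and simulated acquisitions in which the noiseless
expected brightness of a candle is

    E = gain * b * vignette(x, y) * (P0 * A)**2

with ``A`` the pupil-weighted mean of ``exp(-d(ray)/ls)`` over in-tissue ray
path lengths ``d`` — the two-photon square law applied to the unscattered
fraction of the excitation power.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import Ellipsoid, FlatSlab, Geometry, Sphere, TwoLobe
from ._pupil import PupilModel

__all__ = [
    "ScatteringSample",
    "AcquisitionGrid",
    "make_sample",
    "seed_candles",
    "attenuation_factor",
    "attenuation_factor_mc",
    "simulate_acquisition",
    "render_tile",
    "rank_denoise",
]


@dataclass(frozen=True)
class ScatteringSample:
    """A closed convex (per lobe) sample with homogeneous scattering."""

    geometry: Geometry
    ls: float = 100.0  # scattering mean free path, um
    vignette_strength: float = 0.0  # relative sensitivity drop at the field corner

    def __post_init__(self):
        if not self.ls > 0:
            raise ValueError("scattering mean free path ls must be > 0")
        if not 0.0 <= self.vignette_strength < 1.0:
            raise ValueError("vignette_strength must be in [0, 1)")

    def vignette(self, field_x, field_y, fov: float) -> np.ndarray:
        """cos^4-like radial sensitivity profile over one field of view.

        Equal to 1 at the field center and ``1 - vignette_strength`` at the
        corners.
        """
        fx = np.asarray(field_x, dtype=float) - fov / 2
        fy = np.asarray(field_y, dtype=float) - fov / 2
        if self.vignette_strength == 0.0:
            return np.ones(np.broadcast(fx, fy).shape)
        rmax = fov / math.sqrt(2.0)
        theta_max = math.acos((1.0 - self.vignette_strength) ** 0.25)
        rho = np.minimum(np.hypot(fx, fy) / rmax, 1.0)
        return np.cos(rho * theta_max) ** 4


@dataclass(frozen=True)
class AcquisitionGrid:
    """Tiled raster acquisition layout."""

    fov: float = 220.0  # um
    pixels: int = 128
    z_step: float = 4.0  # um
    n_tiles: tuple[int, int] = (1, 1)
    overlap: float = 0.1
    origin: tuple[float, float] = (0.0, 0.0)
    z_range: tuple[float, float] = (0.0, 300.0)
    channels: int = 2

    def __post_init__(self):
        if self.z_step <= 0:
            raise ValueError("z step must be > 0")
        if not 0.0 <= self.overlap < 0.5:
            raise ValueError("overlap fraction must be in [0, 0.5)")

    @property
    def stride(self) -> float:
        return self.fov * (1.0 - self.overlap)

    def tile_origin(self, ix: int, iy: int) -> np.ndarray:
        return np.asarray(self.origin) + np.array([ix, iy]) * self.stride

    def assign_tiles(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Nearest tile index for each 3D point (by tile center)."""
        p = np.atleast_2d(points)
        nx, ny = self.n_tiles
        ix = np.clip(np.round((p[:, 0] - self.origin[0] - self.fov / 2) / self.stride), 0, nx - 1)
        iy = np.clip(np.round((p[:, 1] - self.origin[1] - self.fov / 2) / self.stride), 0, ny - 1)
        return ix.astype(int), iy.astype(int)

    def field_position(self, points: np.ndarray) -> np.ndarray:
        """XY position within the assigned tile's field of view."""
        p = np.atleast_2d(points)
        ix, iy = self.assign_tiles(p)
        origins = np.stack([self.tile_origin(i, j) for i, j in zip(ix, iy)])
        return p[:, :2] - origins

    def z_planes(self) -> np.ndarray:
        z0, z1 = self.z_range
        return np.arange(z0, z1 + 0.5 * self.z_step, self.z_step)


_GEOMETRIES = {"flat", "sphere", "ellipsoid", "two_lobe"}


def make_sample(
    geometry: str = "sphere",
    ls: float = 100.0,
    vignette_strength: float = 0.0,
    **shape_params,
) -> ScatteringSample:
    """Construct a phantom sample from a geometry name and shape parameters.

    Shape parameters (all um): ``radius``/``center`` for ``sphere``,
    ``semiaxes``/``center`` for ``ellipsoid``, ``z0`` for ``flat``,
    ``centers``/``radii`` for ``two_lobe``.
    """
    if geometry not in _GEOMETRIES:
        raise ValueError(f"unknown geometry {geometry!r}; choose from {sorted(_GEOMETRIES)}")
    if geometry == "flat":
        geom = FlatSlab(**shape_params)
    elif geometry == "sphere":
        geom = Sphere(**shape_params)
    elif geometry == "ellipsoid":
        geom = Ellipsoid(**shape_params)
    else:
        geom = TwoLobe(**shape_params)
    return ScatteringSample(geometry=geom, ls=ls, vignette_strength=vignette_strength)


def seed_candles(
    sample: ScatteringSample,
    n: int,
    brightness_cv: float = 0.2,
    seed: int | np.random.Generator = 0,
    max_depth: float = 300.0,
    min_depth: float = 4.0,
    lateral_margin: float = 0.0,
    lateral_extent: float | None = None,
) -> pd.DataFrame:
    """Seed standard-candle cells uniformly over the sample interior.

    Positions are uniform over the interior down to ``max_depth`` below the
    local top surface.  Intrinsic brightness factors ``b`` are lognormal with
    population mean 1 and coefficient of variation ``brightness_cv``,
    independent of position (labeling noise is not location specific).
    """
    if n < 1:
        raise ValueError("need n >= 1 candles")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lo, hi = sample.geometry.bounding_box()
    lo = lo + np.array([lateral_margin, lateral_margin, 0.0])
    hi = hi - np.array([lateral_margin, lateral_margin, 0.0])
    if lateral_extent is not None:
        cx, cy = (lo[0] + hi[0]) / 2, (lo[1] + hi[1]) / 2
        lo[0], hi[0] = max(lo[0], cx - lateral_extent), min(hi[0], cx + lateral_extent)
        lo[1], hi[1] = max(lo[1], cy - lateral_extent), min(hi[1], cy + lateral_extent)
    if np.any(hi <= lo):
        raise ValueError("empty sampling box after lateral restriction")
    pts = np.empty((0, 3))
    attempts = 0
    while len(pts) < n:
        attempts += 1
        if attempts > 1000:
            raise RuntimeError("rejection sampling stalled; relax depth/geometry constraints")
        cand = rng.uniform(lo, hi, size=(max(4 * n, 1000), 3))
        ok = sample.geometry.inside(cand)
        z_top = np.asarray(sample.geometry.surface_z(cand[:, 0], cand[:, 1]))
        depth = cand[:, 2] - z_top
        with np.errstate(invalid="ignore"):
            ok &= np.nan_to_num(depth, nan=-1.0) >= min_depth
            ok &= np.nan_to_num(depth, nan=1e9) <= max_depth
        pts = np.vstack([pts, cand[ok]])
    pts = pts[:n]
    if brightness_cv > 0:
        sigma = math.sqrt(math.log(1.0 + brightness_cv**2))
        b = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)
    else:
        b = np.ones(n)
    return pd.DataFrame(
        {"x": pts[:, 0], "y": pts[:, 1], "z": pts[:, 2], "b": b},
        index=pd.RangeIndex(n, name="candle_id"),
    )


def attenuation_factor(
    sample: ScatteringSample,
    focal_points: np.ndarray,
    pupil: PupilModel | None = None,
) -> np.ndarray:
    """Pupil-weighted attenuation A in (0, 1] at each interior focal point.

    ``A = sum_k w_k exp(-d_k / ls)`` over the pupil ray quadrature, with
    ``d_k`` the in-tissue path length of ray ``k`` from the focus to the
    sample boundary.  A = 1 when all path lengths are zero or ls -> inf.
    """
    pupil = pupil or PupilModel()
    p = np.atleast_2d(np.asarray(focal_points, dtype=float))
    if not np.all(sample.geometry.inside(p)):
        raise ValueError("focal point outside the sample")
    dirs, w = pupil.rays()
    d = sample.geometry.path_lengths(p, dirs)
    a = np.exp(-d / sample.ls) @ w
    return a if np.asarray(focal_points).ndim == 2 else float(a[0])


def attenuation_factor_mc(
    sample: ScatteringSample,
    focal_point: np.ndarray,
    pupil: PupilModel | None = None,
    n_rays: int = 100_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo oracle for :func:`attenuation_factor` (random pupil rays)."""
    pupil = pupil or PupilModel()
    p = np.atleast_2d(np.asarray(focal_point, dtype=float))
    if not np.all(sample.geometry.inside(p)):
        raise ValueError("focal point outside the sample")
    rng = np.random.default_rng(seed)
    dirs = pupil.sample_rays(n_rays, rng)
    d = sample.geometry.path_lengths(p, dirs)
    return float(np.exp(-d / sample.ls).mean())


def simulate_acquisition(
    sample: ScatteringSample,
    candles: pd.DataFrame,
    grid: AcquisitionGrid,
    power_policy,
    seed: int | np.random.Generator = 0,
    pupil: PupilModel | None = None,
    gain: float = 1.0,
    shot_noise: bool = False,
    read_noise_sd: float = 0.0,
) -> pd.DataFrame:
    """Simulate imaging every candle once and record applied power/brightness.

    ``power_policy(points, tile_index, rng)`` maps focal positions (n, 3) and
    the flat tile index to applied relative powers P0 (n,).  Policies that
    emulate the training protocol multiply a reference profile by a per-tile
    factor drawn uniformly from [0.5, 2].
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pupil = pupil or PupilModel()
    pos = candles[["x", "y", "z"]].to_numpy()
    ix, iy = grid.assign_tiles(pos)
    tile_flat = ix * grid.n_tiles[1] + iy
    field = grid.field_position(pos)
    a = attenuation_factor(sample, pos, pupil)
    p0 = np.empty(len(candles))
    for t in np.unique(tile_flat):
        m = tile_flat == t
        p0[m] = np.asarray(power_policy(pos[m], int(t), rng), dtype=float)
    if np.any(p0 < 0):
        raise ValueError("power_policy returned negative power")
    vig = sample.vignette(field[:, 0], field[:, 1], grid.fov)
    expected = gain * candles["b"].to_numpy() * vig * (p0 * a) ** 2
    brightness = expected
    if shot_noise:
        brightness = rng.poisson(expected).astype(float)
    if read_noise_sd > 0:
        brightness = brightness + rng.normal(0, read_noise_sd, size=len(brightness))
    return pd.DataFrame(
        {
            "candle_id": candles.index.to_numpy(),
            "x": pos[:, 0],
            "y": pos[:, 1],
            "z": pos[:, 2],
            "tile_ix": ix,
            "tile_iy": iy,
            "field_x": field[:, 0],
            "field_y": field[:, 1],
            "P0": p0,
            "attenuation": a,
            "expected": expected,
            "brightness": np.maximum(brightness, 0.0),
        }
    )


def render_tile(
    sample: ScatteringSample,
    candles: pd.DataFrame,
    records: pd.DataFrame,
    grid: AcquisitionGrid,
    tile: tuple[int, int] = (0, 0),
    blob_sigma: float = 2.0,
    shg_band: float = 8.0,
) -> np.ndarray:
    """Render one tile as a (channels, z, y, x) stack.

    Channel 0 holds candle fluorescence as 3D Gaussian blobs whose peak equals
    the recorded brightness; channel 1 is an SHG-like band hugging the sample
    surface.
    """
    origin = grid.tile_origin(*tile)
    zs = grid.z_planes()
    px = grid.fov / grid.pixels
    vol = np.zeros((2, len(zs), grid.pixels, grid.pixels))
    # surface channel
    xs = origin[0] + (np.arange(grid.pixels) + 0.5) * px
    ys = origin[1] + (np.arange(grid.pixels) + 0.5) * px
    xg, yg = np.meshgrid(xs, ys, indexing="xy")
    z_top = np.asarray(sample.geometry.surface_z(xg.ravel(), yg.ravel())).reshape(xg.shape)
    for k, z in enumerate(zs):
        with np.errstate(invalid="ignore"):
            band = np.abs(z - z_top) < shg_band
        vol[1, k][np.nan_to_num(band, nan=False).astype(bool)] = 1.0
    # candle channel
    m = (records["tile_ix"] == tile[0]) & (records["tile_iy"] == tile[1])
    recs = records[m]
    half = int(np.ceil(3 * blob_sigma / px))
    for _, r in recs.iterrows():
        cx = (r["x"] - origin[0]) / px - 0.5
        cy = (r["y"] - origin[1]) / px - 0.5
        jx, jy = int(round(cx)), int(round(cy))
        x0, x1 = max(jx - half, 0), min(jx + half + 1, grid.pixels)
        y0, y1 = max(jy - half, 0), min(jy + half + 1, grid.pixels)
        if x0 >= x1 or y0 >= y1:
            continue
        lx = (np.arange(x0, x1) - cx) * px
        ly = (np.arange(y0, y1) - cy) * px
        lz = zs - r["z"]
        gz = np.exp(-0.5 * (lz / blob_sigma) ** 2)
        gy = np.exp(-0.5 * (ly / blob_sigma) ** 2)
        gx = np.exp(-0.5 * (lx / blob_sigma) ** 2)
        vol[0, :, y0:y1, x0:x1] += r["brightness"] * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
    return vol


def rank_denoise(
    scan_a: np.ndarray,
    scan_b: np.ndarray,
    window: int = 3,
    rank: int | None = None,
    gaussian_sigma: float = 2.0,
    apply_gaussian: bool = True,
) -> np.ndarray:
    """Two-scan rank filtering followed by a 2D Gaussian smooth.

    For each pixel the filter pools the ``window x window`` neighborhood from
    both repeated scans (2 * window**2 samples) and keeps the ``rank``-th
    smallest (default: the lower median), which suppresses impulsive outliers
    present in only one scan.  A per-plane Gaussian (sigma in pixels) is then
    applied unless disabled.
    """
    a = np.asarray(scan_a, dtype=float)
    b = np.asarray(scan_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("the two scans must have the same shape")
    if a.ndim == 2:
        return _rank_plane(a, b, window, rank, gaussian_sigma, apply_gaussian)
    out = np.empty_like(a)
    for k in range(a.shape[0]):
        out[k] = _rank_plane(a[k], b[k], window, rank, gaussian_sigma, apply_gaussian)
    return out


def _rank_plane(a, b, window, rank, sigma, apply_gaussian):
    pad = window // 2
    n_samples = 2 * window * window
    if rank is None:
        rank = n_samples // 2 - 1  # lower median
    windows = []
    for plane in (a, b):
        padded = np.pad(plane, pad, mode="reflect")
        sw = np.lib.stride_tricks.sliding_window_view(padded, (window, window))
        windows.append(sw.reshape(*plane.shape, window * window))
    samples = np.concatenate(windows, axis=-1)
    out = np.partition(samples, rank, axis=-1)[..., rank]
    if apply_gaussian and sigma > 0:
        out = ndimage.gaussian_filter(out, sigma, mode="reflect")
    return out
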