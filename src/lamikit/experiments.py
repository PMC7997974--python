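"""End-to-end calibration experiments on synthetic phantoms.

These functions reproduce the standard-candle calibration protocol in
silico: seed candles in a scattering phantom, image each with a reference
power profile multiplied by a per-tile random factor in [0.5, 2], featurize
against the interpolated surface, train the power predictor, and compare
achieved-brightness uniformity on a differently shaped held-out phantom
under three strategies (constant power, the sphere-assumption ray-optics
model, and the learned predictor).
"""

from __future__ import annotations

import numpy as np

from . import phantom, rayoptics
from ._pupil import PupilModel
from .powernet import EomCalibration, PowerRegressor
from .surface import ShapeFeatureConfig, SurfaceMap, featurize_points

__all__ = [
    "upper_surface_points",
    "surface_slope_angle",
    "fit_sphere",
    "lut_power_policy",
    "run_candle_calibration",
    "evaluate_strategies",
]


def upper_surface_points(
    sample: phantom.ScatteringSample,
    n: int = 800,
    seed: int = 0,
    max_angle_deg: float = 65.0,
) -> np.ndarray:
    """Surface points restricted to the objective-facing cap (no overhangs)."""
    rng = np.random.default_rng(seed)
    pts = np.empty((0, 3))
    cos_cap = np.cos(np.deg2rad(max_angle_deg))
    while len(pts) < n:
        cand = sample.geometry.sample_surface(4 * n, rng)
        z_top = np.asarray(sample.geometry.surface_z(cand[:, 0], cand[:, 1]))
        on_top = np.abs(cand[:, 2] - z_top) < 1e-6
        # cap by the local slope of the height map
        gx, gy = _height_gradient(sample, cand[:, 0], cand[:, 1])
        slope_ok = 1.0 / np.sqrt(1.0 + gx**2 + gy**2) >= cos_cap
        keep = on_top & np.nan_to_num(slope_ok, nan=False).astype(bool)
        pts = np.vstack([pts, cand[keep]])
    return pts[:n]


def _height_gradient(sample, x, y, h=2.0):
    z0 = np.asarray(sample.geometry.surface_z(x, y))
    zx = np.asarray(sample.geometry.surface_z(x + h, y))
    zy = np.asarray(sample.geometry.surface_z(x, y + h))
    return (zx - z0) / h, (zy - z0) / h


def surface_slope_angle(smap: SurfaceMap, x, y, h: float = 4.0) -> np.ndarray:
    """Surface normal angle (deg from vertical) from height-map differences."""
    z0 = np.atleast_1d(smap.height(x, y))
    zx = np.atleast_1d(smap.height(np.asarray(x) + h, y))
    zy = np.atleast_1d(smap.height(x, np.asarray(y) + h))
    zx2 = np.atleast_1d(smap.height(np.asarray(x) - h, y))
    zy2 = np.atleast_1d(smap.height(x, np.asarray(y) - h))
    gx = np.where(np.isnan(zx), (z0 - zx2) / h, (zx - z0) / h)
    gy = np.where(np.isnan(zy), (z0 - zy2) / h, (zy - z0) / h)
    gx = np.nan_to_num(gx)
    gy = np.nan_to_num(gy)
    return np.degrees(np.arctan(np.hypot(gx, gy)))


def fit_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares sphere (center, radius) through 3D surface points.

    Linearized fit: ||p||^2 = 2 p.c + (R^2 - ||c||^2).
    """
    p = np.asarray(points, dtype=float)
    A = np.column_stack([2 * p, np.ones(len(p))])
    b = (p**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    radius = float(np.sqrt(sol[3] + center @ center))
    return center, radius


def sphere_depth_angle(points: np.ndarray, center: np.ndarray, radius: float):
    """Vertical depth below, and normal angle at, the fitted sphere's top surface."""
    p = np.atleast_2d(points)
    rho2 = (p[:, 0] - center[0]) ** 2 + (p[:, 1] - center[1]) ** 2
    rho2 = np.minimum(rho2, (0.95 * radius) ** 2)
    z_top = center[2] - np.sqrt(radius**2 - rho2)
    depth = p[:, 2] - z_top
    angle = np.degrees(np.arcsin(np.sqrt(rho2) / radius))
    return depth, angle


def lut_power_policy(
    lut: rayoptics.AttenuationLUT,
    smap: SurfaceMap,
    base_power: float,
    randomize: bool = True,
    low: float = 0.5,
    high: float = 2.0,
    max_power: float = 1.0,
):
    """Reference power profile from the sphere LUT, optionally randomized.

    Returns a policy ``f(points, tile, rng) -> P0`` that multiplies
    ``base_power * lut(depth, normal angle)`` by one uniform factor in
    [low, high] per tile, clipped to ``max_power``.
    """

    def policy(points, tile, rng):
        p = np.atleast_2d(points)
        depth = p[:, 2] - np.atleast_1d(smap.height(p[:, 0], p[:, 1]))
        depth = np.nan_to_num(depth, nan=0.0)
        angle = surface_slope_angle(smap, p[:, 0], p[:, 1])
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            rel = np.atleast_1d(lut.lookup(np.clip(depth, lut.depths[0], None), angle))
        factor = rng.uniform(low, high) if randomize else 1.0
        return np.clip(base_power * rel * factor, 0.0, max_power)

    return policy


def run_candle_calibration(
    sample: phantom.ScatteringSample,
    n_candles: int = 10_000,
    seed: int = 0,
    base_power: float = 0.025,
    gain: float = 8e5,
    brightness_cv: float = 0.2,
    shot_noise: bool = True,
    pupil: PupilModel | None = None,
    calibration: EomCalibration | None = None,
    config: ShapeFeatureConfig | None = None,
    n_surface_points: int = 800,
    lateral_extent: float = 250.0,
    lut: rayoptics.AttenuationLUT | None = None,
) -> dict:
    """One simulated standard-candle calibration run.

    Returns a dict with the surface map, feature matrix, voltages, records,
    candles, and the LUT/calibration used.
    """
    pupil = pupil or PupilModel()
    calibration = calibration or EomCalibration.default()
    config = config or ShapeFeatureConfig()
    smap = SurfaceMap(upper_surface_points(sample, n_surface_points, seed=seed))
    if lut is None:
        lut = rayoptics.precompute_lut(pupil, radius=510.0, ls=sample.ls)
    candles = phantom.seed_candles(
        sample, n_candles, brightness_cv=brightness_cv, seed=seed + 1,
        max_depth=300.0, lateral_extent=lateral_extent,
    )
    grid = phantom.AcquisitionGrid(n_tiles=(3, 3), origin=(-308.0, -308.0))
    policy = lut_power_policy(lut, smap, base_power)
    records = phantom.simulate_acquisition(
        sample, candles, grid, policy, seed=seed + 2, pupil=pupil,
        gain=gain, shot_noise=shot_noise,
    )
    feats = featurize_points(
        smap,
        records[["x", "y", "z"]].to_numpy(),
        records["brightness"].to_numpy(),
        records[["field_x", "field_y"]].to_numpy(),
        config,
    )
    voltages = calibration.voltage(records["P0"].to_numpy())
    return {
        "surface_map": smap,
        "features": feats,
        "voltages": voltages,
        "records": records,
        "candles": candles,
        "lut": lut,
        "calibration": calibration,
        "grid": grid,
        "gain": gain,
        "base_power": base_power,
    }


def evaluate_strategies(
    predictor: PowerRegressor,
    test_sample: phantom.ScatteringSample,
    lut: rayoptics.AttenuationLUT,
    gain: float,
    n_points: int = 2000,
    seed: int = 99,
    pupil: PupilModel | None = None,
    n_surface_points: int = 800,
    lateral_extent: float = 250.0,
    shallow_depth: float = 25.0,
) -> dict:
    """Compare LAMI, the spherical ray-optics model and constant power.

    Probes are unit-brightness test points spread through the held-out
    sample down to 300 um.  For each strategy the achieved (noiseless)
    brightness is computed from the forward model and summarized by its
    coefficient of variation; the learned predictor is additionally scored by
    its median relative power error against the forward-model oracle.
    The constant strategy applies the power appropriate for the shallow
    (first ~25 um) shell, the simplest baseline.
    """
    pupil = pupil or PupilModel()
    cal = predictor.calibration_
    smap = SurfaceMap(upper_surface_points(test_sample, n_surface_points, seed=seed))
    probes = phantom.seed_candles(
        test_sample, n_points, brightness_cv=0.0, seed=seed + 1,
        max_depth=300.0, lateral_extent=lateral_extent,
    )
    grid = phantom.AcquisitionGrid(n_tiles=(3, 3), origin=(-308.0, -308.0))
    pos = probes[["x", "y", "z"]].to_numpy()
    field = grid.field_position(pos)
    a_true = phantom.attenuation_factor(test_sample, pos, pupil)
    vig = test_sample.vignette(field[:, 0], field[:, 1], grid.fov)

    # target brightness = training mean (z-score 0)
    f_target = float(predictor.scaler_.mean_[0])
    p_oracle = np.sqrt(f_target / (gain * vig)) / a_true

    _, p_lami = predictor.predict_at(smap, pos, field, target_z=0.0)
    depth = pos[:, 2] - np.atleast_1d(smap.height(pos[:, 0], pos[:, 1]))
    depth = np.nan_to_num(depth, nan=0.0)
    # the ray-optics baseline assumes an a priori perfectly spherical sample:
    # depth and normal angle come from a sphere fitted to the surface points,
    # not from the true surface, reproducing its model mismatch on non-spheres
    center, radius = fit_sphere(smap.points)
    sph_depth, sph_angle = sphere_depth_angle(pos, center, radius)
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        rel = np.atleast_1d(
            lut.lookup(np.clip(sph_depth, lut.depths[0], None), sph_angle)
        )
    p_ray = np.sqrt(f_target / gain) * rel
    shallow = depth <= shallow_depth
    p_const = float(np.median(p_oracle[shallow])) if shallow.any() else float(np.median(p_oracle))

    def brightness(p_applied):
        return gain * vig * (np.clip(p_applied, 0, cal.max_power) * a_true) ** 2

    def cv(values):
        return float(np.std(values) / np.mean(values))

    rel_err = np.abs(p_lami - p_oracle) / p_oracle
    return {
        "median_rel_power_error": float(np.median(rel_err)),
        "cv_lami": cv(brightness(p_lami)),
        "cv_rayoptics": cv(brightness(p_ray)),
        "cv_constant": cv(brightness(np.full(len(pos), p_const))),
        "depth": depth,
        "p_oracle": p_oracle,
        "p_lami": p_lami,
        "p_ray": p_ray,
        "surface_map": smap,
        "probes": probes,
    }
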