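"""Ray-optics spherical excitation model and imageable-volume accounting.

Relative excitation power is the factor by which incident power must be
increased to obtain the same fluorescence as without scattering, i.e. the
reciprocal of the pupil-weighted attenuation ``A = sum_k w_k exp(-d_k/ls)``
over analytic sphere-line in-tissue path lengths.  Because marginal rays cut
shorter chords through a convex sample than through a flat one, the required
power grows sub-exponentially with depth (log-power concave), unlike the flat
sample's exact exponential.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from ._pupil import PupilModel
from .geometry import Geometry, Sphere

__all__ = [
    "PupilModel",
    "AttenuationLUT",
    "VolumeModel",
    "relative_power",
    "precompute_lut",
    "required_power_profile",
    "imageable_volume",
    "volume_table",
]


def relative_power(
    pupil: PupilModel,
    geometry: Geometry,
    focal_points: np.ndarray,
    ls: float,
) -> np.ndarray:
    """Relative excitation power 1/A at interior focal points (>= 1)."""
    p = np.atleast_2d(np.asarray(focal_points, dtype=float))
    if not np.all(geometry.inside(p)):
        raise ValueError("focal point outside the sample")
    dirs, w = pupil.rays()
    d = geometry.path_lengths(p, dirs)
    a = np.exp(-d / ls) @ w
    out = 1.0 / a
    return out if np.asarray(focal_points).ndim == 2 else float(out[0])


@dataclass
class AttenuationLUT:
    """Precomputed relative power over (vertical depth, surface normal angle).

    The sphere model is fully parameterized by the vertical distance from the
    focal point to the surface and the normal angle at that surface point, so
    a 2D bilinear table reproduces it everywhere.
    """

    depths: np.ndarray           # um, strictly increasing
    angles: np.ndarray           # degrees from vertical, strictly increasing
    values: np.ndarray           # (n_depth, n_angle) relative power
    radius: float
    ls: float
    _interp: RegularGridInterpolator = field(init=False, repr=False)

    def __post_init__(self):
        if np.any(np.diff(self.depths) <= 0) or np.any(np.diff(self.angles) <= 0):
            raise ValueError("LUT grids must be strictly increasing")
        self._interp = RegularGridInterpolator(
            (self.depths, self.angles), self.values, method="linear",
            bounds_error=False, fill_value=None,
        )

    def lookup(self, depth, angle) -> np.ndarray:
        """Bilinear lookup; queries outside the grid are clamped with a warning."""
        d = np.asarray(depth, dtype=float)
        a = np.asarray(angle, dtype=float)
        if (
            np.any(d < self.depths[0]) or np.any(d > self.depths[-1])
            or np.any(a < self.angles[0]) or np.any(a > self.angles[-1])
        ):
            warnings.warn("LUT query outside grid; clamping to bounds")
        d = np.clip(d, self.depths[0], self.depths[-1])
        a = np.clip(a, self.angles[0], self.angles[-1])
        out = self._interp(np.column_stack([np.ravel(d), np.ravel(a)]))
        return out.reshape(np.broadcast(d, a).shape) if d.ndim else float(out[0])

    def to_dict(self) -> dict:
        return {
            "depths": self.depths.tolist(),
            "angles": self.angles.tolist(),
            "values": self.values.tolist(),
            "radius": self.radius,
            "ls": self.ls,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AttenuationLUT":
        return cls(
            depths=np.asarray(d["depths"], dtype=float),
            angles=np.asarray(d["angles"], dtype=float),
            values=np.asarray(d["values"], dtype=float),
            radius=d["radius"],
            ls=d["ls"],
        )


def _sphere_point_at(radius: float, depth: float, angle_deg: float) -> np.ndarray | None:
    """Focal point at `depth` vertically below a surface point whose normal is
    `angle_deg` from vertical, for a sphere of given radius centered at
    (0, 0, radius).  None when the point falls outside the sphere."""
    psi = math.radians(angle_deg)
    # surface point on the upper hemisphere; outward normal makes angle psi with -z
    sx = radius * math.sin(psi)
    sz = radius - radius * math.cos(psi)
    p = np.array([sx, 0.0, sz + depth])
    if (p[0] ** 2 + p[1] ** 2 + (p[2] - radius) ** 2) >= radius**2:
        return None
    return p


def precompute_lut(
    pupil: PupilModel,
    radius: float = 510.0,
    ls: float = 100.0,
    depths: np.ndarray | None = None,
    angles: np.ndarray | None = None,
) -> AttenuationLUT:
    """Tabulate sphere relative power over a (depth, normal-angle) grid."""
    depths = np.asarray(depths if depths is not None else np.linspace(1.0, 320.0, 50))
    angles = np.asarray(angles if angles is not None else np.linspace(0.0, 60.0, 20))
    sphere = Sphere(center=(0.0, 0.0, radius), radius=radius)
    vals = np.ones((len(depths), len(angles)))
    for i, dep in enumerate(depths):
        for j, ang in enumerate(angles):
            p = _sphere_point_at(radius, float(dep), float(ang))
            if p is None:
                vals[i, j] = vals[i - 1, j] if i > 0 else 1.0
                continue
            vals[i, j] = relative_power(pupil, sphere, p, ls)
    return AttenuationLUT(depths=depths, angles=angles, values=vals, radius=radius, ls=ls)


def required_power_profile(
    pupil: PupilModel,
    geometry: Geometry,
    ls: float,
    depths: np.ndarray,
    line_xy: tuple[float, float] = (0.0, 0.0),
    surface_z: float | None = None,
) -> pd.DataFrame:
    """Relative power along a vertical line, with a log-linearity diagnostic.

    The second difference of log power is ~0 for an exact exponential and
    negative (concave) for the sub-exponential profile of a convex sample.
    """
    depths = np.asarray(depths, dtype=float)
    x, y = line_xy
    z0 = surface_z if surface_z is not None else float(np.asarray(geometry.surface_z(x, y)))
    pts = np.column_stack([np.full_like(depths, x), np.full_like(depths, y), z0 + depths])
    power = relative_power(pupil, geometry, pts, ls)
    logp = np.log(power)
    d2 = np.full_like(depths, np.nan)
    if len(depths) >= 3:
        d2[1:-1] = np.diff(logp, 2) / np.diff(depths)[:-1] ** 2
    return pd.DataFrame({"depth": depths, "relative_power": power, "log_power": logp, "d2_log_power": d2})


@dataclass(frozen=True)
class VolumeModel:
    """Imageable-volume accounting for illumination strategies.

    strategy:
      constant          - thin spherical shell (thickness ``shell``) times a
                          quarter factor for the un-shadowed fraction
      exponential_h     - exponential-with-depth modulation, valid to depth h
                          within lateral radius r (cylinder pi r^2 h)
      arbitrary_h_r     - arbitrary z-profile, valid to depth h within radius r
      surface_offset_r  - arbitrary profile offset from the sample top, wider
                          validity radius r
      lami              - full shell from the surface down to ``max_depth``
    """

    strategy: str = "lami"
    radius: float = 510.0
    shell: float = 25.0
    quarter_factor: float = 0.25
    h: float = 140.0
    r: float = 125.0
    max_depth: float = 300.0

    def __post_init__(self):
        if not 0 < self.shell < self.radius:
            raise ValueError("require 0 < shell thickness < radius")
        if not 0 < self.h <= self.radius:
            raise ValueError("require 0 < h <= radius")


def _shell_volume(outer: float, inner: float) -> float:
    return 4.0 / 3.0 * math.pi * (outer**3 - inner**3)


def imageable_volume(model: VolumeModel) -> float:
    """Volume (um^3) to which the strategy can deliver appropriate power."""
    r_out = model.radius
    if model.strategy == "constant":
        return _shell_volume(r_out, r_out - model.shell) * model.quarter_factor
    if model.strategy == "lami":
        return _shell_volume(r_out, r_out - model.max_depth)
    if model.strategy in ("exponential_h", "arbitrary_h_r", "surface_offset_r"):
        # intermediate rows: cylinder of validity radius r and depth reach h
        # (an assumption; the strategies constrain only h and r)
        return math.pi * model.r**2 * model.h
    raise ValueError(f"unknown strategy {model.strategy!r}")


def volume_table(radius: float = 510.0, ls: float = 100.0) -> pd.DataFrame:
    """Default strategy comparison with the volume ratio against constant power."""
    rows = [
        VolumeModel(strategy="constant", radius=radius),
        VolumeModel(strategy="exponential_h", radius=radius, h=140.0, r=125.0),
        VolumeModel(strategy="arbitrary_h_r", radius=radius, h=300.0, r=125.0),
        VolumeModel(strategy="surface_offset_r", radius=radius, h=300.0, r=250.0),
        VolumeModel(strategy="lami", radius=radius, max_depth=300.0),
    ]
    vols = [imageable_volume(m) for m in rows]
    return pd.DataFrame(
        {
            "strategy": [m.strategy for m in rows],
            "volume_um3": vols,
            "ratio_vs_constant": [v / vols[0] for v in vols],
        }
    )
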