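"""Objective pupil model: quadrature over the excitation ray bundle.

The back focal plane carries a Gaussian-amplitude beam with zero phase; each
point of the pupil maps to a ray converging on the focus at polar angle
theta with sin(theta) = rho * NA / n (rho in [0, 1] the normalized pupil
radius).  Per-ray power weights are proportional to the Gaussian *intensity*
times the annulus area, normalized to sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = ["PupilModel"]


@dataclass(frozen=True)
class PupilModel:
    na: float = 1.05
    index: float = 1.33
    fill_factor: float = 1.0  # 1/e amplitude radius in units of the pupil radius
    n_radial: int = 12
    n_azimuthal: int = 24

    def __post_init__(self):
        if not 0.0 <= self.na < self.index:
            raise ValueError("require 0 <= NA < immersion index")

    @classmethod
    def paraxial(cls) -> "PupilModel":
        """Pupil collapsed to the single axial ray."""
        return cls(na=0.0, n_radial=1, n_azimuthal=1)

    def rays(self) -> tuple[np.ndarray, np.ndarray]:
        """Deterministic quadrature nodes.

        Returns
        -------
        directions : (m, 3) unit vectors pointing *up* out of the sample
            (dz <= 0), i.e. the reversed propagation direction from the focus
            back toward the objective.
        weights : (m,) normalized power weights.
        """
        return _rays_cached(self.na, self.index, self.fill_factor, self.n_radial, self.n_azimuthal)

    def sample_rays(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Monte-Carlo ray directions drawn from the pupil power density."""
        if self.na == 0.0:
            return np.tile([0.0, 0.0, -1.0], (n, 1))
        # rejection-sample rho from p(rho) ~ exp(-2 rho^2 / f^2) * rho on [0, 1]
        f2 = self.fill_factor**2
        out = np.empty(n)
        filled = 0
        while filled < n:
            cand = rng.uniform(0, 1, size=2 * (n - filled))
            u = rng.uniform(0, 1, size=cand.size)
            acc = cand[u < cand * np.exp(-2 * cand**2 / f2)]
            take = acc[: n - filled]
            out[filled : filled + take.size] = take
            filled += take.size
        phi = rng.uniform(0, 2 * np.pi, size=n)
        sin_t = out * self.na / self.index
        cos_t = np.sqrt(1 - sin_t**2)
        return np.column_stack(
            [sin_t * np.cos(phi), sin_t * np.sin(phi), -cos_t]
        )


@lru_cache(maxsize=32)
def _rays_cached(na, index, fill_factor, n_radial, n_azimuthal):
    if na == 0.0 or n_radial * n_azimuthal == 1:
        return np.array([[0.0, 0.0, -1.0]]), np.array([1.0])
    rho = (np.arange(n_radial) + 0.5) / n_radial
    phi = 2 * np.pi * np.arange(n_azimuthal) / n_azimuthal
    w_r = np.exp(-2 * rho**2 / fill_factor**2) * rho
    rho_g, phi_g = np.meshgrid(rho, phi, indexing="ij")
    w = np.repeat(w_r, n_azimuthal)
    w = w / w.sum()
    sin_t = (rho_g * na / index).ravel()
    cos_t = np.sqrt(1 - sin_t**2)
    dirs = np.column_stack(
        [sin_t * np.cos(phi_g.ravel()), sin_t * np.sin(phi_g.ravel()), -cos_t]
    )
    return dirs, w
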