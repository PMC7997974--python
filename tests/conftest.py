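"""Shared fixtures: phantoms, surface maps, synthetic stacks and tracks."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from lamikit import phantom
from lamikit._pupil import PupilModel
from lamikit.experiments import upper_surface_points
from lamikit.surface import SurfaceMap


@pytest.fixture(scope="session")
def pupil():
    return PupilModel()


@pytest.fixture(scope="session")
def sphere_sample():
    return phantom.make_sample("sphere", ls=100.0, center=(0.0, 0.0, 510.0), radius=510.0)


@pytest.fixture(scope="session")
def sphere_surface_map(sphere_sample):
    return SurfaceMap(upper_surface_points(sphere_sample, 1200, seed=1))


@pytest.fixture(scope="session")
def flat_surface_map():
    rng = np.random.default_rng(0)
    pts = np.column_stack([rng.uniform(-500, 500, (60, 2)), np.zeros(60)])
    return SurfaceMap(pts)


def make_cell_volume(shape, n_cells, seed=0, radius=2.0, z_radius=1.6, smooth=0.5):
    """Dense sharp-edged cell phantom used by the registration tests."""
    rng = np.random.default_rng(seed)
    vol = np.zeros(shape)
    zz, yy, xx = np.indices(shape).astype(float)
    for _ in range(n_cells):
        c = rng.uniform([1, 3, 3], [shape[0] - 1, shape[1] - 3, shape[2] - 3])
        a = rng.uniform(0.6, 1.4)
        vol += a * ((((zz - c[0]) / z_radius) ** 2 + ((yy - c[1]) / radius) ** 2 + ((xx - c[2]) / radius) ** 2) < 1.0)
    return ndimage.gaussian_filter(vol, smooth)


@pytest.fixture()
def cell_volume():
    return make_cell_volume((10, 64, 64), 400, seed=0)


def make_random_walk_tracks(n_tracks, n_steps=60, diffusivity=2.0, dt=0.5, seed=0, confine=None):
    from lamikit.motility import Track

    tracks = []
    for i in range(n_tracks):
        rng = np.random.default_rng(seed + i)
        steps = rng.normal(0, np.sqrt(2 * diffusivity * dt), size=(n_steps, 3))
        pos = np.cumsum(steps, axis=0)
        if confine is not None:
            for k in range(1, n_steps):
                nrm = np.linalg.norm(pos[k])
                if nrm > confine:
                    pos[k] = pos[k] / nrm * confine
        tracks.append(Track(i, np.arange(n_steps) * dt, pos))
    return tracks
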