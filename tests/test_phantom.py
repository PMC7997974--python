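"""Phantom forward model: geometry, candles, attenuation, acquisition, denoising."""

import numpy as np
import pandas as pd
import pytest

from lamikit import phantom
from lamikit._pupil import PupilModel
from lamikit.geometry import FlatSlab, Sphere, TwoLobe


class TestMakeSample:
    def test_sphere_inside_outside(self, sphere_sample):
        g = sphere_sample.geometry
        assert g.inside(np.array([[0.0, 0.0, 510.0]]))[0]
        assert not g.inside(np.array([[0.0, 0.0, 510.0 + 511.0]]))[0]

    def test_flat_surface_constant(self):
        s = phantom.make_sample("flat", ls=50.0)
        x = np.linspace(-200, 200, 9)
        assert np.allclose(s.geometry.surface_z(x, x), 0.0)

    def test_two_lobe_surface_has_two_maxima(self):
        s = phantom.make_sample("two_lobe", ls=100.0)
        xs = np.linspace(-700, 700, 141)
        z = np.asarray(s.geometry.surface_z(xs, np.zeros_like(xs)))
        # top surface height minima (shallowest z) at the two lobe apices
        finite = np.nan_to_num(z, nan=np.inf)
        interior = finite[1:-1]
        local_min = (interior < finite[:-2]) & (interior <= finite[2:])
        apices = xs[1:-1][local_min & np.isfinite(interior)]
        assert len(apices) == 2
        assert np.allclose(sorted(apices), [-300, 300], atol=15)

    def test_nonpositive_ls_rejected(self):
        with pytest.raises(ValueError, match="mean free path"):
            phantom.make_sample("sphere", ls=0.0)

    def test_degenerate_shape_rejected(self):
        with pytest.raises(ValueError):
            phantom.make_sample("sphere", ls=100.0, radius=-5.0)

    def test_unknown_geometry_rejected(self):
        with pytest.raises(ValueError, match="unknown geometry"):
            phantom.make_sample("torus", ls=100.0)


class TestSeedCandles:
    def test_zero_cv_gives_unit_brightness(self, sphere_sample):
        candles = phantom.seed_candles(sphere_sample, 500, brightness_cv=0.0, seed=1)
        assert np.all(candles["b"] == 1.0)

    def test_lognormal_mean_near_one(self, sphere_sample):
        candles = phantom.seed_candles(sphere_sample, 10_000, brightness_cv=0.2, seed=2)
        assert 0.98 <= candles["b"].mean() <= 1.02

    def test_seeded_reproducibility(self, sphere_sample):
        a = phantom.seed_candles(sphere_sample, 200, brightness_cv=0.3, seed=7)
        b = phantom.seed_candles(sphere_sample, 200, brightness_cv=0.3, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_positions_inside_and_within_depth(self, sphere_sample):
        candles = phantom.seed_candles(sphere_sample, 300, seed=3, max_depth=250.0)
        pos = candles[["x", "y", "z"]].to_numpy()
        assert np.all(sphere_sample.geometry.inside(pos))
        depth = pos[:, 2] - np.asarray(sphere_sample.geometry.surface_z(pos[:, 0], pos[:, 1]))
        assert np.all(depth <= 250.0 + 1e-9)

    def test_impossible_constraints_stall(self, sphere_sample):
        with pytest.raises((RuntimeError, ValueError)):
            phantom.seed_candles(sphere_sample, 10, seed=0, max_depth=1e-9, min_depth=0.0)


class TestAttenuation:
    def test_no_scattering_limit(self, pupil):
        s = phantom.make_sample("sphere", ls=1e12)
        a = phantom.attenuation_factor(s, [0.0, 0.0, 510.0], pupil)
        assert a == pytest.approx(1.0, abs=1e-9)

    def test_surface_focus_is_unattenuated(self, pupil):
        s = phantom.make_sample("flat", ls=100.0)
        a = phantom.attenuation_factor(s, [0.0, 0.0, 1e-9], pupil)
        assert a == pytest.approx(1.0, abs=1e-3)

    def test_flat_axial_ray_single_exponential(self):
        s = phantom.make_sample("flat", ls=100.0)
        a = phantom.attenuation_factor(s, [0.0, 0.0, 100.0], PupilModel.paraxial())
        assert a == pytest.approx(np.exp(-1.0), abs=1e-9)

    def test_outside_focus_rejected(self, sphere_sample, pupil):
        with pytest.raises(ValueError, match="outside"):
            phantom.attenuation_factor(sphere_sample, [0.0, 0.0, 2000.0], pupil)

    def test_monotone_decreasing_with_depth(self, sphere_sample, pupil):
        zs = np.linspace(5, 400, 30)
        pts = np.column_stack([np.zeros_like(zs), np.zeros_like(zs), zs])
        a = phantom.attenuation_factor(sphere_sample, pts, pupil)
        assert np.all(np.diff(a) < 0)

    def test_sphere_subexponential_vs_flat(self, sphere_sample, pupil):
        """Required power 1/A in a sphere never exceeds the flat-sample value."""
        flat = phantom.make_sample("flat", ls=100.0)
        zs = np.linspace(10, 300, 15)
        pts = np.column_stack([np.zeros_like(zs), np.zeros_like(zs), zs])
        a_sphere = phantom.attenuation_factor(sphere_sample, pts, pupil)
        a_flat = phantom.attenuation_factor(flat, pts, pupil)
        assert np.all(1.0 / a_sphere <= 1.0 / a_flat + 1e-12)

    def test_quadrature_matches_monte_carlo(self, sphere_sample, pupil):
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 20:
            c = rng.uniform([-300, -300, 10], [300, 300, 300])
            z_top = sphere_sample.geometry.surface_z(c[0], c[1])
            if np.isnan(z_top) or c[2] <= z_top + 5:
                continue
            q = phantom.attenuation_factor(sphere_sample, c, pupil)
            m = phantom.attenuation_factor_mc(sphere_sample, c, pupil, n_rays=100_000, seed=checked)
            assert abs(q - m) / m < 0.01
            checked += 1

    def test_two_lobe_path_through_gap(self):
        """Union path length through overlapping lobes counts shared tissue once."""
        s = phantom.make_sample("two_lobe", ls=100.0)
        # focal point at the left lobe center, ray pointing +x through both lobes
        p = np.array([[-300.0, 0.0, 400.0]])
        d = np.array([[1.0, 0.0, 0.0]])
        total = s.geometry.path_lengths(p, d)[0, 0]
        # left lobe radius 400 + right lobe chord 800, minus the 200 um overlap
        assert total == pytest.approx(400.0 + 800.0 - 200.0, abs=1e-6)


@pytest.fixture(scope="module")
def setup(sphere_sample):
    candles = phantom.seed_candles(sphere_sample, 200, brightness_cv=0.0, seed=4, lateral_extent=250)
    grid = phantom.AcquisitionGrid(n_tiles=(3, 3), origin=(-308.0, -308.0))
    return candles, grid


class TestSimulateAcquisition:

    def test_two_photon_square_law(self, sphere_sample, setup, pupil):
        candles, grid = setup
        rec1 = phantom.simulate_acquisition(
            sphere_sample, candles, grid, lambda p, t, r: np.full(len(p), 0.1), seed=0, pupil=pupil
        )
        rec2 = phantom.simulate_acquisition(
            sphere_sample, candles, grid, lambda p, t, r: np.full(len(p), 0.2), seed=0, pupil=pupil
        )
        assert np.allclose(rec2["brightness"], 4.0 * rec1["brightness"], rtol=1e-12)

    def test_depth_brightness_ratio_follows_exponential(self):
        """Flat sample, axial pupil: brightness(z)/brightness(0) = exp(-2z/ls)."""
        flat = phantom.make_sample("flat", ls=100.0)
        par = PupilModel.paraxial()
        candles = pd.DataFrame({"x": [0.0, 0.0], "y": [0.0, 0.0], "z": [1e-12, 150.0], "b": [1.0, 1.0]})
        grid = phantom.AcquisitionGrid(origin=(-110.0, -110.0))
        rec = phantom.simulate_acquisition(flat, candles, grid, lambda p, t, r: np.ones(len(p)), seed=0, pupil=par)
        ratio = rec["brightness"].iloc[1] / rec["brightness"].iloc[0]
        assert ratio == pytest.approx(np.exp(-2 * 150.0 / 100.0), rel=1e-9)

    def test_randomizing_factors_within_bounds(self, sphere_sample, setup, pupil):
        from lamikit import experiments, rayoptics

        candles, grid = setup
        smap = pytest.importorskip("lamikit.surface").SurfaceMap(
            experiments.upper_surface_points(sphere_sample, 400, seed=5)
        )
        lut = rayoptics.precompute_lut(pupil, ls=sphere_sample.ls, depths=np.linspace(1, 320, 15), angles=np.linspace(0, 60, 8))
        policy = experiments.lut_power_policy(lut, smap, base_power=0.025)
        rec = phantom.simulate_acquisition(sphere_sample, candles, grid, policy, seed=6, pupil=pupil)
        base = experiments.lut_power_policy(lut, smap, base_power=0.025, randomize=False)
        rng = np.random.default_rng(0)
        ref = np.concatenate([
            base(rec.loc[m, ["x", "y", "z"]].to_numpy(), 0, rng)
            for m in [rec.index]
        ])
        factors = rec["P0"].to_numpy() / ref
        assert factors.min() >= 0.5 - 1e-9 and factors.max() <= 2.0 + 1e-9

    def test_negative_power_rejected(self, sphere_sample, setup, pupil):
        candles, grid = setup
        with pytest.raises(ValueError, match="negative"):
            phantom.simulate_acquisition(
                sphere_sample, candles, grid, lambda p, t, r: np.full(len(p), -0.1), seed=0, pupil=pupil
            )

    def test_zero_power_gives_zero_brightness(self, sphere_sample, setup, pupil):
        candles, grid = setup
        rec = phantom.simulate_acquisition(
            sphere_sample, candles, grid, lambda p, t, r: np.zeros(len(p)), seed=0, pupil=pupil, shot_noise=True
        )
        assert np.all(rec["brightness"] == 0.0)

    def test_seeded_records_bit_identical(self, sphere_sample, setup, pupil):
        candles, grid = setup
        kw = dict(seed=9, pupil=pupil, shot_noise=True, gain=1e5)
        policy = lambda p, t, r: np.full(len(p), 0.1)
        a = phantom.simulate_acquisition(sphere_sample, candles, grid, policy, **kw)
        b = phantom.simulate_acquisition(sphere_sample, candles, grid, policy, **kw)
        pd.testing.assert_frame_equal(a, b)


class TestRankDenoise:
    def test_constant_planes_unchanged_before_gaussian(self):
        a = np.full((16, 16), 3.5)
        out = phantom.rank_denoise(a, a.copy(), apply_gaussian=False)
        assert np.allclose(out, 3.5)

    def test_single_scan_outlier_suppressed(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0.9, 1.1, (21, 21))
        b = rng.uniform(0.9, 1.1, (21, 21))
        a[10, 10] = 100.0  # saturated pixel in one scan only
        out = phantom.rank_denoise(a, b, apply_gaussian=False)
        assert out[10, 10] < 0.5 * 100.0

    def test_gaussian_variance_reduction(self):
        rng = np.random.default_rng(1)
        noise = rng.normal(0, 1.0, (128, 128))
        from scipy import ndimage

        sm = ndimage.gaussian_filter(noise, 2.0, mode="reflect")
        assert noise.var() / sm.var() >= 4.0

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError, match="same shape"):
            phantom.rank_denoise(np.zeros((4, 4)), np.zeros((5, 5)))

    def test_output_shape_matches_input(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(size=(3, 12, 12))
        out = phantom.rank_denoise(a, a)
        assert out.shape == a.shape


class TestVignette:
    def test_center_is_unity(self):
        s = phantom.make_sample("flat", ls=100.0, vignette_strength=0.3)
        assert s.vignette(110.0, 110.0, 220.0) == pytest.approx(1.0)

    def test_corner_falls_by_strength(self):
        s = phantom.make_sample("flat", ls=100.0, vignette_strength=0.3)
        assert s.vignette(0.0, 0.0, 220.0) == pytest.approx(0.7, abs=1e-9)
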