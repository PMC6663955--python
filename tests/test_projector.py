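"""Analytic system model: adjointness, conservation, scatter, noise,
thinning."""

import numpy as np
import pytest

from spectenh.core import GridSpec, Volume
from spectenh.projector import (
    PHOTOPEAK,
    SCATTER,
    DetectorConfig,
    ProjectionSet,
    add_poisson,
    add_scatter,
    back_project,
    forward_project,
    get_projector,
    thin_counts,
)


def _proj_set(arr, cfg, voxel=4.0, noisy=False):
    return ProjectionSet(
        windows={PHOTOPEAK: arr}, config=cfg, voxel_size=voxel, is_noisy=noisy
    )


class TestForwardBackward:
    def test_zero_activity_projects_to_zero(self, small_detector):
        act = Volume(np.zeros((8, 8, 8)), 4.0)
        proj = forward_project(act, None, small_detector)
        assert not proj.photopeak.any()

    def test_count_conservation_point_source(self, small_detector):
        # mu = 0, PSF off: every angle's image sums to A x sens x time
        act = np.zeros((8, 8, 8))
        act[4, 4, 4] = 2.5
        p = get_projector(act.shape, 4.0, small_detector)
        proj = p.forward(act, None, attenuation=False, psf=False)
        expected = 2.5 * small_detector.sensitivity * small_detector.scan_time_s
        assert proj.sum(axis=(1, 2)) == pytest.approx(
            np.full(4, expected), rel=1e-9
        )

    def test_axis_aligned_rays_match_brute_force(self, rng):
        """At 90-degree angle spacing the rotation is exact, so per-ray
        values must match an independent ray-marching computation."""
        cfg = DetectorConfig(
            n_angles=4, sensitivity=1.0, scan_time_s=1.0, psf_sigma0=0.0,
            psf_slope=0.0,
        )
        d = 4.0
        act = rng.random((8, 8, 8))
        mu = np.full((8, 8, 8), 0.02)
        p = get_projector(act.shape, d, cfg)
        got = p.forward(act, mu, psf=False)
        # oracle for angle 0: rays along +y toward large y
        ref = np.zeros((8, 8))
        for z in range(8):
            for x in range(8):
                for y in range(8):
                    path = mu[z, y + 1 :, x].sum() + 0.5 * mu[z, y, x]
                    ref[z, x] += act[z, y, x] * np.exp(-path * d)
        assert got[0] == pytest.approx(ref, rel=1e-6)

    def test_adjointness_identity(self, rng, small_detector):
        shape = (8, 8, 8)
        p = get_projector(shape, 4.0, small_detector)
        x = rng.random(shape)
        mu = rng.random(shape) * 0.05
        y = rng.random((4, 8, 8))
        lhs = float((p.forward(x, mu) * y).sum())
        rhs = float((x * p.backward(y, mu)).sum())
        assert lhs == pytest.approx(rhs, rel=1e-6)

    def test_backprojected_single_bin_smears_one_ray(self):
        cfg = DetectorConfig(
            n_angles=4, sensitivity=1.0, scan_time_s=1.0, psf_sigma0=0.0,
            psf_slope=0.0,
        )
        proj = np.zeros((4, 8, 8))
        proj[0, 3, 5] = 2.0
        ps = _proj_set(proj, cfg)
        vol = back_project(ps, None, cfg, attenuation=False, psf=False)
        nz = np.nonzero(vol.data)
        assert set(nz[0]) == {3}
        assert set(nz[2]) == {5}
        assert vol.data[3, :, 5] == pytest.approx(np.full(8, 2.0), rel=1e-9)

    def test_uniform_mu_increase_never_increases_counts(self, rng, small_detector):
        shape = (8, 8, 8)
        p = get_projector(shape, 4.0, small_detector)
        act = rng.random(shape)
        mu1 = np.full(shape, 0.01)
        mu2 = np.full(shape, 0.02)
        assert np.all(p.forward(act, mu2) <= p.forward(act, mu1) + 1e-12)

    def test_rotational_symmetry(self):
        """A rotationally symmetric (smooth radial) phantom projects
        identically at every angle within interpolation tolerance."""
        grid = GridSpec(16, 16, 16, voxel_size=8.0)
        zw, yw, xw = grid.world_coords()
        r2 = xw**2 + yw**2
        act = np.broadcast_to(np.exp(-r2 / (2 * 20.0**2)), grid.shape).copy()
        cfg = DetectorConfig(n_angles=12, sensitivity=1.0, scan_time_s=1.0)
        p = get_projector(grid.shape, 8.0, cfg)
        proj = p.forward(act, None, attenuation=False, psf=False)
        totals = proj.sum(axis=(1, 2))
        assert np.ptp(totals) / totals.mean() < 0.02
        ref = proj[0]
        for ia in range(12):
            rel = np.abs(proj[ia] - ref).max() / ref.max()
            assert rel < 0.02


class TestScatter:
    def test_zero_fraction_is_identity(self, torso32):
        from dataclasses import replace

        cfg = replace(DetectorConfig(n_angles=8), scatter_to_primary=0.0)
        proj = forward_project(torso32.activity, torso32.mu, cfg)
        out = add_scatter(proj, cfg)
        assert np.array_equal(out.photopeak, proj.photopeak)
        assert not out.windows[SCATTER].any()

    def test_scatter_total_is_fraction_of_primary(self, torso32):
        cfg = DetectorConfig(n_angles=8)
        proj = forward_project(torso32.activity, torso32.mu, cfg)
        out = add_scatter(proj, cfg)
        assert out.windows[SCATTER].sum() == pytest.approx(
            cfg.scatter_to_primary * proj.photopeak.sum(), rel=1e-9
        )
        assert out.photopeak.sum() == pytest.approx(
            (1 + cfg.scatter_to_primary) * proj.photopeak.sum(), rel=1e-9
        )

    def test_point_source_scatter_fwhm(self):
        # oversampled detector grid: 2 mm bins, 80 mm kernel
        cfg = DetectorConfig(n_angles=2, scatter_kernel_fwhm=80.0)
        arr = np.zeros((2, 128, 128))
        arr[:, 64, 64] = 1000.0
        ps = _proj_set(arr, cfg, voxel=2.0)
        s = add_scatter(ps, cfg).windows[SCATTER][0]
        profile = s[64]
        half = profile.max() / 2
        above = np.where(profile >= half)[0]
        # linear interpolation at the half-maximum crossings
        lo, hi = above[0], above[-1]
        f_lo = lo - 1 + (half - profile[lo - 1]) / (profile[lo] - profile[lo - 1])
        f_hi = hi + (profile[hi] - half) / (profile[hi] - profile[hi + 1])
        fwhm_mm = (f_hi - f_lo) * 2.0
        assert fwhm_mm == pytest.approx(80.0, rel=0.05)

    def test_noisy_input_rejected(self, torso32):
        cfg = DetectorConfig(n_angles=8)
        proj = forward_project(torso32.activity, torso32.mu, cfg)
        noisy = add_poisson(add_scatter(proj, cfg), 0)
        with pytest.raises(ValueError, match="before noise"):
            add_scatter(noisy, cfg)


class TestPoissonAndThinning:
    def test_zero_expectation_stays_zero_and_seeded(self):
        cfg = DetectorConfig(n_angles=2)
        arr = np.zeros((2, 4, 4))
        arr[0, 0, 0] = 5.0
        ps = _proj_set(arr, cfg)
        a = add_poisson(ps, 42)
        b = add_poisson(ps, 42)
        assert np.array_equal(a.photopeak, b.photopeak)
        assert a.photopeak[arr == 0].sum() == 0
        assert np.issubdtype(a.photopeak.dtype, np.integer)

    def test_poisson_mean_and_variance(self):
        cfg = DetectorConfig(n_angles=2)
        arr = np.full((2, 240, 240), 20.0)
        noisy = add_poisson(_proj_set(arr, cfg), 7).photopeak.astype(float)
        assert noisy.mean() == pytest.approx(20.0, rel=0.01)
        assert noisy.var() / noisy.mean() == pytest.approx(1.0, rel=0.05)

    def test_thinning_expectation_and_poissonness(self):
        cfg = DetectorConfig(n_angles=2)
        arr = np.full((2, 160, 160), 20.0)  # ~1e6 total expected counts
        noisy = add_poisson(_proj_set(arr, cfg), 3)
        thinned = thin_counts(noisy, 0.25, 4)
        total = noisy.photopeak.sum()
        assert thinned.photopeak.sum() == pytest.approx(0.25 * total, rel=0.005)
        t = thinned.photopeak.astype(float)
        assert t.var() / t.mean() == pytest.approx(1.0, rel=0.05)
        assert thinned.config.scan_time_s == pytest.approx(
            0.25 * noisy.config.scan_time_s
        )

    def test_thinning_fraction_one_is_identity(self):
        cfg = DetectorConfig(n_angles=2)
        noisy = add_poisson(_proj_set(np.full((2, 8, 8), 9.0), cfg), 0)
        same = thin_counts(noisy, 1.0, 1)
        assert np.array_equal(same.photopeak, noisy.photopeak)

    def test_thinning_requires_integer_counts(self):
        cfg = DetectorConfig(n_angles=2)
        ps = _proj_set(np.full((2, 8, 8), 9.0), cfg)
        with pytest.raises(ValueError, match="integer"):
            thin_counts(ps, 0.5, 0)

    def test_negative_expectation_rejected(self):
        cfg = DetectorConfig(n_angles=2)
        ps = _proj_set(np.full((2, 4, 4), 1.0), cfg)
        ps.windows[PHOTOPEAK] = ps.windows[PHOTOPEAK] - 2.0  # bypass validation
        with pytest.raises(ValueError):
            add_poisson(ps, 0)
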