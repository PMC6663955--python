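"""FBP: ramp filter, Chang correction, reconstruction calibration."""

import numpy as np
import pytest

from spectenh.core import GridSpec, Volume
from spectenh.projector import (
    PHOTOPEAK,
    DetectorConfig,
    ProjectionSet,
    add_poisson,
    add_scatter,
    forward_project,
)
from spectenh.recon_fbp import (
    FbpConfig,
    chang_correction,
    chang_factors,
    fbp_reconstruct,
    ramp_filter,
)
from spectenh.metrics import mse_normalized


def _ps(arr, cfg, voxel=4.0):
    return ProjectionSet(
        windows={PHOTOPEAK: arr}, config=cfg, voxel_size=voxel
    )


class TestRampFilter:
    def test_constant_rows_dc_removed(self):
        """The filter's zero-frequency response is exactly zero: a constant
        row keeps only the edge response of its finite support, which dies
        away from the row ends."""
        cfg = DetectorConfig(n_angles=2)
        n = 64
        arr = np.full((2, 8, n), 7.0)
        out = ramp_filter(_ps(arr, cfg)).photopeak
        # interior: far below the input scale (pure-DC content removed)
        assert np.abs(out[..., n // 4 : 3 * n // 4]).max() < 1e-3 * 7.0
        # a truly periodic constant (circular filtering) is killed exactly
        from spectenh.recon_fbp import _ramp_kernel_response

        resp = _ramp_kernel_response(n, 4.0, "none")
        assert resp[0] == 0.0

    def test_linearity(self, rng):
        cfg = DetectorConfig(n_angles=2)
        x = rng.random((2, 4, 16))
        y = rng.random((2, 4, 16))
        fx = ramp_filter(_ps(x, cfg)).photopeak
        fy = ramp_filter(_ps(y, cfg)).photopeak
        fxy = ramp_filter(_ps(2.0 * x + 3.0 * y, cfg)).photopeak
        assert fxy == pytest.approx(2.0 * fx + 3.0 * fy, abs=1e-10)

    def test_impulse_response_matches_closed_form_kernel(self):
        cfg = DetectorConfig(n_angles=2)
        n, d = 16, 4.0
        arr = np.zeros((2, 1, n))
        arr[0, 0, 8] = 1.0
        out = ramp_filter(_ps(arr, cfg, voxel=d)).photopeak[0, 0]
        expected = np.zeros(n)
        for i in range(n):
            k = i - 8
            if k == 0:
                expected[i] = 1.0 / (4 * d * d)
            elif k % 2:
                expected[i] = -1.0 / (np.pi**2 * k**2 * d * d)
        assert out == pytest.approx(expected, abs=1e-6)


class TestChang:
    def test_identity_for_zero_attenuation(self, rng):
        cfg = DetectorConfig(n_angles=8)
        v = Volume(rng.random((8, 8, 8)), 4.0)
        mu = Volume(np.zeros((8, 8, 8)), 4.0)
        out = chang_correction(v, mu, cfg)
        assert out.data == pytest.approx(v.data, rel=1e-9)

    def test_factors_at_least_one_and_monotone_in_mu(self):
        grid = GridSpec(16, 16, 16, voxel_size=8.0)
        zw, yw, xw = grid.world_coords()
        cyl = ((xw**2 + yw**2) <= 48.0**2) * 1.0
        cfg = DetectorConfig(n_angles=16)
        f1 = chang_factors(Volume(np.broadcast_to(cyl * 0.01, grid.shape).copy(), 8.0), cfg)
        f2 = chang_factors(Volume(np.broadcast_to(cyl * 0.02, grid.shape).copy(), 8.0), cfg)
        assert f1.min() >= 1.0 - 1e-9
        assert np.all(f2 >= f1 - 1e-9)

    def test_cylinder_center_matches_exp_mu_r(self):
        # all angular path lengths from the center equal R -> factor exp(mu R)
        grid = GridSpec(33, 33, 33, voxel_size=4.0)
        zw, yw, xw = grid.world_coords()
        R = 48.0
        mu_val = 0.015
        cyl = ((xw**2 + yw**2) <= R**2) * mu_val
        mu = Volume(np.broadcast_to(cyl, grid.shape).copy(), 4.0)
        cfg = DetectorConfig(n_angles=32)
        f = chang_factors(mu, cfg)
        center = f[16, 16, 16]
        assert center == pytest.approx(np.exp(mu_val * R), rel=0.01)

    def test_off_center_voxel_matches_ray_oracle(self):
        """Per-voxel factor against independent fine-step ray marching
        through a smooth attenuation blob."""
        grid = GridSpec(33, 33, 33, voxel_size=4.0)
        zw, yw, xw = grid.world_coords()
        sig = 20.0  # compact: the blob vanishes well inside the grid
        mu_data = 0.02 * np.exp(-(xw**2 + yw**2 + zw**2) / (2 * sig**2))
        mu = Volume(np.broadcast_to(mu_data, grid.shape).copy(), 4.0)
        n_ang = 16
        cfg = DetectorConfig(n_angles=n_ang)
        f = chang_factors(mu, cfg)

        def mu_at(x, y, z):
            return 0.02 * np.exp(-(x**2 + y**2 + z**2) / (2 * sig**2))

        iz, iy, ix = 16, 18, 14  # off-center voxel away from edges
        x0 = (ix - 16) * 4.0
        y0 = (iy - 16) * 4.0
        step = 0.25
        surv = []
        for a in np.arange(n_ang) * 2 * np.pi / n_ang:
            # ray toward the detector for angle a: direction of +y in the
            # frame rotated by a, i.e. world (+sin a, +cos a)
            dx, dy = np.sin(a), np.cos(a)
            ts = np.arange(0.0, 200.0, step)
            vals = mu_at(x0 + dx * ts, y0 + dy * ts, 0.0)
            surv.append(np.exp(-np.trapezoid(vals, dx=step)))
        oracle = n_ang / np.sum(surv)
        assert f[iz, iy, ix] == pytest.approx(oracle, rel=0.01)


class TestFbpReconstruct:
    def test_point_source_recovered_at_argmax(self):
        grid = GridSpec(32, 32, 32, voxel_size=8.0)
        act = np.zeros(grid.shape)
        act[16, 14, 18] = 5.0
        cfg = DetectorConfig(n_angles=32, psf_sigma0=0.0, psf_slope=0.0)
        proj = forward_project(Volume(act, 8.0), None, cfg, psf=False)
        rec = fbp_reconstruct(
            proj, None, cfg, FbpConfig(post_filter_fwhm=0.0, chang_enabled=False)
        )
        assert np.unravel_index(np.argmax(rec.data), rec.shape) == (16, 14, 18)

    def test_activity_calibration_on_uniform_cylinder(self):
        # mu = 0, PSF off: total reconstructed activity within 5% of truth
        grid = GridSpec(32, 32, 32, voxel_size=8.0)
        zw, yw, xw = grid.world_coords()
        act = np.broadcast_to(
            ((xw**2 + yw**2) <= 60.0**2) * (np.abs(zw) <= 60.0) * 2.0, grid.shape
        ).copy()
        truth = act.sum()
        cfg = DetectorConfig(n_angles=48, psf_sigma0=0.0, psf_slope=0.0)
        proj = forward_project(Volume(act, 8.0), None, cfg, psf=False)
        rec = fbp_reconstruct(
            proj, None, cfg, FbpConfig(post_filter_fwhm=0.0, chang_enabled=False)
        )
        assert rec.total == pytest.approx(truth, rel=0.05)

    def test_round_trip_nmse_small_on_smooth_phantom(self):
        """Noise-free, attenuation-free round trip recovers a smooth
        phantom with small normalized MSE at 64^3 / 120 angles."""
        grid = GridSpec()
        zw, yw, xw = grid.world_coords()
        act = np.exp(-((xw - 20) ** 2 + yw**2 + zw**2) / (2 * 60.0**2))
        act = np.broadcast_to(act, grid.shape).copy()
        cfg = DetectorConfig(n_angles=120, psf_sigma0=0.0, psf_slope=0.0)
        proj = forward_project(Volume(act, grid.voxel_size), None, cfg, psf=False)
        rec = fbp_reconstruct(
            proj, None, cfg, FbpConfig(post_filter_fwhm=0.0, chang_enabled=False)
        )
        assert mse_normalized(rec.data, act) < 0.05

    def test_shorter_scan_never_improves_mse(self, torso32):
        """5-min FBP reconstructions are on average no better than 20-min
        ones (same phantom, paired noise seeds)."""
        from dataclasses import replace

        base = DetectorConfig(n_angles=24)
        mse = {300.0: [], 1200.0: []}
        for seed in range(5):
            for st in (1200.0, 300.0):
                cfg = replace(base, scan_time_s=st)
                proj = add_poisson(
                    add_scatter(
                        forward_project(torso32.activity, torso32.mu, cfg), cfg
                    ),
                    seed,
                )
                rec = fbp_reconstruct(proj, torso32.mu, cfg)
                mse[st].append(mse_normalized(rec, torso32.activity))
        assert np.mean(mse[300.0]) >= np.mean(mse[1200.0])

    def test_chang_requires_mu(self, torso32):
        cfg = DetectorConfig(n_angles=8)
        proj = forward_project(torso32.activity, torso32.mu, cfg)
        with pytest.raises(ValueError, match="attenuation map"):
            fbp_reconstruct(proj, None, cfg, FbpConfig(chang_enabled=True))
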