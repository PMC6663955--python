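"""OSEM reconstruction: DEW estimate, EM properties, reference presets."""

from dataclasses import replace

import numpy as np
import pytest

from spectenh.core import GridSpec, Volume
from spectenh.metrics import mse_normalized
from spectenh.projector import (
    PHOTOPEAK,
    SCATTER,
    DetectorConfig,
    ProjectionSet,
    add_poisson,
    add_scatter,
    forward_project,
    get_projector,
)
from spectenh.recon_osem import (
    CLINIC_CONFIG,
    MC_CONFIG,
    OsemConfig,
    dew_scatter_estimate,
    osem_reconstruct,
    reconstruct_clinic,
    reconstruct_mc,
)


def _two_window(pp, sc, cfg, voxel=4.0):
    return ProjectionSet(
        windows={PHOTOPEAK: pp, SCATTER: sc}, config=cfg, voxel_size=voxel
    )


class TestDewEstimate:
    def test_empty_scatter_window_gives_zero(self):
        cfg = DetectorConfig(n_angles=2)
        ps = _two_window(np.ones((2, 8, 8)), np.zeros((2, 8, 8)), cfg)
        est = dew_scatter_estimate(ps, OsemConfig(scatter_mode="dew"))
        assert not est.any()

    def test_total_scales_with_k(self, rng):
        cfg = DetectorConfig(n_angles=2)
        sc = rng.random((2, 16, 16))
        ps = _two_window(np.ones((2, 16, 16)), sc, cfg)
        ocfg = OsemConfig(scatter_mode="dew", dew_k=0.5)
        est = dew_scatter_estimate(ps, ocfg)
        assert est.sum() == pytest.approx(0.5 * sc.sum(), rel=1e-9)

    def test_uniform_window_smooths_to_uniform(self):
        cfg = DetectorConfig(n_angles=2)
        sc = np.full((2, 16, 16), 4.0)
        ps = _two_window(np.ones((2, 16, 16)), sc, cfg)
        est = dew_scatter_estimate(ps, OsemConfig(scatter_mode="dew", dew_k=0.5))
        assert est == pytest.approx(np.full_like(sc, 2.0), rel=1e-9)

    def test_missing_window_rejected(self):
        cfg = DetectorConfig(n_angles=2)
        ps = ProjectionSet(
            windows={PHOTOPEAK: np.ones((2, 8, 8))}, config=cfg, voxel_size=4.0
        )
        with pytest.raises(ValueError, match="scatter window"):
            dew_scatter_estimate(ps, OsemConfig(scatter_mode="dew"))


class TestOsem:
    def test_point_source_recovery(self):
        grid = GridSpec(16, 16, 16, voxel_size=8.0)
        act = np.zeros(grid.shape)
        act[8, 7, 9] = 4.0
        cfg = DetectorConfig(
            n_angles=16, psf_sigma0=0.0, psf_slope=0.0, scatter_to_primary=0.0
        )
        proj = forward_project(Volume(act, 8.0), None, cfg, psf=False)
        rec = osem_reconstruct(
            proj, None, cfg,
            OsemConfig(n_iterations=10, n_subsets=8, psf_enabled=False),
        )
        assert np.unravel_index(np.argmax(rec.data), rec.shape) == (8, 7, 9)
        # mass concentrates: the true voxel holds most of the activity
        assert rec.data[8, 7, 9] / rec.total > 0.5

    def test_mlem_count_preservation(self, rng):
        """After each full MLEM iteration (1 subset, no attenuation, no
        PSF, no scatter) total projected counts equal the data's."""
        shape = (8, 8, 8)
        cfg = DetectorConfig(
            n_angles=8, sensitivity=1.0, scan_time_s=1.0, psf_sigma0=0.0,
            psf_slope=0.0,
        )
        p = get_projector(shape, 4.0, cfg)
        x_true = rng.random(shape) + 0.1
        y = p.forward(x_true, None, attenuation=False, psf=False)
        ps = ProjectionSet(windows={PHOTOPEAK: y}, config=cfg, voxel_size=4.0)
        for n_it in (1, 2, 3):
            rec = osem_reconstruct(
                ps, None, cfg,
                OsemConfig(n_iterations=n_it, n_subsets=1, psf_enabled=False),
            )
            fwd = p.forward(rec.data, None, attenuation=False, psf=False)
            assert fwd.sum() == pytest.approx(y.sum(), rel=1e-4)

    def test_noiseless_nmse_decreases_monotonically(self, torso32):
        cfg = DetectorConfig(n_angles=24)
        proj = add_scatter(
            forward_project(torso32.activity, torso32.mu, cfg), cfg
        )
        errs = []
        for n_it in (1, 3, 6, 10):
            rec = osem_reconstruct(
                proj, torso32.mu, cfg,
                OsemConfig(n_iterations=n_it, n_subsets=8, scatter_mode="model"),
            )
            errs.append(mse_normalized(rec, torso32.activity))
        assert all(b <= a + 1e-12 for a, b in zip(errs, errs[1:]))

    def test_model_mode_converges_toward_truth_on_smooth_phantom(self):
        """With the exact scatter model and noise-free data, 10 x 8 OSEM
        reaches small normalized MSE on a smooth phantom."""
        grid = GridSpec()
        zw, yw, xw = grid.world_coords()
        act = np.broadcast_to(
            5.0 * np.exp(-((xw - 20) ** 2 + yw**2 + zw**2) / (2 * 50.0**2)),
            grid.shape,
        ).copy()
        mu = np.broadcast_to(
            0.015 * ((xw / 180) ** 2 + (yw / 130) ** 2 <= 1.0), grid.shape
        ).copy()
        cfg = DetectorConfig(n_angles=40)
        actv, muv = Volume(act, grid.voxel_size), Volume(mu, grid.voxel_size)
        proj = add_scatter(forward_project(actv, muv, cfg), cfg)
        rec = osem_reconstruct(
            proj, muv, cfg, OsemConfig(n_iterations=10, n_subsets=8, scatter_mode="model")
        )
        assert mse_normalized(rec, actv) < 0.02

    def test_subset_indivisibility_rejected(self, torso32):
        cfg = DetectorConfig(n_angles=24)
        proj = forward_project(torso32.activity, torso32.mu, cfg)
        with pytest.raises(ValueError, match="divisible"):
            osem_reconstruct(proj, torso32.mu, cfg, OsemConfig(n_subsets=7))

    def test_all_zero_projections_warn_and_return_zero(self):
        cfg = DetectorConfig(n_angles=8)
        ps = ProjectionSet(
            windows={PHOTOPEAK: np.zeros((8, 8, 8))}, config=cfg, voxel_size=4.0
        )
        with pytest.warns(UserWarning, match="all-zero"):
            rec = osem_reconstruct(ps, None, cfg, OsemConfig(n_subsets=8))
        assert not rec.data.any()


class TestReferencePresets:
    @pytest.fixture(scope="class")
    def noisy_proj(self, torso32):
        cfg = DetectorConfig(n_angles=24)
        return (
            add_poisson(
                add_scatter(forward_project(torso32.activity, torso32.mu, cfg), cfg),
                9,
            ),
            cfg,
        )

    def test_presets_differ_only_in_scatter_and_post_filter(self):
        assert MC_CONFIG.n_iterations == CLINIC_CONFIG.n_iterations == 10
        assert MC_CONFIG.n_subsets == CLINIC_CONFIG.n_subsets == 8
        assert MC_CONFIG.psf_enabled and CLINIC_CONFIG.psf_enabled
        assert MC_CONFIG.scatter_mode == "model"
        assert CLINIC_CONFIG.scatter_mode == "dew"
        assert CLINIC_CONFIG.dew_k == 0.5
        assert CLINIC_CONFIG.dew_smooth_fwhm == 5.0
        assert MC_CONFIG.post_filter_fwhm == 0.0
        assert CLINIC_CONFIG.post_filter_fwhm == 5.0

    def test_metadata_records_iterations(self, noisy_proj, torso32):
        proj, cfg = noisy_proj
        rec = reconstruct_mc(proj, torso32.mu, cfg, n_subsets=8)
        assert rec.meta["n_iterations"] == 10
        assert rec.meta["n_subsets"] == 8
        assert rec.meta["method"] == "mc"

    def test_deterministic_given_fixed_inputs(self, noisy_proj, torso32):
        proj, cfg = noisy_proj
        a = reconstruct_mc(proj, torso32.mu, cfg)
        b = reconstruct_mc(proj, torso32.mu, cfg)
        assert np.array_equal(a.data, b.data)

    def test_post_filter_reduces_voxelwise_variance(self, torso64):
        # needs a grid fine enough that the 5 mm kernel spans > 1 voxel
        cfg = DetectorConfig(n_angles=24)
        proj = add_poisson(
            add_scatter(forward_project(torso64.activity, torso64.mu, cfg), cfg),
            9,
        )
        clinic = reconstruct_clinic(proj, torso64.mu, cfg)
        unfiltered = osem_reconstruct(
            proj, torso64.mu, cfg, replace(CLINIC_CONFIG, post_filter_fwhm=0.0)
        )
        liver = torso64.masks.mask("liver_background")
        assert clinic.data[liver].var() < unfiltered.data[liver].var()

    def test_mc_beats_fbp_on_noiseless_data(self, torso32):
        from spectenh.recon_fbp import fbp_reconstruct

        cfg = DetectorConfig(n_angles=24)
        proj = add_scatter(forward_project(torso32.activity, torso32.mu, cfg), cfg)
        mc = reconstruct_mc(proj, torso32.mu, cfg)
        fbp = fbp_reconstruct(proj, torso32.mu, cfg)
        assert mse_normalized(mc, torso32.activity) < mse_normalized(
            fbp, torso32.activity
        )

    def test_clinic_no_worse_than_mc_on_noisy_data(self, torso32):
        """Averaged over noise seeds, the approximate-scatter clinical
        reconstruction does not beat the full-model reference."""
        cfg = DetectorConfig(n_angles=24)
        noiseless = add_scatter(
            forward_project(torso32.activity, torso32.mu, cfg), cfg
        )
        mse_mc, mse_cl = [], []
        for seed in range(5):
            noisy = add_poisson(noiseless, seed)
            mse_mc.append(
                mse_normalized(reconstruct_mc(noisy, torso32.mu, cfg), torso32.activity)
            )
            mse_cl.append(
                mse_normalized(
                    reconstruct_clinic(noisy, torso32.mu, cfg), torso32.activity
                )
            )
        assert np.mean(mse_cl) >= np.mean(mse_mc)
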