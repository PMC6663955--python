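"""End-to-end experiment driver.

Chains phantom generation -> projection simulation -> reconstruction (up to
four methods: FBP, CNN-enhanced FBP, clinical-style OSEM, full-model OSEM)
-> training of the enhancement network -> evaluation, at desk scale, and
aggregates the radioembolization metrics across held-out volumes and scan
times. All randomness flows from one master seed through fixed derivation
keys, so a rerun with the same configuration is bit-identical.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .core import GridSpec, Volume
from .enhancer import EnhancerModel, NetSpec, TrainConfig, build_network, enhance, train
from .metrics import compare_methods, lsf, mse_normalized
from .phantom import (
    PhantomSet,
    SyntheticVolumeSpec,
    make_synthetic_volume,
    random_torso_phantom,
)
from .projector import DetectorConfig, add_poisson, add_scatter, forward_project
from .recon_fbp import FbpConfig, fbp_reconstruct
from .recon_osem import reconstruct_clinic, reconstruct_mc
from .trainset import DatasetSpec, build_pairs, make_ground_truth, volume_seed

__all__ = ["ExperimentConfig", "run_experiment", "build_library", "clinical_diameter_px"]

# derivation keys for the master-seed streams
_K_DONOR, _K_TRAIN, _K_VAL, _K_PAIRS, _K_NET, _K_EVAL, _K_GT = (
    1_000_000,
    2_000_000,
    3_000_000,
    4_000_000,
    5_000_000,
    6_000_000,
    7_000_000,
)


def clinical_diameter_px(voxel_size: float) -> tuple[int, int]:
    """Patch-sphere diameter range matching the clinical-matrix convention.

    The canonical range is 7-20 pixels on a 3.9 mm grid (27.3-78 mm);
    rescale to the current voxel size so the physical sphere sizes are
    preserved on coarser desk grids.
    """
    lo = max(2, int(round(7 * 3.9 / voxel_size)))
    hi = max(lo + 1, int(round(20 * 3.9 / voxel_size)))
    return lo, hi


@dataclass(frozen=True)
class ExperimentConfig:
    """One auditable place for every stage's settings."""

    grid: GridSpec = field(default_factory=GridSpec)
    detector: DetectorConfig = field(default_factory=lambda: DetectorConfig(n_angles=60))
    fbp: FbpConfig = field(default_factory=FbpConfig)
    net: NetSpec = field(default_factory=NetSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    n_donors: int = 6
    n_train: int = 40
    n_val: int = 5
    scan_times_s: tuple[float, ...] = (1200.0,)
    methods: tuple[str, ...] = ("fbp", "cnn")
    n_noise_realizations: int = 1
    slice_stride: int = 1
    master_seed: int = 1
    diameter_px: tuple[int, int] | None = None  # None -> clinical_diameter_px
    # "phantom": the generated digital volumes are the ground truth.
    # "mc_recon": emulate the clinical situation where no true distribution
    # exists — the full-model OSEM reconstruction of the original (noisy)
    # projections is declared ground truth, and everything (training pairs,
    # evaluation projections, metrics) derives from it.
    gt_mode: str = "phantom"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid"] = self.grid.to_dict()
        d["detector"] = self.detector.to_dict()
        return d


def build_library(cfg: ExperimentConfig) -> list[PhantomSet]:
    """Randomized torso-phantom donors for the synthetic generator."""
    return [
        random_torso_phantom(volume_seed(cfg.master_seed, _K_DONOR + i), cfg.grid)
        for i in range(cfg.n_donors)
    ]


def _synthetic_volumes(
    cfg: ExperimentConfig, library: list[PhantomSet], n: int, key: int
) -> list[PhantomSet]:
    diam = cfg.diameter_px or clinical_diameter_px(cfg.grid.voxel_size)
    out = []
    for i in range(n):
        spec = SyntheticVolumeSpec(
            library=library,
            diameter_px=diam,
            seed=volume_seed(cfg.master_seed, key + i),
        )
        ps = make_synthetic_volume(spec)
        ps.activity.meta["id"] = f"{'val' if key == _K_VAL else 'train'}_{i}"
        out.append(ps)
    return out


def _reconstruct_case(
    method: str,
    proj,
    mu: Volume,
    det_cfg: DetectorConfig,
    fbp_cfg: FbpConfig,
    model: EnhancerModel | None,
) -> Volume:
    if method in ("fbp", "cnn"):
        fbp = fbp_reconstruct(proj, mu, det_cfg, fbp_cfg)
        if method == "fbp":
            return fbp
        if model is None:
            raise ValueError("cnn method requires a trained model")
        return enhance(model, fbp)
    if method == "clinic":
        return reconstruct_clinic(proj, mu, det_cfg)
    if method == "mc":
        return reconstruct_mc(proj, mu, det_cfg)
    raise ValueError(f"unknown method {method!r}")


def run_experiment(
    cfg: ExperimentConfig, out_dir: str | Path | None = None
) -> tuple[dict, dict[float, EnhancerModel]]:
    """Run the full pipeline and return (report, trained models by scan time).

    The report holds one row per (validation volume, scan time, noise
    realization, method) plus per-method aggregates: mean normalized MSE,
    mean absolute LSF difference to ground truth, and Mann-Whitney
    p-values of each method's MSE distribution against the CNN's.
    """
    t0 = time.time()
    stage = "library"
    try:
        library = build_library(cfg)
        stage = "synthetic volumes"
        train_sets = _synthetic_volumes(cfg, library, cfg.n_train, _K_TRAIN)
        val_sets = _synthetic_volumes(cfg, library, cfg.n_val, _K_VAL)

        if cfg.gt_mode == "mc_recon":
            # no true distribution is assumed available: acquire original
            # projections of every volume and set the full-model OSEM
            # reconstruction as the ground truth
            stage = "ground-truth reconstruction"
            det0 = replace(cfg.detector, scan_time_s=cfg.scan_times_s[0])
            for j, ps in enumerate(train_sets + val_sets):
                seed = volume_seed(cfg.master_seed, _K_GT + j)
                proj0 = add_poisson(
                    add_scatter(forward_project(ps.activity, ps.mu, det0), det0),
                    seed,
                )
                gt = make_ground_truth(proj0, ps.mu, det0)
                gt.meta["id"] = ps.activity.meta.get("id", str(j))
                ps.activity = gt
        elif cfg.gt_mode != "phantom":
            raise ValueError(f"unknown gt_mode {cfg.gt_mode!r}")

        models: dict[float, EnhancerModel] = {}
        rows: list[dict] = []
        for st_i, st in enumerate(cfg.scan_times_s):
            det = replace(cfg.detector, scan_time_s=st)
            if "cnn" in cfg.methods:
                stage = f"training pairs ({st:.0f} s)"
                ds = DatasetSpec(
                    n_real=0,
                    n_synthetic=cfg.n_train,
                    scan_time_s=st,
                    seed=volume_seed(cfg.master_seed, _K_PAIRS + st_i),
                    slice_stride=cfg.slice_stride,
                )
                tr_pairs = build_pairs(
                    [s.activity for s in train_sets],
                    [s.mu for s in train_sets],
                    det,
                    ds,
                    synthetic_flags=[True] * len(train_sets),
                )
                va_pairs = build_pairs(
                    [s.activity for s in val_sets],
                    [s.mu for s in val_sets],
                    det,
                    replace(ds, seed=volume_seed(cfg.master_seed, _K_PAIRS + 50 + st_i)),
                )
                stage = f"network training ({st:.0f} s)"
                model = build_network(
                    cfg.net, seed=volume_seed(cfg.master_seed, _K_NET + st_i)
                )
                model = train(
                    model,
                    tr_pairs,
                    va_pairs,
                    replace(cfg.train, seed=volume_seed(cfg.master_seed, _K_NET + st_i)),
                )
                models[st] = model

            stage = f"evaluation ({st:.0f} s)"
            for vi, ps in enumerate(val_sets):
                gt = ps.activity
                lsf_gt = lsf(gt, ps.masks)
                for rep in range(cfg.n_noise_realizations):
                    noise_seed = volume_seed(
                        cfg.master_seed, _K_EVAL + 10_000 * st_i + 100 * vi + rep
                    )
                    proj = add_poisson(
                        add_scatter(forward_project(gt, ps.mu, det), det), noise_seed
                    )
                    for method in cfg.methods:
                        recon = _reconstruct_case(
                            method, proj, ps.mu, det, cfg.fbp, models.get(st)
                        )
                        rows.append(
                            {
                                "volume": gt.meta.get("id", str(vi)),
                                "scan_time_s": st,
                                "noise_rep": rep,
                                "method": method,
                                "mse_norm": mse_normalized(recon, gt),
                                "lsf": lsf(recon, ps.masks),
                                "lsf_gt": lsf_gt,
                                "lsf_diff_pp": lsf(recon, ps.masks) - lsf_gt,
                            }
                        )
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"experiment failed during stage: {stage}") from exc

    aggregates: dict[str, dict] = {}
    for st in cfg.scan_times_s:
        for method in cfg.methods:
            sel = [
                r for r in rows if r["method"] == method and r["scan_time_s"] == st
            ]
            key = f"{method}@{st:.0f}s"
            aggregates[key] = {
                "mean_mse_norm": float(np.mean([r["mse_norm"] for r in sel])),
                "mean_abs_lsf_diff_pp": float(
                    np.mean([abs(r["lsf_diff_pp"]) for r in sel])
                ),
                "n_cases": len(sel),
            }
        if "cnn" in cfg.methods and len(cfg.methods) > 1:
            cnn_mse = [
                r["mse_norm"]
                for r in rows
                if r["method"] == "cnn" and r["scan_time_s"] == st
            ]
            for method in cfg.methods:
                if method == "cnn" or len(cnn_mse) < 3:
                    continue
                other = [
                    r["mse_norm"]
                    for r in rows
                    if r["method"] == method and r["scan_time_s"] == st
                ]
                aggregates[f"cnn_vs_{method}@{st:.0f}s"] = {
                    "mannwhitney_p": compare_methods(cnn_mse, other)
                }

    report = {
        "config": cfg.to_dict(),
        "rows": rows,
        "aggregates": aggregates,
        "training": {
            f"{st:.0f}s": {
                "min_val_loss": m.min_val_loss,
                "best_epoch": m.best_epoch,
                "epochs_run": len(m.history["val_loss"]),
            }
            for st, m in models.items()
        },
        "wall_clock_s": time.time() - t0,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(json.dumps(report, indent=1))
        (out_dir / "manifest.json").write_text(
            json.dumps({"config": cfg.to_dict(), "master_seed": cfg.master_seed}, indent=1)
        )
    return report, models
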