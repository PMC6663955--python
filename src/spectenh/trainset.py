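"""Training-pair construction with the reconstruct-then-re-project scheme.

The central data-generation idea: a reference reconstruction (or a
synthetic volume composed from reference reconstructions) is declared the
ground truth, *re-projected* through the simulator at the target scan time
with scatter and Poisson noise, and reconstructed with FBP; the network
then trains from those FBP slices back to the ground-truth slices. Because
the input is derived from the target itself, the mapping the network sees
is consistent — unlike training FBP directly against an iterative
reconstruction of the same raw projections (``direct_pairs``, kept as the
ablation path).

Samples are five adjacent axial FBP slices (channel-stacked) against the
central ground-truth slice; edge slices are padded by edge replication so
every slice of a volume yields a pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core import Volume
from .projector import DetectorConfig, ProjectionSet, add_poisson, add_scatter
from .recon_fbp import FbpConfig, fbp_reconstruct
from .recon_osem import reconstruct_mc
from . import projector as _proj

__all__ = [
    "DatasetSpec",
    "TrainingPair",
    "make_ground_truth",
    "degrade_volume",
    "build_pairs",
    "direct_pairs",
    "slice_blocks",
]

NORM_SCALE = 1e-3  # pair values are activity / (volume total * NORM_SCALE)


@dataclass(frozen=True)
class DatasetSpec:
    """Bookkeeping for a training dataset build."""

    n_real: int = 100
    n_synthetic: int = 900
    scan_time_s: float = 1200.0
    seed: int = 0
    slice_stride: int = 1  # take every k-th axial slice as a sample

    def __post_init__(self) -> None:
        if self.slice_stride < 1:
            raise ValueError("slice_stride must be >= 1")


@dataclass
class TrainingPair:
    """One sample: 5 adjacent input slices and the central target slice."""

    input: np.ndarray  # (5, H, W) float32, normalized
    target: np.ndarray  # (1, H, W) float32, normalized
    volume_id: str
    slice_index: int
    norm: float  # multiply network output by this to restore MBq/voxel
    synthetic: bool = False
    meta: dict = field(default_factory=dict)


def volume_seed(master_seed: int, volume_index: int) -> int:
    """Per-volume RNG stream derived from (master seed, volume id); < 2^31."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(volume_index,))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def make_ground_truth(
    raw_proj: ProjectionSet, mu: Volume, det_cfg: DetectorConfig | None = None
) -> Volume:
    """Reference reconstruction declared ground truth (full-model OSEM,
    10 iterations x 8 subsets, no post-filter)."""
    gt = reconstruct_mc(raw_proj, mu, det_cfg)
    gt.meta["method"] = "ground_truth"
    return gt


def degrade_volume(
    gt: Volume,
    mu: Volume,
    det_cfg: DetectorConfig,
    seed: int,
    scan_time_s: float | None = None,
    fbp_cfg: FbpConfig | None = None,
) -> Volume:
    """Re-project a ground-truth volume and reconstruct it with FBP.

    forward projection -> effective scatter -> Poisson noise at the given
    scan time -> FBP with Chang correction and 5 mm post-filter.
    """
    cfg = det_cfg
    if scan_time_s is not None:
        cfg = replace(det_cfg, scan_time_s=scan_time_s)
    proj = _proj.forward_project(gt, mu, cfg)
    proj = add_scatter(proj, cfg)
    proj = add_poisson(proj, seed)
    return fbp_reconstruct(proj, mu, cfg, fbp_cfg)


def slice_blocks(data: np.ndarray) -> np.ndarray:
    """(nz, H, W) -> (nz, 5, H, W) blocks of 5 adjacent slices.

    Edge replication: slice 0's block is [s0, s0, s0, s1, s2].
    """
    nz = data.shape[0]
    idx = np.clip(
        np.arange(nz)[:, None] + np.arange(-2, 3)[None, :], 0, nz - 1
    )
    return data[idx]  # fancy indexing -> (nz, 5, H, W)


def _pairs_from_volumes(
    inputs: Sequence[Volume],
    targets: Sequence[Volume],
    ids: Sequence[str],
    synthetic_flags: Sequence[bool],
    slice_stride: int,
) -> list[TrainingPair]:
    pairs: list[TrainingPair] = []
    for vin, vgt, vid, syn in zip(inputs, targets, ids, synthetic_flags):
        norm = vin.total * NORM_SCALE
        if norm <= 0:
            raise ValueError(f"volume {vid} has non-positive total activity")
        x = (vin.data / norm).astype(np.float32)
        y = (vgt.data / norm).astype(np.float32)
        blocks = slice_blocks(x)
        for z in range(0, x.shape[0], slice_stride):
            pairs.append(
                TrainingPair(
                    input=blocks[z],
                    target=y[z][None],
                    volume_id=str(vid),
                    slice_index=z,
                    norm=float(norm),
                    synthetic=bool(syn),
                )
            )
    return pairs


def build_pairs(
    gt_volumes: Sequence[Volume],
    mu_maps: Sequence[Volume],
    det_cfg: DetectorConfig,
    spec: DatasetSpec,
    synthetic_flags: Sequence[bool] | None = None,
) -> list[TrainingPair]:
    """Re-projection training pairs for a set of ground-truth volumes.

    Each volume is degraded (project + scatter + Poisson + FBP) with its
    own seeded noise stream derived from ``spec.seed``, then paired
    slice-by-slice with the ground truth. Deterministic for a fixed spec.
    """
    if len(gt_volumes) != len(mu_maps):
        raise ValueError("each ground-truth volume needs an attenuation map")
    if synthetic_flags is None:
        synthetic_flags = [False] * len(gt_volumes)
    fbps = [
        degrade_volume(
            gt, mu, det_cfg, seed=volume_seed(spec.seed, i),
            scan_time_s=spec.scan_time_s,
        )
        for i, (gt, mu) in enumerate(zip(gt_volumes, mu_maps))
    ]
    ids = [v.meta.get("id", str(i)) for i, v in enumerate(gt_volumes)]
    return _pairs_from_volumes(
        fbps, gt_volumes, ids, synthetic_flags, spec.slice_stride
    )


def direct_pairs(
    gt_volumes: Sequence[Volume],
    raw_projections: Sequence[ProjectionSet],
    mu_maps: Sequence[Volume],
    det_cfg: DetectorConfig,
    slice_stride: int = 1,
) -> list[TrainingPair]:
    """Ablation path: FBP of the *original* projections against the
    reference reconstruction of those same projections (no re-projection)."""
    if not (len(gt_volumes) == len(raw_projections) == len(mu_maps)):
        raise ValueError("volumes, projections and mu maps must align")
    fbps = [
        fbp_reconstruct(proj, mu, det_cfg)
        for proj, mu in zip(raw_projections, mu_maps)
    ]
    ids = [v.meta.get("id", str(i)) for i, v in enumerate(gt_volumes)]
    return _pairs_from_volumes(
        fbps, gt_volumes, ids, [False] * len(gt_volumes), slice_stride
    )
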