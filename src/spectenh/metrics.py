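"""Evaluation metrics for radioembolization SPECT reconstructions.

Covers the quantities used to judge reconstruction quality in the
pre-treatment workflow: a scale-free normalized mean squared error against
the ground-truth distribution, the lung shunting fraction (LSF), per-sphere
uptake ratios, contrast-to-noise ratio (CNR), and a rank-based two-sample
comparison across methods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import Volume
from .phantom import LabelMasks

__all__ = [
    "MetricReport",
    "mse_normalized",
    "lsf",
    "uptake_ratio",
    "cnr",
    "compare_methods",
]


@dataclass
class MetricReport:
    """Per-reconstruction metric bundle."""

    method: str
    scan_time_s: float
    mse_norm: float | None = None
    lsf: float | None = None
    uptake_ratios: dict[str, float] = field(default_factory=dict)
    cnr: float | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "scan_time_s": self.scan_time_s,
            "mse_norm": self.mse_norm,
            "lsf": self.lsf,
            "uptake_ratios": self.uptake_ratios,
            "cnr": self.cnr,
            **self.extra,
        }


def _data(v) -> np.ndarray:
    return v.data if isinstance(v, Volume) else np.asarray(v)


def mse_normalized(recon, gt) -> float:
    """Mean squared error between activity-normalized volumes.

    Each volume is divided by its own total before comparison, so a global
    rescaling of either argument leaves the value unchanged. The mean over
    voxels is multiplied by n_voxels^2 — a fixed display scaling that brings
    typical values to order 0.01-1 for clinical-matrix volumes.
    """
    r = _data(recon).astype(np.float64)
    g = _data(gt).astype(np.float64)
    if r.shape != g.shape:
        raise ValueError(f"shape mismatch: {r.shape} vs {g.shape}")
    tr, tg = r.sum(), g.sum()
    if tr <= 0 or tg <= 0:
        raise ValueError("volumes must have positive total activity")
    n = r.size
    return float(np.mean((r / tr - g / tg) ** 2) * n * n)


def lsf(volume, masks: LabelMasks) -> float:
    """Lung shunting fraction in percent.

    100 x lung activity / (lung + liver-region activity), where the liver
    region includes intrahepatic spheres and their cold cores (total hepatic
    activity, the radioembolization convention).
    """
    v = _data(volume)
    lung = masks.lung_mask()
    liver = masks.liver_region_mask()
    if not lung.any() or not liver.any():
        raise ValueError("lung and liver masks must be non-empty")
    lung_sum = float(v[lung].sum())
    liver_sum = float(v[liver].sum())
    denom = lung_sum + liver_sum
    if denom == 0:
        raise ValueError("no activity in lung+liver region")
    return 100.0 * lung_sum / denom


def uptake_ratio(volume, sphere_mask: np.ndarray, background_mask: np.ndarray) -> float:
    """Mean sphere concentration over mean liver-background concentration."""
    v = _data(volume)
    if not sphere_mask.any() or not background_mask.any():
        raise ValueError("masks must be non-empty")
    if (sphere_mask & background_mask).any():
        raise ValueError("sphere and background masks must be disjoint")
    bg = float(v[background_mask].mean())
    if bg == 0:
        raise ValueError("background mean is zero")
    return float(v[sphere_mask].mean()) / bg


def cnr(volume, sphere_mask: np.ndarray, background_mask: np.ndarray) -> float:
    """Contrast-to-noise ratio: (mean_sphere - mean_bg) / sd_bg (population sd)."""
    v = _data(volume)
    if background_mask.sum() < 2:
        raise ValueError("background mask needs at least 2 voxels")
    sd = float(v[background_mask].std())
    if sd == 0:
        raise ValueError("background standard deviation is zero")
    return (float(v[sphere_mask].mean()) - float(v[background_mask].mean())) / sd


def compare_methods(values_a, values_b) -> float:
    """Two-sided Mann-Whitney U p-value between two per-case value sets.

    Exact distribution for small samples (n <= 8 per group, no ties),
    normal approximation with tie correction otherwise. All-identical
    pooled values return p = 1 with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 cases per group")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        warnings.warn("all pooled values identical; p-value is 1")
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))
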