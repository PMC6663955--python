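"""Digital phantoms: anthropomorphic torso ground truth and patch-sphere
synthetic training volumes.

The torso phantom reproduces, digitally, the activity configuration of a
commercial anthropomorphic torso phantom as used in radioembolization QA:
a liver with uniform background activity, hot spheres inside the liver at a
fixed uptake ratio (one with a cold core), smaller extrahepatic spheres at a
lower ratio, and lungs holding a prescribed lung shunting fraction (LSF) of
the total hepatic activity. The synthetic generator composes new liver
activity distributions by repeatedly stamping spheres filled with activity
patches copied from *other* volumes in a donor library, until the whole
liver is covered — a cheap way to multiply the diversity of training data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .core import GridSpec, Volume

__all__ = [
    "SphereSpec",
    "TorsoPhantomSpec",
    "SyntheticVolumeSpec",
    "LabelMasks",
    "PhantomSet",
    "sphere_mask",
    "make_torso_phantom",
    "random_torso_phantom",
    "make_synthetic_volume",
]

# role names used in the label table
ROLE_BODY = "body"
ROLE_LIVER = "liver_background"
ROLE_LUNG_L = "lung_left"
ROLE_LUNG_R = "lung_right"


@dataclass(frozen=True)
class SphereSpec:
    """One sphere of the torso phantom.

    center is world mm (x, y, z); cold_core_ml > 0 carves a concentric
    zero-activity core out of the hot sphere.
    """

    center: tuple[float, float, float]
    volume_ml: float
    uptake_ratio: float
    cold_core_ml: float = 0.0
    inside_liver: bool = True


def _default_spheres() -> tuple[SphereSpec, ...]:
    return (
        SphereSpec((80.0, 35.0, -60.0), 15.7, 7.7, 0.0, True),
        SphereSpec((25.0, 5.0, -85.0), 18.7, 7.7, 5.6, True),
        SphereSpec((-80.0, -40.0, -100.0), 2.0, 2.7, 0.0, False),
        SphereSpec((-80.0, 30.0, -40.0), 4.1, 2.7, 0.0, False),
        SphereSpec((-70.0, -60.0, -10.0), 8.1, 2.7, 0.0, False),
    )


@dataclass(frozen=True)
class TorsoPhantomSpec:
    """Geometry and activity configuration of the digital torso phantom.

    Defaults follow the standard QA configuration: extrahepatic spheres of
    2.0/4.1/8.1 mL at uptake ratio 2.7 versus liver background, an
    intrahepatic solid 15.7 mL sphere and a cold-core sphere (5.6 mL cold in
    18.7 mL hot) at ratio 7.7, lungs at LSF 5.2% and 157 MBq total activity.
    Ellipsoid geometry and attenuation values are the package's own choices
    (typical 140 keV values), exposed here for configuration.
    """

    liver_center: tuple[float, float, float] = (55.0, 20.0, -70.0)
    liver_axes: tuple[float, float, float] = (85.0, 70.0, 75.0)
    lung_left_center: tuple[float, float, float] = (-65.0, 0.0, 90.0)
    lung_right_center: tuple[float, float, float] = (65.0, 0.0, 90.0)
    lung_axes: tuple[float, float, float] = (50.0, 60.0, 85.0)
    body_axes: tuple[float, float] = (190.0, 130.0)  # transaxial ellipse, mm
    spheres: tuple[SphereSpec, ...] = field(default_factory=_default_spheres)
    lung_shunt_fraction: float = 5.2  # percent of lung+liver activity in lungs
    total_activity: float = 157.0  # MBq
    mu_soft: float = 0.015  # per mm at 140 keV
    mu_lung: float = 0.004  # per mm


@dataclass
class LabelMasks:
    """Integer label volume plus a table mapping label -> role.

    Table entries are JSON-serializable dicts with at least a ``role`` key;
    sphere entries carry ``inside_liver``, ``volume_ml`` and ``uptake_ratio``.
    Labels are disjoint by construction (each voxel has exactly one label).
    """

    labels: np.ndarray
    table: dict[int, dict]
    voxel_size: float

    def label_for_role(self, role: str) -> int:
        for lab, entry in self.table.items():
            if entry["role"] == role:
                return lab
        raise KeyError(f"no label with role {role!r}")

    def mask(self, role: str) -> np.ndarray:
        return self.labels == self.label_for_role(role)

    def labels_where(self, predicate) -> list[int]:
        return [lab for lab, e in self.table.items() if predicate(e)]

    def lung_mask(self) -> np.ndarray:
        labs = self.labels_where(lambda e: e["role"].startswith("lung"))
        return np.isin(self.labels, labs)

    def liver_region_mask(self) -> np.ndarray:
        """Liver background plus intrahepatic spheres and their cold cores."""
        labs = self.labels_where(
            lambda e: e["role"] == ROLE_LIVER
            or (e["role"].startswith(("sphere", "cold_core")) and e.get("inside_liver"))
        )
        return np.isin(self.labels, labs)

    def sphere_masks(self, inside_liver: bool | None = None) -> dict[str, np.ndarray]:
        out = {}
        for lab, e in self.table.items():
            if e["role"].startswith("sphere"):
                if inside_liver is None or e.get("inside_liver") == inside_liver:
                    out[e["role"]] = self.labels == lab
        return out

    def background_mask(self, margin_voxels: int = 2) -> np.ndarray:
        """Liver background excluding a safety margin around every sphere."""
        bg = self.mask(ROLE_LIVER)
        sphere_labs = self.labels_where(
            lambda e: e["role"].startswith(("sphere", "cold_core"))
        )
        if sphere_labs:
            spheres = np.isin(self.labels, sphere_labs)
            if margin_voxels > 0:
                spheres = ndimage.binary_dilation(spheres, iterations=margin_voxels)
            bg = bg & ~spheres
        return bg


@dataclass
class PhantomSet:
    """A matched (activity, attenuation, labels) triple on one grid."""

    activity: Volume
    mu: Volume
    masks: LabelMasks


def sphere_mask(
    center_mm: Sequence[float], volume_ml: float, grid: GridSpec
) -> np.ndarray:
    """Boolean mask of voxels whose centers lie within the sphere.

    The radius follows r = (3V / 4 pi)^(1/3). A sphere smaller than one
    voxel still claims its containing voxel, so masks are never empty for
    in-grid centers; a center outside the grid extent raises.
    """
    if volume_ml <= 0:
        raise ValueError("volume_ml must be positive")
    cx, cy, cz = center_mm
    r = (3.0 * volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)  # mm
    zw, yw, xw = grid.world_coords()
    half = np.array([grid.n_x, grid.n_y, grid.n_z]) * grid.voxel_size / 2
    if abs(cx) > half[0] + r or abs(cy) > half[1] + r or abs(cz) > half[2] + r:
        raise ValueError(
            f"sphere at {tuple(center_mm)} mm lies outside the grid extent"
        )
    d2 = (xw - cx) ** 2 + (yw - cy) ** 2 + (zw - cz) ** 2
    mask = d2 <= r * r
    if not mask.any():
        # sub-voxel sphere: claim the containing voxel
        idx = np.unravel_index(np.argmin(d2), d2.shape)
        if d2[idx] > (grid.voxel_size * np.sqrt(3)) ** 2:
            raise ValueError(
                f"sphere at {tuple(center_mm)} mm lies outside the grid extent"
            )
        mask = np.zeros(grid.shape, dtype=bool)
        mask[idx] = True
    return mask


def _ellipsoid(grid: GridSpec, center, axes) -> np.ndarray:
    cx, cy, cz = center
    ax, ay, az = axes
    zw, yw, xw = grid.world_coords()
    return ((xw - cx) / ax) ** 2 + ((yw - cy) / ay) ** 2 + (
        (zw - cz) / az
    ) ** 2 <= 1.0


def make_torso_phantom(
    spec: TorsoPhantomSpec, grid: GridSpec | None = None
) -> PhantomSet:
    """Build the digital torso phantom ground truth.

    Liver background voxels get uniform concentration c, spheres get
    c * uptake_ratio, cold cores 0; lung activity is set so that
    lung / (lung + liver-region) equals ``lung_shunt_fraction`` percent,
    and the whole volume is rescaled to ``total_activity`` MBq. Attenuation
    is ``mu_soft`` inside the body ellipse, ``mu_lung`` inside lungs, zero
    outside. Raises a geometry error naming the offending sphere if one
    escapes the grid or an intrahepatic sphere escapes the liver.
    """
    grid = grid or GridSpec()
    zw, yw, xw = grid.world_coords()
    bx, by = spec.body_axes
    body = np.broadcast_to(
        (xw / bx) ** 2 + (yw / by) ** 2 <= 1.0, grid.shape
    ).copy()
    liver_ell = _ellipsoid(grid, spec.liver_center, spec.liver_axes)
    lung_l = _ellipsoid(grid, spec.lung_left_center, spec.lung_axes)
    lung_r = _ellipsoid(grid, spec.lung_right_center, spec.lung_axes)
    lungs = lung_l | lung_r
    liver = liver_ell & ~lungs & body

    labels = np.zeros(grid.shape, dtype=np.int16)
    table: dict[int, dict] = {}
    labels[body] = 1
    table[1] = {"role": ROLE_BODY}
    labels[liver] = 2
    table[2] = {"role": ROLE_LIVER}
    labels[lung_l] = 3
    table[3] = {"role": ROLE_LUNG_L}
    labels[lung_r] = 4
    table[4] = {"role": ROLE_LUNG_R}

    next_label = 5
    sphere_entries: list[tuple[int, SphereSpec, np.ndarray]] = []
    for i, s in enumerate(spec.spheres):
        try:
            m = sphere_mask(s.center, s.volume_ml, grid)
        except ValueError as exc:
            raise ValueError(f"sphere {i} ({s.volume_ml} mL): {exc}") from exc
        if s.inside_liver and not (m <= liver_ell).all():
            raise ValueError(
                f"sphere {i} ({s.volume_ml} mL) marked intrahepatic but "
                "escapes the liver ellipsoid"
            )
        if not s.inside_liver and not (m <= (body & ~liver_ell & ~lungs)).all():
            raise ValueError(
                f"sphere {i} ({s.volume_ml} mL) marked extrahepatic but "
                "overlaps liver/lungs or leaves the body"
            )
        labels[m] = next_label
        table[next_label] = {
            "role": f"sphere_{i}",
            "inside_liver": bool(s.inside_liver),
            "volume_ml": s.volume_ml,
            "uptake_ratio": s.uptake_ratio,
        }
        sphere_entries.append((next_label, s, m))
        next_label += 1
    for lab, s, m in list(sphere_entries):
        if s.cold_core_ml > 0:
            core = sphere_mask(s.center, s.cold_core_ml, grid)
            labels[core] = next_label
            table[next_label] = {
                "role": f"cold_core_{lab - 5}",
                "inside_liver": bool(s.inside_liver),
                "volume_ml": s.cold_core_ml,
                "uptake_ratio": 0.0,
            }
            next_label += 1

    masks = LabelMasks(labels=labels, table=table, voxel_size=grid.voxel_size)

    act = np.zeros(grid.shape, dtype=np.float64)
    act[masks.mask(ROLE_LIVER)] = 1.0
    for lab, e in table.items():
        if e["role"].startswith("sphere"):
            act[labels == lab] = e["uptake_ratio"]
        elif e["role"].startswith("cold_core"):
            act[labels == lab] = 0.0

    f = spec.lung_shunt_fraction
    lung_vox = masks.lung_mask()
    if f > 0 and lung_vox.any():
        liver_total = act[masks.liver_region_mask()].sum()
        lung_total = liver_total * f / (100.0 - f)
        act[lung_vox] = lung_total / lung_vox.sum()

    total = act.sum()
    if total <= 0:
        raise ValueError("phantom has no activity")
    act *= spec.total_activity / total

    mu = np.zeros(grid.shape, dtype=np.float64)
    mu[body] = spec.mu_soft
    mu[lungs] = spec.mu_lung

    activity = Volume(act, grid.voxel_size, meta={"kind": "torso_phantom"})
    mu_vol = Volume(mu, grid.voxel_size, meta={"kind": "attenuation"})
    return PhantomSet(activity, mu_vol, masks)


def random_torso_phantom(
    seed: int, grid: GridSpec | None = None, texture_strength: float = 0.35
) -> PhantomSet:
    """A randomized variant of the torso phantom, for donor libraries.

    Liver/lung geometry is jittered, sphere contents and LSF are randomized,
    and a smooth multiplicative texture is applied to the liver region so
    donor activity patterns are non-uniform (emulating the heterogeneity of
    reconstructed patient distributions). The lung activity is re-set after
    texturing so the sampled LSF holds exactly.
    """
    grid = grid or GridSpec()
    rng = np.random.default_rng(seed)
    base = TorsoPhantomSpec()
    jitter = lambda c, s: tuple(np.asarray(c) + rng.uniform(-s, s, 3))
    scale = lambda a: tuple(np.asarray(a) * rng.uniform(0.85, 1.1, 3))
    lsf = float(rng.uniform(2.0, 10.0))
    liver_center = jitter(base.liver_center, 10.0)
    liver_axes = scale(base.liver_axes)

    def random_inliver_sphere(volume_ml, ratio, cold=0.0):
        r_mm = (3 * volume_ml * 1000 / (4 * np.pi)) ** (1 / 3)
        for _ in range(200):
            u = rng.uniform(-1, 1, 3) * 0.55
            c = np.asarray(liver_center) + u * np.asarray(liver_axes)
            # entire sphere inside the liver ellipsoid (conservative check)
            if np.linalg.norm(u) + r_mm / min(liver_axes) <= 0.92:
                return SphereSpec(tuple(c), volume_ml, ratio, cold, True)
        return SphereSpec(tuple(liver_center), volume_ml, ratio, cold, True)

    spheres = [
        random_inliver_sphere(
            float(rng.uniform(8.0, 25.0)), float(rng.uniform(3.0, 10.0))
        ),
        random_inliver_sphere(
            float(rng.uniform(10.0, 25.0)),
            float(rng.uniform(3.0, 10.0)),
            cold=float(rng.uniform(2.0, 6.0)),
        ),
    ]
    spec = TorsoPhantomSpec(
        liver_center=liver_center,
        liver_axes=liver_axes,
        spheres=tuple(spheres),
        lung_shunt_fraction=lsf,
        total_activity=base.total_activity,
    )
    ps = make_torso_phantom(spec, grid)

    if texture_strength > 0:
        liver_region = ps.masks.liver_region_mask()
        noise = rng.standard_normal(grid.shape)
        smooth = ndimage.gaussian_filter(noise, sigma=2.5)
        smooth /= max(smooth.std(), 1e-12)
        texture = np.clip(1.0 + texture_strength * smooth, 0.2, None)
        act = ps.activity.data
        act[liver_region] *= texture[liver_region]
        # re-impose the sampled LSF and the total activity after texturing
        lung_vox = ps.masks.lung_mask()
        liver_total = act[liver_region].sum()
        act[lung_vox] = liver_total * lsf / (100.0 - lsf) / lung_vox.sum()
        act *= spec.total_activity / act.sum()
    ps.activity.meta.update(kind="random_torso_phantom", seed=seed, lsf=lsf)
    return ps


@dataclass
class SyntheticVolumeSpec:
    """Configuration for patch-sphere synthetic volume generation.

    ``library`` must hold at least two donors (patches always come from a
    donor other than the one supplying the liver mask). Sphere diameters are
    drawn uniformly from ``diameter_px`` (inclusive, voxels). If
    ``lung_lsf_range`` is not None, the donor's lungs are filled uniformly at
    an LSF drawn from that range so held-out volumes carry a lung
    compartment; set it to None for liver-only volumes.
    """

    library: Sequence[PhantomSet]
    diameter_px: tuple[int, int] = (7, 20)
    seed: int = 0
    total_activity: float = 150.0  # MBq
    lung_lsf_range: tuple[float, float] | None = (2.0, 10.0)


def make_synthetic_volume(spec: SyntheticVolumeSpec) -> PhantomSet:
    """Compose a synthetic activity volume from donor patches.

    One donor supplies the liver mask and attenuation map; spheres with
    random diameters are stamped at random in-liver locations and filled
    with same-shape activity patches copied from *other* donors, until every
    liver voxel is covered (later spheres overwrite earlier ones where they
    overlap). The result is rescaled to ``total_activity``.
    """
    lib = list(spec.library)
    if len(lib) < 2:
        raise ValueError(
            "donor library must contain at least 2 volumes "
            "(patches must come from another donor)"
        )
    dmin, dmax = spec.diameter_px
    if dmin < 1 or dmax < dmin:
        raise ValueError("invalid diameter range")
    rng = np.random.default_rng(spec.seed)

    i0 = int(rng.integers(len(lib)))
    donor0 = lib[i0]
    shape = donor0.activity.shape
    liver = donor0.masks.liver_region_mask()
    liver_idx = np.argwhere(liver)

    # donor in-liver voxel lists for patch source sampling
    others = [i for i in range(len(lib)) if i != i0]
    donor_liver_idx = {
        i: np.argwhere(lib[i].masks.liver_region_mask()) for i in others
    }

    offsets_cache: dict[int, np.ndarray] = {}

    def ball_offsets(d_px: int) -> np.ndarray:
        if d_px not in offsets_cache:
            r = d_px / 2.0
            n = int(np.ceil(r))
            g = np.mgrid[-n : n + 1, -n : n + 1, -n : n + 1]
            keep = (g**2).sum(axis=0) <= r * r
            offsets_cache[d_px] = g[:, keep].T  # (k, 3)
        return offsets_cache[d_px]

    act = np.zeros(shape, dtype=np.float64)
    uncovered = liver.copy()
    n_spheres = 0
    while uncovered.any():
        unc_idx = np.argwhere(uncovered)
        center = unc_idx[int(rng.integers(len(unc_idx)))]
        d_px = int(rng.integers(dmin, dmax + 1))
        offs = ball_offsets(d_px)
        tgt = center[None, :] + offs

        di = others[int(rng.integers(len(others)))]
        donor = lib[di]
        src_liver = donor_liver_idx[di]
        src_center = src_liver[int(rng.integers(len(src_liver)))]
        src = src_center[None, :] + offs

        in_grid = ((tgt >= 0) & (tgt < np.array(shape))).all(axis=1)
        tgt = tgt[in_grid]
        src = src[in_grid]
        tz, ty, tx = tgt.T
        in_liver = liver[tz, ty, tx]
        tgt = tgt[in_liver]
        src = src[in_liver]
        if len(tgt) == 0:
            continue

        vals = np.zeros(len(src))
        src_ok = ((src >= 0) & (src < np.array(shape))).all(axis=1)
        sz, sy, sx = src[src_ok].T
        src_in_liver = donor.masks.liver_region_mask()[sz, sy, sx]
        sel = np.where(src_ok)[0][src_in_liver]
        vals[sel] = donor.activity.data[
            src[sel, 0], src[sel, 1], src[sel, 2]
        ]
        act[tgt[:, 0], tgt[:, 1], tgt[:, 2]] = vals
        uncovered[tgt[:, 0], tgt[:, 1], tgt[:, 2]] = False
        n_spheres += 1

    if spec.lung_lsf_range is not None:
        lung_vox = donor0.masks.lung_mask()
        if lung_vox.any():
            f = float(rng.uniform(*spec.lung_lsf_range))
            liver_total = act[liver].sum()
            if liver_total > 0:
                act[lung_vox] = liver_total * f / (100.0 - f) / lung_vox.sum()

    total = act.sum()
    if total <= 0:
        warnings.warn("synthetic volume has zero activity before rescaling")
    else:
        act *= spec.total_activity / total

    activity = Volume(
        act,
        donor0.activity.voxel_size,
        meta={
            "kind": "synthetic_volume",
            "seed": spec.seed,
            "liver_donor": i0,
            "n_spheres": n_spheres,
            "uncovered_liver_voxels": int(uncovered.sum()),
        },
    )
    return PhantomSet(activity, donor0.mu.copy(), donor0.masks)
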