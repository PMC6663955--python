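"""Analytic parallel-hole SPECT system model.

A rotation-based projector: for each detector angle the volume is resampled
into the detector frame with a precomputed sparse bilinear rotation
operator, attenuated voxel-by-voxel with the cumulative attenuation along
the ray to the detector, blurred per depth plane with the depth-dependent
collimator PSF, and summed along rays. Every building block (sparse
rotation, diagonal attenuation, symmetric zero-padded Gaussian convolution,
ray sum) has an exact matrix adjoint, so forward and back projection form a
true operator pair — the property OSEM's convergence rests on. The rotation
into the detector frame is applied in its mass-conserving (push) form, so
total counts are conserved exactly when attenuation is off.

Scatter is modelled effectively: a fixed fraction of the primary counts,
broadly blurred, is added to the photopeak window and deposited in the
lower energy window, which makes the lower window an (idealized) estimate
of photopeak scatter for dual-energy-window correction downstream. Poisson
noise and binomial count thinning turn noise-free expected counts into
realistic measurements at a chosen scan time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from scipy import ndimage, sparse

from .core import Volume, require_same_grid

__all__ = [
    "DetectorConfig",
    "ProjectionSet",
    "Projector",
    "get_projector",
    "forward_project",
    "back_project",
    "add_scatter",
    "add_poisson",
    "thin_counts",
    "smooth_projections",
]

PHOTOPEAK = "photopeak"
SCATTER = "scatter"

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class DetectorConfig:
    """Acquisition geometry and effective physics parameters.

    Defaults describe a single-head LEHR parallel-hole acquisition with a
    technetium-99m photopeak window of 129-150 keV and a lower scatter
    window of 108-129 keV; 120 angles over 360 degrees and a 20-min scan.
    ``sensitivity`` is detected photopeak counts per MBq*s and is sized so a
    ~157 MBq torso phantom at 20 min yields a few million counts.
    The PSF is Gaussian with sigma(d) = psf_sigma0 + psf_slope * d, d the
    source-to-collimator distance.
    """

    n_angles: int = 120
    windows_kev: tuple[tuple[float, float], ...] = ((129.0, 150.0), (108.0, 129.0))
    sensitivity: float = 3.0  # counts per MBq*s
    psf_sigma0: float = 1.6  # mm
    psf_slope: float = 0.017
    detector_radius: float = 250.0  # mm
    scatter_to_primary: float = 0.3
    scatter_kernel_fwhm: float = 80.0  # mm
    scan_time_s: float = 1200.0

    def __post_init__(self) -> None:
        if self.n_angles < 2:
            raise ValueError("need at least 2 angles")
        if self.sensitivity <= 0:
            raise ValueError("sensitivity must be positive")
        if self.psf_sigma0 < 0 or self.psf_slope < 0:
            raise ValueError("PSF parameters must be non-negative")
        if not 0.0 <= self.scatter_to_primary <= 1.0:
            raise ValueError("scatter_to_primary must be in [0, 1]")

    @property
    def angles_deg(self) -> np.ndarray:
        return np.arange(self.n_angles) * 360.0 / self.n_angles

    def to_dict(self) -> dict[str, Any]:
        return {
            "n_angles": self.n_angles,
            "windows_kev": [list(w) for w in self.windows_kev],
            "sensitivity": self.sensitivity,
            "psf_sigma0": self.psf_sigma0,
            "psf_slope": self.psf_slope,
            "detector_radius": self.detector_radius,
            "scatter_to_primary": self.scatter_to_primary,
            "scatter_kernel_fwhm": self.scatter_kernel_fwhm,
            "scan_time_s": self.scan_time_s,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "DetectorConfig":
        d = dict(d)
        if "windows_kev" in d:
            d["windows_kev"] = tuple(tuple(w) for w in d["windows_kev"])
        return cls(**d)


@dataclass
class ProjectionSet:
    """Per-angle 2D count images for each energy window.

    Window arrays have shape (n_angles, n_v, n_u) where v is the axial
    detector axis (volume z) and u the transaxial axis (rotated x). Values
    are expected counts (float) before noise, sampled counts (integers)
    after.
    """

    windows: dict[str, np.ndarray]
    config: DetectorConfig
    voxel_size: float
    is_noisy: bool = False
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, arr in self.windows.items():
            if name not in (PHOTOPEAK, SCATTER):
                raise ValueError(f"unknown window {name!r}")
            if arr.shape[0] != self.config.n_angles:
                raise ValueError("window/angle count mismatch")
            if (arr < 0).any():
                raise ValueError("projection counts must be non-negative")

    @property
    def photopeak(self) -> np.ndarray:
        return self.windows[PHOTOPEAK]

    @property
    def scan_time_s(self) -> float:
        return self.config.scan_time_s

    def copy(self, **updates: Any) -> "ProjectionSet":
        out = ProjectionSet(
            windows={k: v.copy() for k, v in self.windows.items()},
            config=self.config,
            voxel_size=self.voxel_size,
            is_noisy=self.is_noisy,
            meta=dict(self.meta),
        )
        for k, v in updates.items():
            setattr(out, k, v)
        return out


def _pull_rotation(ny: int, nx: int, angle_deg: float) -> sparse.csr_matrix:
    """Sparse bilinear resampling operator for an in-plane rotation.

    Row r (output pixel) holds the bilinear weights of the input pixels at
    the inverse-rotated location of r; out-of-grid samples get zero weight.
    The transpose is the mass-conserving (push) rotation by the opposite
    angle.
    """
    th = np.deg2rad(angle_deg)
    c, s = np.cos(th), np.sin(th)
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    y0 = yy - cy
    x0 = xx - cx
    ys = c * y0 + s * x0 + cy
    xs = -s * y0 + c * x0 + cx
    yf = np.floor(ys).astype(int)
    xf = np.floor(xs).astype(int)
    wy = ys - yf
    wx = xs - xf
    rows, cols, vals = [], [], []
    out_idx = yy * nx + xx
    for dy, dx, w in (
        (0, 0, (1 - wy) * (1 - wx)),
        (0, 1, (1 - wy) * wx),
        (1, 0, wy * (1 - wx)),
        (1, 1, wy * wx),
    ):
        yi = yf + dy
        xi = xf + dx
        ok = (yi >= 0) & (yi < ny) & (xi >= 0) & (xi < nx) & (w > 0)
        rows.append(out_idx[ok])
        cols.append((yi * nx + xi)[ok])
        vals.append(w[ok])
    m = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(ny * nx, ny * nx),
    )
    return m.tocsr()


def smooth_projections(arr: np.ndarray, fwhm_mm: float, voxel_size: float) -> np.ndarray:
    """Per-angle 2D Gaussian smoothing of a projection stack.

    Wrap-around boundaries keep the normalized kernel count-conserving.
    """
    if fwhm_mm <= 0:
        return arr.astype(np.float64, copy=True)
    sig = fwhm_mm / _FWHM_TO_SIGMA / voxel_size
    out = np.empty(arr.shape, dtype=np.float64)
    for ia in range(arr.shape[0]):
        out[ia] = ndimage.gaussian_filter(
            arr[ia].astype(np.float64), sigma=sig, mode="wrap"
        )
    return out


class Projector:
    """Forward/back projector for one grid + detector configuration.

    Caches the per-angle sparse rotation operators; reuse one instance
    across volumes on the same grid (see :func:`get_projector`).
    """

    def __init__(
        self, shape: tuple[int, int, int], voxel_size: float, cfg: DetectorConfig
    ):
        self.shape = tuple(shape)
        self.voxel_size = float(voxel_size)
        self.cfg = cfg
        nz, ny, nx = self.shape
        if ny != nx:
            raise ValueError("transaxial grid must be square (n_y == n_x)")
        # pull resampling per angle; its transpose pushes into the detector frame
        self._pull = [_pull_rotation(ny, nx, a) for a in cfg.angles_deg]
        self._push = [m.T.tocsr() for m in self._pull]
        # depth-dependent PSF sigma (pixels) per y-plane of the detector frame
        y_world = (np.arange(ny) - (ny - 1) / 2) * self.voxel_size
        depth = np.maximum(cfg.detector_radius - y_world, 0.0)
        self._psf_sigma_px = (cfg.psf_sigma0 + cfg.psf_slope * depth) / self.voxel_size

    # -- frame transforms ---------------------------------------------------
    def to_detector_frame(self, vol: np.ndarray, ia: int) -> np.ndarray:
        """Mass-conserving resample into the frame of detector angle ia."""
        nz, ny, nx = self.shape
        flat = vol.reshape(nz, ny * nx)
        return (self._push[ia] @ flat.T).T.reshape(nz, ny, nx)

    def from_detector_frame(self, vol: np.ndarray, ia: int) -> np.ndarray:
        """Exact adjoint of :meth:`to_detector_frame` (a pull resample)."""
        nz, ny, nx = self.shape
        flat = vol.reshape(nz, ny * nx)
        return (self._pull[ia] @ flat.T).T.reshape(nz, ny, nx)

    def attenuation_factors(self, mu: np.ndarray, ia: int) -> np.ndarray:
        """Survival exp(-integral of mu to the detector) in the detector frame.

        The detector sits at the +y side of the rotated frame; the path
        integral takes half the voxel's own mu plus everything between it
        and the grid edge.
        """
        mu_r = self.to_detector_frame(mu, ia)
        csum = np.cumsum(mu_r[:, ::-1, :], axis=1)[:, ::-1, :] - mu_r
        path = (csum + 0.5 * mu_r) * self.voxel_size
        return np.exp(-path)

    def psf_blur(self, planes: np.ndarray) -> np.ndarray:
        """Blur each y-plane (z, x) with its depth's Gaussian. Self-adjoint
        (symmetric kernel with zero-padded boundaries)."""
        out = np.empty_like(planes)
        for iy in range(planes.shape[1]):
            sig = self._psf_sigma_px[iy]
            if sig <= 1e-6:
                out[:, iy, :] = planes[:, iy, :]
            else:
                out[:, iy, :] = ndimage.gaussian_filter(
                    planes[:, iy, :], sigma=sig, mode="constant", cval=0.0
                )
        return out

    # -- projections --------------------------------------------------------
    def forward(
        self,
        act: np.ndarray,
        mu: np.ndarray | None = None,
        attenuation: bool = True,
        psf: bool = True,
        angles: np.ndarray | list[int] | None = None,
    ) -> np.ndarray:
        """Expected primary photopeak counts, shape (n_used_angles, n_z, n_x).

        ``angles`` selects a subset of angle indices (for ordered subsets);
        default all.
        """
        cfg = self.cfg
        nz, ny, nx = self.shape
        idx = range(cfg.n_angles) if angles is None else list(angles)
        out = np.empty((len(idx), nz, nx))
        scale = cfg.sensitivity * cfg.scan_time_s
        for k, ia in enumerate(idx):
            w = self.to_detector_frame(act, ia)
            if attenuation and mu is not None:
                w = w * self.attenuation_factors(mu, ia)
            if psf:
                w = self.psf_blur(w)
            out[k] = w.sum(axis=1) * scale
        return out

    def backward(
        self,
        proj: np.ndarray,
        mu: np.ndarray | None = None,
        attenuation: bool = True,
        psf: bool = True,
        angles: np.ndarray | list[int] | None = None,
    ) -> np.ndarray:
        """Exact adjoint of :meth:`forward` (same ``angles`` subset)."""
        cfg = self.cfg
        idx = range(cfg.n_angles) if angles is None else list(angles)
        if proj.shape[0] != len(idx):
            raise ValueError("projection stack does not match the angle subset")
        vol = np.zeros(self.shape)
        scale = cfg.sensitivity * cfg.scan_time_s
        for k, ia in enumerate(idx):
            w = np.broadcast_to(proj[k][:, None, :], self.shape).copy()
            if psf:
                w = self.psf_blur(w)
            if attenuation and mu is not None:
                w = w * self.attenuation_factors(mu, ia)
            vol += self.from_detector_frame(w, ia)
        return vol * scale

    def scatter_operator(self, primary: np.ndarray) -> np.ndarray:
        """Effective photopeak scatter for given primary counts."""
        if self.cfg.scatter_to_primary == 0:
            return np.zeros_like(primary)
        return self.cfg.scatter_to_primary * smooth_projections(
            primary, self.cfg.scatter_kernel_fwhm, self.voxel_size
        )


_PROJECTOR_CACHE: dict[tuple, Projector] = {}


def get_projector(
    shape: tuple[int, int, int], voxel_size: float, cfg: DetectorConfig
) -> Projector:
    """Return a cached projector for this grid/detector combination.

    Only geometry-determining fields key the cache (rotation operators and
    PSF widths); scan time, sensitivity and scatter parameters are pure
    scalings read from the current config at call time.
    """
    key = (
        tuple(shape),
        float(voxel_size),
        cfg.n_angles,
        cfg.psf_sigma0,
        cfg.psf_slope,
        cfg.detector_radius,
    )
    if key not in _PROJECTOR_CACHE:
        if len(_PROJECTOR_CACHE) > 8:
            _PROJECTOR_CACHE.clear()
        _PROJECTOR_CACHE[key] = Projector(shape, voxel_size, cfg)
    proj = _PROJECTOR_CACHE[key]
    proj.cfg = cfg
    return proj


def forward_project(
    act: Volume, mu: Volume | None, cfg: DetectorConfig, psf: bool = True
) -> ProjectionSet:
    """Noise-free expected photopeak primary counts for all angles."""
    if mu is not None:
        require_same_grid(act, mu, "activity and attenuation")
    proj = get_projector(act.shape, act.voxel_size, cfg)
    pp = proj.forward(
        act.data.astype(np.float64),
        None if mu is None else mu.data.astype(np.float64),
        attenuation=mu is not None,
        psf=psf,
    )
    return ProjectionSet(
        windows={PHOTOPEAK: pp},
        config=cfg,
        voxel_size=act.voxel_size,
        is_noisy=False,
        meta={"primary_only": True},
    )


def back_project(
    proj: ProjectionSet,
    mu: Volume | None,
    cfg: DetectorConfig,
    attenuation: bool = True,
    psf: bool = True,
    window: str = PHOTOPEAK,
) -> Volume:
    """Adjoint of :func:`forward_project` applied to one window."""
    arr = proj.windows[window]
    nz, nx = arr.shape[1], arr.shape[2]
    shape = (nz, nx, nx) if mu is None else mu.shape
    if mu is not None and (mu.shape[0] != nz or mu.shape[2] != nx):
        raise ValueError("projection geometry does not match attenuation grid")
    p = get_projector(shape, proj.voxel_size, cfg)
    vol = p.backward(
        arr.astype(np.float64),
        None if mu is None else mu.data.astype(np.float64),
        attenuation=attenuation and mu is not None,
        psf=psf,
    )
    return Volume(vol, proj.voxel_size, meta={"kind": "backprojection"})


def add_scatter(
    primary: ProjectionSet, cfg: DetectorConfig | None = None
) -> ProjectionSet:
    """Populate photopeak scatter and the lower energy window.

    photopeak <- primary + S with S = scatter_to_primary x (primary blurred
    with a broad Gaussian per angle); the scatter window is set to S itself,
    i.e. the lower window is a perfect scatter estimate under this effective
    model (the DEW k factor downstream controls the assumed relation).
    Counts are conserved per window. Must run before noise.
    """
    if primary.is_noisy:
        raise ValueError("scatter must be added before noise is sampled")
    cfg = cfg or primary.config
    s = cfg.scatter_to_primary * smooth_projections(
        primary.photopeak, cfg.scatter_kernel_fwhm, primary.voxel_size
    )
    out = primary.copy()
    out.windows[PHOTOPEAK] = primary.photopeak + s
    out.windows[SCATTER] = s
    out.meta["primary_only"] = False
    return out


def add_poisson(proj: ProjectionSet, seed: int) -> ProjectionSet:
    """Replace each bin by a Poisson draw with that bin's expectation."""
    rng = np.random.default_rng(seed)
    out = proj.copy(is_noisy=True)
    for name, arr in proj.windows.items():
        if (arr < 0).any():
            raise ValueError("negative expectations")
        out.windows[name] = rng.poisson(arr).astype(np.int64)
    out.meta["noise_seed"] = int(seed)
    return out


def thin_counts(proj: ProjectionSet, fraction: float, seed: int) -> ProjectionSet:
    """Binomial thinning: retain each recorded count with probability ``fraction``.

    Statistically exact simulation of a shorter scan (metadata scan time is
    scaled accordingly); requires sampled integer counts.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    for arr in proj.windows.values():
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("thinning requires sampled integer counts")
    out = proj.copy()
    if fraction < 1.0:
        rng = np.random.default_rng(seed)
        for name, arr in proj.windows.items():
            out.windows[name] = rng.binomial(arr, fraction)
    out.config = replace(proj.config, scan_time_s=proj.config.scan_time_s * fraction)
    out.meta["thinned_fraction"] = float(fraction)
    return out
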