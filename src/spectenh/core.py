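"""Core containers: voxel grids and volumes.

Array convention: volumes are numpy arrays indexed ``[z, y, x]`` (axis 0 is
the axial direction, i.e. the slice axis). World coordinates are in mm,
voxel-center based, with the origin at the grid center; world x/y/z map to
array axes 2/1/0. Activity volumes store MBq per voxel, attenuation maps
store linear attenuation coefficients per mm at 140 keV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

__all__ = ["GridSpec", "Volume"]


@dataclass(frozen=True)
class GridSpec:
    """Isotropic voxel grid.

    The default is the desk-scale grid (64^3 at 7.8 mm); :meth:`full_scale`
    returns the clinical-matrix grid (128^3 at 3.9 mm). Both span the same
    physical extent (~500 mm per axis).
    """

    n_x: int = 64
    n_y: int = 64
    n_z: int = 64
    voxel_size: float = 7.8  # mm, isotropic

    def __post_init__(self) -> None:
        if min(self.n_x, self.n_y, self.n_z) < 8:
            raise ValueError("grid must have at least 8 voxels per axis")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @classmethod
    def full_scale(cls) -> "GridSpec":
        return cls(n_x=128, n_y=128, n_z=128, voxel_size=3.9)

    @property
    def shape(self) -> tuple[int, int, int]:
        """Array shape (n_z, n_y, n_x)."""
        return (self.n_z, self.n_y, self.n_x)

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_size**3 / 1000.0

    def world_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-center world coordinates (z, y, x), each broadcastable to shape."""
        z = (np.arange(self.n_z) - (self.n_z - 1) / 2) * self.voxel_size
        y = (np.arange(self.n_y) - (self.n_y - 1) / 2) * self.voxel_size
        x = (np.arange(self.n_x) - (self.n_x - 1) / 2) * self.voxel_size
        return (
            z[:, None, None],
            y[None, :, None],
            x[None, None, :],
        )

    def to_dict(self) -> dict[str, Any]:
        return {
            "n_x": self.n_x,
            "n_y": self.n_y,
            "n_z": self.n_z,
            "voxel_size": self.voxel_size,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "GridSpec":
        return cls(**d)


@dataclass
class Volume:
    """A 3D image on a :class:`GridSpec`-compatible grid.

    ``data`` is indexed [z, y, x]; ``voxel_size`` is in mm. ``meta`` carries
    provenance (method tags, seeds, units) and is preserved through I/O.
    """

    data: np.ndarray
    voxel_size: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("Volume data must be 3D")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def grid(self) -> GridSpec:
        nz, ny, nx = self.data.shape
        return GridSpec(n_x=nx, n_y=ny, n_z=nz, voxel_size=self.voxel_size)

    @property
    def total(self) -> float:
        """Sum over voxels (total MBq for an activity volume)."""
        return float(self.data.sum())

    def copy(self, data: np.ndarray | None = None, **meta: Any) -> "Volume":
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return Volume(
            data=self.data.copy() if data is None else data,
            voxel_size=self.voxel_size,
            meta=new_meta,
        )

    def same_grid(self, other: "Volume") -> bool:
        return self.shape == other.shape and np.isclose(
            self.voxel_size, other.voxel_size
        )


def require_same_grid(a: Volume, b: Volume, what: str = "volumes") -> None:
    if not a.same_grid(b):
        raise ValueError(
            f"{what} must share a grid: {a.shape}@{a.voxel_size}mm vs "
            f"{b.shape}@{b.voxel_size}mm"
        )


# re-export for convenience
_ = replace
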