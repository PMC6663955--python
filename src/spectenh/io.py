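"""Reading and writing volumes, projections, masks and models.

Volumes travel as NIfTI (.nii.gz) with the voxel size in the header and a
JSON sidecar (``<stem>.meta.json``) for provenance metadata. Projection
sets are one NIfTI stack per energy window plus one JSON sidecar holding
the detector configuration, windows, scan time and noise state. Label
volumes carry their label table in a JSON sidecar. Models are an npz of
weight arrays plus a JSON manifest (architecture, training history).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import Volume
from .enhancer import EnhancerModel, NetSpec, TrainConfig, build_network
from .phantom import LabelMasks
from .projector import DetectorConfig, ProjectionSet

__all__ = [
    "save_volume",
    "load_volume",
    "save_projections",
    "load_projections",
    "save_masks",
    "load_masks",
    "save_model",
    "load_model",
]


def _sidecar(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".meta.json")
    return path.with_suffix(".meta.json")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def save_volume(vol: Volume, path: str | Path) -> Path:
    """Write a volume as NIfTI; array axes (z, y, x) map to NIfTI (x, y, z)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag([vol.voxel_size] * 3 + [1.0])
    img = nib.Nifti1Image(np.asarray(vol.data).T, affine)
    img.header.set_zooms((vol.voxel_size,) * 3)
    nib.save(img, str(path))
    _sidecar(path).write_text(
        json.dumps({"voxel_size": vol.voxel_size, "meta": _jsonable(vol.meta)})
    )
    return path


def load_volume(path: str | Path) -> Volume:
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj).T
    voxel = float(img.header.get_zooms()[0])
    meta = {}
    sc = _sidecar(path)
    if sc.exists():
        d = json.loads(sc.read_text())
        voxel = float(d.get("voxel_size", voxel))
        meta = d.get("meta", {})
    return Volume(data, voxel, meta=meta)


def save_projections(proj: ProjectionSet, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, arr in proj.windows.items():
        img = nib.Nifti1Image(np.asarray(arr, dtype=np.float64).T, np.eye(4))
        nib.save(img, str(out_dir / f"{name}.nii.gz"))
    sidecar = {
        "config": proj.config.to_dict(),
        "voxel_size": proj.voxel_size,
        "is_noisy": proj.is_noisy,
        "windows": sorted(proj.windows),
        "meta": _jsonable(proj.meta),
    }
    (out_dir / "projections.json").write_text(json.dumps(sidecar, indent=1))
    return out_dir


def load_projections(in_dir: str | Path) -> ProjectionSet:
    in_dir = Path(in_dir)
    sc_path = in_dir / "projections.json"
    if not sc_path.exists():
        raise FileNotFoundError(f"missing projection sidecar {sc_path}")
    sc = json.loads(sc_path.read_text())
    for key in ("config", "voxel_size", "windows"):
        if key not in sc:
            raise ValueError(f"projection sidecar missing field {key!r}")
    windows = {}
    for name in sc["windows"]:
        arr = np.asarray(nib.load(str(in_dir / f"{name}.nii.gz")).dataobj).T
        if sc.get("is_noisy"):
            arr = np.rint(arr).astype(np.int64)
        windows[name] = arr
    return ProjectionSet(
        windows=windows,
        config=DetectorConfig.from_dict(sc["config"]),
        voxel_size=float(sc["voxel_size"]),
        is_noisy=bool(sc.get("is_noisy", False)),
        meta=sc.get("meta", {}),
    )


def save_masks(masks: LabelMasks, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag([masks.voxel_size] * 3 + [1.0])
    img = nib.Nifti1Image(masks.labels.astype(np.int16).T, affine)
    nib.save(img, str(path))
    _sidecar(path).write_text(
        json.dumps(
            {"voxel_size": masks.voxel_size, "table": _jsonable(masks.table)}
        )
    )
    return path


def load_masks(path: str | Path) -> LabelMasks:
    path = Path(path)
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj).astype(np.int16).T
    d = json.loads(_sidecar(path).read_text())
    table = {int(k): v for k, v in d["table"].items()}
    return LabelMasks(labels=labels, table=table, voxel_size=float(d["voxel_size"]))


def save_model(model: EnhancerModel, prefix: str | Path) -> Path:
    """Write ``<prefix>.npz`` (weights) and ``<prefix>.json`` (manifest)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(str(prefix) + ".npz", **model.net.params)
    manifest = {
        "net_spec": vars(model.net_spec).copy()
        if not isinstance(model.net_spec, dict)
        else model.net_spec,
        "train_cfg": None if model.train_cfg is None else vars(model.train_cfg).copy(),
        "history": model.history,
        "best_epoch": model.best_epoch,
        "meta": _jsonable(model.meta),
    }
    Path(str(prefix) + ".json").write_text(json.dumps(_jsonable(manifest), indent=1))
    return prefix


def load_model(prefix: str | Path) -> EnhancerModel:
    prefix = str(prefix)
    manifest = json.loads(Path(prefix + ".json").read_text())
    spec = NetSpec(**manifest["net_spec"])
    model = build_network(spec, seed=0)
    with np.load(prefix + ".npz") as npz:
        model.net.set_weights({k: npz[k] for k in npz.files})
    model.history = manifest.get("history", {"train_loss": [], "val_loss": []})
    model.best_epoch = manifest.get("best_epoch")
    model.meta = manifest.get("meta", {})
    if manifest.get("train_cfg"):
        model.train_cfg = TrainConfig(**manifest["train_cfg"])
    return model
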