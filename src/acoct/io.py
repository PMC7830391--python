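"""Reading and writing of geometries, volumes and projection stacks.

Geometries and phantom specs are plain YAML/JSON mappings.  Volumes are
written as NIfTI (via nibabel), multi-page TIFF (via tifffile) or ``.npy``;
projection stacks as TIFF/NIfTI/``.npy`` with a sidecar JSON recording the
angle list and any noise metadata.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile
import yaml

from .geometry import ImageVolume, ProjectionSet, ScanGeometry
from .phantoms import NoiseModel, PhantomSpec

__all__ = [
    "load_geometry",
    "save_geometry",
    "load_phantom_spec",
    "save_phantom_spec",
    "load_volume",
    "save_volume",
    "load_projections",
    "save_projections",
]


def _load_mapping(path: Path) -> dict:
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def _save_mapping(obj: dict, path: Path) -> None:
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(obj, sort_keys=False))
    else:
        path.write_text(json.dumps(obj, indent=2))


def load_geometry(path: str | Path) -> ScanGeometry:
    return ScanGeometry.from_dict(_load_mapping(Path(path)))


def save_geometry(geom: ScanGeometry, path: str | Path) -> None:
    _save_mapping(geom.to_dict(), Path(path))


def load_phantom_spec(path: str | Path) -> PhantomSpec:
    return PhantomSpec.from_dict(_load_mapping(Path(path)))


def save_phantom_spec(spec: PhantomSpec, path: str | Path) -> None:
    _save_mapping(spec.to_dict(), Path(path))


def save_volume(vol: ImageVolume, path: str | Path) -> None:
    path = Path(path)
    if path.name.endswith((".nii", ".nii.gz")):
        affine = np.diag(list(vol.voxel_size) + [1.0] * (4 - vol.values.ndim))
        if affine.shape != (4, 4):
            aff = np.eye(4)
            aff[: vol.values.ndim, : vol.values.ndim] = np.diag(vol.voxel_size)
            affine = aff
        nib.save(nib.Nifti1Image(vol.values, affine), str(path))
    elif path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, vol.values.astype(np.float32))
        _save_mapping({"voxel_size": list(vol.voxel_size)}, path.with_suffix(".json"))
    elif path.suffix == ".npy":
        np.save(path, vol.values)
        _save_mapping({"voxel_size": list(vol.voxel_size)}, path.with_suffix(".json"))
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")


def load_volume(path: str | Path, voxel_size=None) -> ImageVolume:
    path = Path(path)
    if path.name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        if voxel_size is None:
            voxel_size = tuple(float(z) for z in img.header.get_zooms()[: data.ndim])
        return ImageVolume(data, voxel_size)
    if path.suffix in (".tif", ".tiff"):
        data = np.asarray(tifffile.imread(path), dtype=np.float64)
    elif path.suffix == ".npy":
        data = np.load(path)
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")
    if voxel_size is None:
        side = path.with_suffix(".json")
        if side.exists():
            voxel_size = tuple(_load_mapping(side)["voxel_size"])
        else:
            voxel_size = (1.0,) * data.ndim
    return ImageVolume(data, voxel_size)


def save_projections(
    proj: ProjectionSet, path: str | Path, noise: NoiseModel | None = None
) -> None:
    """Projection stack plus a sidecar JSON with angles and noise metadata."""
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, proj.values.astype(np.float32))
    elif path.suffix == ".npy":
        np.save(path, proj.values)
    elif path.name.endswith((".nii", ".nii.gz")):
        nib.save(nib.Nifti1Image(proj.values, np.eye(4)), str(path))
    else:
        raise ValueError(f"unsupported projection format: {path.suffix}")
    meta: dict = {"angles": list(proj.angles)}
    if noise is not None:
        meta["noise"] = asdict(noise)
    _save_mapping(meta, _sidecar(path))


def _sidecar(path: Path) -> Path:
    return path.parent / (path.name.split(".")[0] + ".meta.json")


def load_projections(path: str | Path) -> ProjectionSet:
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        data = np.asarray(tifffile.imread(path), dtype=np.float64)
    elif path.suffix == ".npy":
        data = np.load(path)
    elif path.name.endswith((".nii", ".nii.gz")):
        data = np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)
    else:
        raise ValueError(f"unsupported projection format: {path.suffix}")
    meta = _load_mapping(_sidecar(path))
    return ProjectionSet(data, tuple(meta["angles"]))
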