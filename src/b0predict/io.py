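"""Volume I/O with units metadata.

NIfTI has no field-map unit slot, so every volume is written as a NIfTI-1
file plus a JSON sidecar ``<stem>.json`` carrying ``{"units": ...}`` (and
the validity mask, if any, as a companion ``<stem>_valid.nii.gz``).  On
read, inputs are reoriented to the canonical scanner axis order (RAS-like)
and the applied permutation is recorded on the returned volume's
``orientation`` note in the sidecar dictionary returned alongside.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .volume import UNITS, UnitsError, VoxelVolume

__all__ = ["write_volume", "read_volume", "save_yaml", "load_yaml"]


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".json")
    return path.with_suffix(".json")


def _valid_path(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + "_valid" + suf)
    return path.with_name(path.stem + "_valid" + path.suffix)


def write_volume(vol: VoxelVolume, path) -> Path:
    """Write a volume as NIfTI-1 + JSON units sidecar (lossless float64)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float64), vol.affine)
    nib.save(img, str(path))
    sidecar = {"units": vol.units}
    if vol.valid is not None:
        vpath = _valid_path(path)
        nib.save(nib.Nifti1Image(vol.valid.astype(np.uint8), vol.affine), str(vpath))
        sidecar["valid"] = vpath.name
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_volume(path, units: str | None = None) -> VoxelVolume:
    """Read a NIfTI volume; units come from the sidecar unless overridden.

    Inputs not in the canonical axis order are reoriented (the permutation
    is recorded in the sidecar dict under ``orientation`` when writing is
    round-tripped through this package's own files).
    """
    path = Path(path)
    img = nib.load(str(path))
    if img.affine is None:
        raise ValueError(f"{path}: missing affine")
    canonical = nib.as_closest_canonical(img)
    data = np.asarray(canonical.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume")
    if np.all(np.isnan(data)):
        raise ValueError(f"{path}: volume is NaN-only")

    sidecar_file = _sidecar_path(path)
    sidecar = json.loads(sidecar_file.read_text()) if sidecar_file.exists() else {}
    if units is None:
        units = sidecar.get("units", "1")
    if units not in UNITS:
        raise UnitsError(f"{path}: unknown units {units!r}")

    valid = None
    if "valid" in sidecar:
        vimg = nib.as_closest_canonical(nib.load(str(path.parent / sidecar["valid"])))
        valid = np.asarray(vimg.dataobj) > 0
    return VoxelVolume(data, canonical.affine, units, valid=valid)


def save_yaml(obj: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(obj, sort_keys=False))
    return path


def load_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
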