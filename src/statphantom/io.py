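"""Volume I/O: NRRD label grids with a YAML organ/material sidecar.

The label grid is written as a standard NRRD file (uint16) with the cm
spacing and origin in the header; the organ map travels in a small
human-readable YAML sidecar next to it (``<stem>.organs.yaml``), since
NRRD has no native notion of label semantics.  Round trips are exact.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import SimpleITK as sitk
import yaml

from .grid import LabeledVolume


def sidecar_path(path) -> Path:
    path = Path(path)
    return path.parent / (path.stem + ".organs.yaml")


def write_volume(phantom: LabeledVolume, path) -> Path:
    """Write a phantom as NRRD + organ-map sidecar; returns the NRRD path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # SimpleITK arrays are indexed [z, y, x]; ours are [x, y, z].
    img = sitk.GetImageFromArray(np.ascontiguousarray(phantom.labels.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in phantom.spacing))
    img.SetOrigin(tuple(float(o) for o in phantom.origin))
    sitk.WriteImage(img, str(path), useCompression=False)
    organs = {
        int(oid): {"name": name, "material": int(mat)}
        for oid, (name, mat) in phantom.organ_map.items()
    }
    with open(sidecar_path(path), "w") as fh:
        yaml.safe_dump({"organs": organs}, fh, sort_keys=True)
    return path


def read_volume(path) -> LabeledVolume:
    """Read an NRRD label grid and its organ-map sidecar."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = sitk.ReadImage(str(path))
    spacing = img.GetSpacing()
    if any(s <= 0 for s in spacing):
        raise ValueError(f"{path}: non-positive voxel spacing {spacing}")
    labels = sitk.GetArrayFromImage(img)
    if labels.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {labels.ndim}D")
    labels = np.ascontiguousarray(labels.transpose(2, 1, 0))
    side = sidecar_path(path)
    if not side.exists():
        raise FileNotFoundError(f"organ-map sidecar not found: {side}")
    with open(side) as fh:
        meta = yaml.safe_load(fh)
    organ_map = {
        int(oid): (entry["name"], int(entry["material"]))
        for oid, entry in meta.get("organs", {}).items()
    }
    present = sorted(int(lab) for lab in np.unique(labels)
                     if lab != 0 and int(lab) not in organ_map)
    if present:
        raise ValueError(f"{path}: labels missing from sidecar organ map: {present}")
    return LabeledVolume(labels.astype(np.uint16), spacing=spacing,
                         origin=img.GetOrigin(), organ_map=organ_map)
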