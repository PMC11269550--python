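"""NIfTI-1 and sidecar file helpers.

Conventions:

* DWI volumes are 4-D NIfTI (x, y, z, volume) with FSL-dialect ``.bval`` /
  ``.bvec`` text files alongside.
* Tensor fields are 4-D NIfTI with 6 components in lower-triangular order
  (Dxx, Dxy, Dyy, Dxz, Dyz, Dzz).
* Scalar maps are one 3-D NIfTI per metric, grid and affine copied from
  the source volume.
* Label maps are integer NIfTI with a JSON sidecar mapping codes to ROI
  names.

Volumes are written uncompressed (``.nii``) so identical data yields
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "save_volume",
    "load_volume",
    "save_label_map",
    "load_label_map",
]


def save_volume(
    data: np.ndarray, path: str | Path, affine: np.ndarray | None = None
) -> Path:
    """Write an array as NIfTI-1; returns the path written."""
    path = Path(path)
    if affine is None:
        affine = np.eye(4)
    img = nib.Nifti1Image(np.asarray(data), affine)
    nib.save(img, str(path))
    return path


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI volume; returns (data, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def save_label_map(
    labels: np.ndarray,
    roi_names: dict[str, int],
    path: str | Path,
    affine: np.ndarray | None = None,
) -> Path:
    """Write an integer label volume plus its ``.json`` code sidecar."""
    path = Path(path)
    save_volume(np.asarray(labels, dtype=np.int16), path, affine)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps({str(code): name for name, code in roi_names.items()}, indent=2)
        + "\n"
    )
    return path


def load_label_map(path: str | Path) -> tuple[np.ndarray, dict[str, int]]:
    """Read a label volume and its sidecar; returns (labels, name -> code)."""
    labels, _ = load_volume(path)
    sidecar = Path(path).with_suffix(".json")
    codes = json.loads(sidecar.read_text())
    return labels.astype(np.int16), {name: int(code) for code, name in codes.items()}
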