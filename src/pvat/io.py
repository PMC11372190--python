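"""NIfTI and JSON input/output helpers.

Volumes and masks travel as NIfTI-1 with the voxel spacing in the header;
landmarks as JSON lists of ``{"name", "x_mm", "y_mm", "z_mm"}`` records.
All physical coordinates are millimetres in the scanner-aligned frame
``index * spacing`` (diagonal affine); non-diagonal affines are flagged by
:func:`pvat.pipeline.validate_inputs` rather than silently reinterpreted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np


@dataclass
class CTVolume:
    """A 3-D scalar field of Hounsfield units on an anisotropic voxel grid."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_volume(volume: CTVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32), _affine(volume.spacing))
    nib.save(img, str(path))


def load_volume(path: str | Path) -> CTVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return CTVolume(data=data, spacing=spacing)


def save_mask(mask: np.ndarray, spacing, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(spacing))
    nib.save(img, str(path))


def load_mask(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data != 0, spacing


def load_mask_raw(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float], np.ndarray]:
    """Mask voxels as stored (no binarisation), spacing, and the affine."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing, np.asarray(img.affine)


def save_landmarks(landmarks: dict[str, np.ndarray], path: str | Path) -> None:
    records = [
        {"name": name, "x_mm": float(p[0]), "y_mm": float(p[1]), "z_mm": float(p[2])}
        for name, p in sorted(landmarks.items())
    ]
    Path(path).write_text(json.dumps(records, indent=2) + "\n")


def load_landmarks(path: str | Path) -> dict[str, np.ndarray]:
    records = json.loads(Path(path).read_text())
    return {
        r["name"]: np.array([r["x_mm"], r["y_mm"], r["z_mm"]], dtype=float) for r in records
    }


def save_label_map(
    labels: np.ndarray, spacing, legend: dict[str, int], path: str | Path
) -> None:
    """Integer-coded section label map plus a JSON legend next to it."""
    img = nib.Nifti1Image(np.asarray(labels, dtype=np.int16), _affine(spacing))
    nib.save(img, str(path))
    legend_path = Path(str(path).replace(".nii.gz", "").replace(".nii", "") + "_legend.json")
    legend_path.write_text(json.dumps(legend, indent=2) + "\n")
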