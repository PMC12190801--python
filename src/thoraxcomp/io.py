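"""NIfTI input/output for CT volumes and organ labelmaps.

Volumes and masks are kept on a fixed internal axis convention:
array axes are (x, y, z) with z ascending cranio-caudally toward the
head.  Files are reoriented to closest-canonical (RAS+) on read, which
realises that convention for any NIfTI with a valid affine.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

__all__ = [
    "CTVolume",
    "OrganMaskSet",
    "VolumeIOError",
    "MaskAlignmentError",
    "VERTEBRA_NAMES",
    "read_volume",
    "write_volume",
    "read_mask_set",
    "write_mask",
    "load_mask_sidecar",
]

#: canonical names for the thoracic vertebral masks, T1 (superior) .. T12
VERTEBRA_NAMES = tuple(f"vertebra_T{i}" for i in range(1, 13))


class VolumeIOError(ValueError):
    """Raised when a file cannot be interpreted as a valid CT volume."""


class MaskAlignmentError(ValueError):
    """Raised when a mask does not align with its reference CT volume."""


@dataclass(frozen=True)
class CTVolume:
    """A 3-D grid of CT attenuation values in Hounsfield units.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Attenuation values in HU.  z is cranio-caudal, head at high z.
    spacing : tuple of float
        Voxel spacing (dx, dy, dz) in millimetres; all positive.
    origin : tuple of float
        Physical offset of voxel (0, 0, 0) in millimetres.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3 or vox.size == 0:
            raise VolumeIOError(
                f"CT volume must be a non-empty 3-D grid, got shape {vox.shape}"
            )
        if not np.all(np.isfinite(vox)):
            raise VolumeIOError("CT volume contains non-finite attenuation values")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise VolumeIOError(f"voxel spacing must be three positive values, got {self.spacing}")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz


@dataclass
class OrganMaskSet:
    """Named binary masks aligned to one CT grid.

    Recognised names include ``lungs``, ``heart``, ``eat``, ``body`` and
    the vertebral masks ``vertebra_T1`` .. ``vertebra_T12``.  Vertebral
    masks must be pairwise disjoint.  A free-form ``provenance`` tag per
    mask records where it came from (model output, phantom truth, ...).
    """

    masks: dict[str, np.ndarray]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.masks:
            raise MaskAlignmentError("mask set is empty")
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) != 1:
            raise MaskAlignmentError(f"masks have inconsistent shapes: {sorted(shapes)}")
        self.masks = {name: np.asarray(m, dtype=bool) for name, m in self.masks.items()}
        self._check_vertebrae_disjoint()

    def _check_vertebrae_disjoint(self) -> None:
        present = [n for n in VERTEBRA_NAMES if n in self.masks]
        if len(present) < 2:
            return
        stack = np.zeros(self.shape, dtype=np.uint8)
        for n in present:
            stack += self.masks[n]
        if stack.max() > 1:
            raise MaskAlignmentError("vertebra masks overlap; labels must be pairwise disjoint")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.masks.values())).shape

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def get(self, name: str) -> np.ndarray | None:
        return self.masks.get(name)

    def require(self, name: str) -> np.ndarray:
        if name not in self.masks:
            raise MaskAlignmentError(f"required mask {name!r} is missing")
        return self.masks[name]

    def union(self, names) -> np.ndarray:
        out = np.zeros(self.shape, dtype=bool)
        for n in names:
            if n in self.masks:
                out |= self.masks[n]
        return out


def _canonical(img: nib.Nifti1Image) -> nib.Nifti1Image:
    try:
        return nib.as_closest_canonical(img)
    except Exception as exc:  # unusual affines
        raise VolumeIOError(f"cannot reorient image to canonical axes: {exc}") from exc


def read_volume(path) -> CTVolume:
    """Read a single-channel 3-D NIfTI image as a :class:`CTVolume`."""
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"volume file not found: {path}")
    img = _canonical(nib.load(str(path)))
    if img.ndim != 3:
        raise VolumeIOError(f"{path} is {img.ndim}-D; expected a scalar 3-D image")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(s <= 0 for s in spacing):
        raise VolumeIOError(f"{path} has non-positive voxel spacing {spacing}")
    data = np.asarray(img.get_fdata(dtype=np.float64))
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return CTVolume(voxels=data, spacing=spacing, origin=origin)


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    aff[:3, 3] = origin
    return aff


def write_volume(volume: CTVolume, path) -> Path:
    """Write a :class:`CTVolume` to NIfTI (float64, lossless round-trip)."""
    path = Path(path)
    img = nib.Nifti1Image(volume.voxels.astype(np.float64), _affine(volume.spacing, volume.origin))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))
    return path


def write_mask(mask: np.ndarray, spacing, path, origin=(0.0, 0.0, 0.0)) -> Path:
    """Write a binary or small-integer labelmap as uint8 NIfTI."""
    path = Path(path)
    arr = np.asarray(mask)
    if arr.ndim != 3:
        raise VolumeIOError(f"labelmap must be 3-D, got shape {arr.shape}")
    img = nib.Nifti1Image(arr.astype(np.uint8), _affine(spacing, origin))
    img.header.set_zooms(tuple(spacing))
    nib.save(img, str(path))
    return path


def _load_mask_file(name: str, path: Path, label: int | None, reference: CTVolume) -> np.ndarray:
    if not path.exists():
        raise VolumeIOError(f"mask file for {name!r} not found: {path}")
    img = _canonical(nib.load(str(path)))
    if img.ndim != 3:
        raise MaskAlignmentError(f"mask {name!r} is {img.ndim}-D; expected 3-D")
    data = np.asarray(img.dataobj)
    if data.shape != reference.shape:
        raise MaskAlignmentError(
            f"mask {name!r} has shape {data.shape}, reference volume is {reference.shape}"
        )
    if label is None:
        return data != 0
    return data == label


def read_mask_set(entries: Mapping, reference: CTVolume, provenance: str = "file") -> OrganMaskSet:
    """Load a name -> file mapping into an :class:`OrganMaskSet`.

    ``entries`` values are either a path (nonzero voxels become the mask)
    or a ``(path, label)`` pair / ``{"path": ..., "label": ...}`` mapping
    selecting one integer from a multi-label atlas file.  All masks are
    binarized and checked against the reference grid; vertebral masks
    must not overlap.
    """
    masks: dict[str, np.ndarray] = {}
    for name, entry in entries.items():
        if isinstance(entry, Mapping):
            path, label = Path(entry["path"]), entry.get("label")
        elif isinstance(entry, (tuple, list)):
            path, label = Path(entry[0]), int(entry[1])
        else:
            path, label = Path(entry), None
        masks[name] = _load_mask_file(name, path, label, reference)
    return OrganMaskSet(masks=masks, provenance={n: provenance for n in masks})


def load_mask_sidecar(path) -> dict:
    """Read a JSON/YAML sidecar mapping mask names to files (or atlas labels).

    Relative paths are resolved against the sidecar's directory.
    """
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        import yaml

        entries = yaml.safe_load(path.read_text())
    else:
        entries = json.loads(path.read_text())
    if not isinstance(entries, dict):
        raise VolumeIOError(f"mask sidecar {path} must map names to files")
    resolved = {}
    for name, entry in entries.items():
        if isinstance(entry, Mapping):
            entry = dict(entry)
            entry["path"] = str((path.parent / entry["path"]).resolve())
        elif isinstance(entry, (tuple, list)):
            entry = [str((path.parent / entry[0]).resolve()), int(entry[1])]
        else:
            entry = str((path.parent / entry).resolve())
        resolved[name] = entry
    return resolved
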