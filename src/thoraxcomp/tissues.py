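"""HU-based tissue attribution within the compartmentalised thorax.

Attenuation classes come from closed HU intervals (adipose -190..-30,
muscle -29..+150, bone +151..+1200).  Attribution rules:

* intrathoracic adipose-density voxels are VAT, unless covered by the
  epicardial fat mask (then EAT);
* extrathoracic muscle-density voxels are skeletal muscle (SM);
* bone-density voxels are bone in any compartment;
* extrathoracic adipose-density voxels are SAT when their connected
  component touches the skin (the outermost body-surface shell) and
  IMAT otherwise;
* everything else is unassigned.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .compartments import CompartmentMap
from .io import CTVolume

__all__ = [
    "HuRanges",
    "TissueLabelMap",
    "DENSITY_CODES",
    "TISSUE_CODES",
    "classify_hu",
    "assign_tissues",
    "split_sat_imat",
    "body_surface_shell",
]

#: density-class codes returned by :func:`classify_hu`
DENSITY_CODES = {"unassigned": 0, "adipose": 1, "muscle": 2, "bone": 3}

#: tissue labelmap codes (NIfTI code table)
TISSUE_CODES = {"unassigned": 0, "sm": 1, "bone": 2, "sat": 3, "imat": 4, "vat": 5, "eat": 6}


@dataclass(frozen=True)
class HuRanges:
    """Closed HU intervals for the three attenuation classes."""

    adipose: tuple[float, float] = (-190.0, -30.0)
    muscle: tuple[float, float] = (-29.0, 150.0)
    bone: tuple[float, float] = (151.0, 1200.0)

    def __post_init__(self) -> None:
        for name in ("adipose", "muscle", "bone"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} interval {lo}..{hi} is empty")
        if not (self.adipose[1] < self.muscle[0] <= self.muscle[1] < self.bone[0]):
            raise ValueError("HU intervals must be disjoint and ordered adipose < muscle < bone")


@dataclass
class TissueLabelMap:
    """Per-voxel tissue assignment on the T5-T11 slab."""

    labels: np.ndarray  # uint8, codes per TISSUE_CODES
    slab: tuple[int, int]
    spacing: tuple[float, float, float]

    def mask(self, tissue: str) -> np.ndarray:
        return self.labels == TISSUE_CODES[tissue]

    def count(self, tissue: str) -> int:
        return int(np.count_nonzero(self.labels == TISSUE_CODES[tissue]))


def classify_hu(values, ranges: HuRanges = HuRanges()):
    """Map HU values to density classes (total on finite HU, closed bounds).

    Accepts scalars or arrays; returns codes per :data:`DENSITY_CODES`.
    """
    arr = np.asarray(values, dtype=float)
    out = np.zeros(arr.shape, dtype=np.uint8)
    for name in ("adipose", "muscle", "bone"):
        lo, hi = getattr(ranges, name)
        out[(arr >= lo) & (arr <= hi)] = DENSITY_CODES[name]
    if np.isscalar(values) or arr.ndim == 0:
        return int(out)
    return out


def body_surface_shell(body: np.ndarray) -> np.ndarray:
    """Outermost 1-voxel layer of the body mask (26-connected erosion difference)."""
    eroded = ndi.binary_erosion(body, structure=np.ones((3, 3, 3), dtype=bool))
    return body & ~eroded


def split_sat_imat(adipose: np.ndarray, body: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Partition extrathoracic adipose into skin-contacting SAT and interior IMAT.

    26-connected components of the adipose mask that intersect the body
    surface shell become SAT in their entirety; all remaining
    components are IMAT.
    """
    sat = np.zeros_like(adipose)
    imat = np.zeros_like(adipose)
    if not adipose.any():
        return sat, imat
    shell = body_surface_shell(body)
    labelled, n = ndi.label(adipose, structure=np.ones((3, 3, 3), dtype=bool))
    touching = np.unique(labelled[shell & adipose])
    touching = touching[touching > 0]
    sat = np.isin(labelled, touching) & adipose
    imat = adipose & ~sat
    return sat, imat


def assign_tissues(
    volume: CTVolume,
    compartments: CompartmentMap,
    eat_mask: np.ndarray | None = None,
    ranges: HuRanges = HuRanges(),
    eat_density_gated: bool = True,
    body_mask: np.ndarray | None = None,
) -> TissueLabelMap:
    """Attribute every slab body voxel to one of the six tissues (or unassigned).

    ``eat_density_gated`` keeps only adipose-density voxels of the EAT
    mask as EAT (so EAT density is computed over fat-density voxels,
    consistent with the other adipose tissues); with the flag off, every
    intrathoracic EAT-mask voxel is EAT regardless of attenuation.

    ``body_mask`` (full-extent, not slab-cropped) defines the skin
    surface used by the SAT/IMAT split; when omitted, the slab-cropped
    compartment body is used.
    """
    if volume.shape != compartments.labels.shape:
        raise ValueError(
            f"volume {volume.shape} and compartments {compartments.labels.shape} are misaligned"
        )
    if eat_mask is None:
        eat_mask = np.zeros(volume.shape, dtype=bool)
    elif eat_mask.shape != volume.shape:
        raise ValueError("EAT mask is misaligned with the CT volume")

    density = classify_hu(volume.voxels, ranges)
    intra = compartments.intrathoracic
    extra = compartments.extrathoracic
    in_body = intra | extra

    labels = np.zeros(volume.shape, dtype=np.uint8)
    bone = in_body & (density == DENSITY_CODES["bone"])
    labels[bone] = TISSUE_CODES["bone"]

    fat = density == DENSITY_CODES["adipose"]
    if eat_density_gated:
        eat = intra & fat & eat_mask
    else:
        eat = intra & eat_mask
    vat = intra & fat & ~eat
    labels[eat] = TISSUE_CODES["eat"]
    labels[vat] = TISSUE_CODES["vat"]

    sm = extra & (density == DENSITY_CODES["muscle"])
    labels[sm] = TISSUE_CODES["sm"]

    extrathoracic_fat = extra & fat
    if body_mask is None:
        body_mask = in_body
    elif body_mask.shape != volume.shape:
        raise ValueError("body mask is misaligned with the CT volume")
    sat, imat = split_sat_imat(extrathoracic_fat, body_mask)
    labels[sat] = TISSUE_CODES["sat"]
    labels[imat] = TISSUE_CODES["imat"]

    return TissueLabelMap(labels=labels, slab=compartments.slab, spacing=compartments.spacing)
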