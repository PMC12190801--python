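"""Body compartmentalisation: body mask, intrathoracic hull, T5-T11 slab.

The body is split into an intrathoracic compartment (the slice-wise
convex hull over the intrathoracic organs, excluding bone-density
voxels) and an extrathoracic remainder (which keeps the bones), then
everything is cropped to the cranio-caudal range spanned by vertebrae
T5 through T11.  Scans that do not cover that full range are rejected,
mirroring the study-level exclusion rule.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull, QhullError

from .io import CTVolume, OrganMaskSet

__all__ = [
    "CompartmentMap",
    "EmptyFieldOfViewError",
    "VertebralCoverageError",
    "COMPARTMENT_CODES",
    "extract_body_mask",
    "intrathoracic_hull",
    "vertebral_slab",
    "build_compartments",
    "convex_hull_slice",
]

#: integer codes used when a compartment map is written as a labelmap
COMPARTMENT_CODES = {"outside": 0, "intrathoracic": 1, "extrathoracic": 2}

#: default HU threshold separating body tissue from surrounding air,
#: midway between lung parenchyma and soft tissue
BODY_AIR_THRESHOLD_HU = -500.0

#: organ masks whose union seeds the intrathoracic hull
DEFAULT_HULL_ORGANS = ("lungs", "heart", "eat")


class EmptyFieldOfViewError(ValueError):
    """No voxel above the air threshold: nothing to segment."""


class VertebralCoverageError(ValueError):
    """Scan does not capture the entire range between T5 and T11."""


@dataclass
class CompartmentMap:
    """Per-voxel compartment labels plus the slab they are valid on."""

    labels: np.ndarray  # uint8, codes per COMPARTMENT_CODES
    slab: tuple[int, int]
    spacing: tuple[float, float, float]

    @property
    def intrathoracic(self) -> np.ndarray:
        return self.labels == COMPARTMENT_CODES["intrathoracic"]

    @property
    def extrathoracic(self) -> np.ndarray:
        return self.labels == COMPARTMENT_CODES["extrathoracic"]

    @property
    def in_body(self) -> np.ndarray:
        return self.labels != COMPARTMENT_CODES["outside"]


def extract_body_mask(volume: CTVolume, air_threshold: float = BODY_AIR_THRESHOLD_HU) -> np.ndarray:
    """Largest 26-connected component above ``air_threshold``, holes filled slice-wise.

    Internal air spaces (lung parenchyma, bowel gas) are re-included by
    2-D hole filling on every axial slice, so the mask is the solid body
    outline.
    """
    above = volume.voxels >= air_threshold
    if not above.any():
        raise EmptyFieldOfViewError(
            f"empty field of view: no voxel reaches {air_threshold} HU"
        )
    labelled, n = ndi.label(above, structure=np.ones((3, 3, 3), dtype=bool))
    if n > 1:
        counts = np.bincount(labelled.ravel())
        counts[0] = 0
        body = labelled == int(np.argmax(counts))
    else:
        body = above
    fill_structure = np.ones((3, 3), dtype=bool)  # 8-neighbourhood fills
    out = np.empty_like(body)
    for z in range(body.shape[2]):
        out[:, :, z] = ndi.binary_fill_holes(body[:, :, z], structure=fill_structure)
    return out


def convex_hull_slice(mask2d: np.ndarray) -> np.ndarray:
    """Filled 2-D convex hull of a binary slice.

    A pixel belongs to the hull iff its centre is a convex combination
    of the true pixel centres (facet inequalities with a 1e-9 slack;
    degenerate point/segment inputs use exact integer arithmetic).
    """
    pts = np.argwhere(mask2d)
    out = np.zeros_like(mask2d, dtype=bool)
    if len(pts) == 0:
        return out
    x0, y0 = pts.min(axis=0)
    x1, y1 = pts.max(axis=0)
    try:
        hull = ConvexHull(pts.astype(float))
    except QhullError:
        # collinear or single point: exact segment membership
        uniq = np.unique(pts, axis=0)
        if len(uniq) == 1:
            out[tuple(uniq[0])] = True
            return out
        d = uniq - uniq[0]
        axis = d[-1]
        sub = np.zeros((x1 - x0 + 1, y1 - y0 + 1), dtype=bool)
        gx, gy = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1), indexing="ij")
        qd0, qd1 = gx - uniq[0, 0], gy - uniq[0, 1]
        on_line = qd0 * axis[1] - qd1 * axis[0] == 0
        t = qd0 * axis[0] + qd1 * axis[1]
        tt = d @ axis
        sub = on_line & (t >= tt.min()) & (t <= tt.max())
        out[x0 : x1 + 1, y0 : y1 + 1] = sub
        return out
    gx, gy = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1), indexing="ij")
    q = np.stack([gx.ravel(), gy.ravel(), np.ones(gx.size)], axis=1)
    inside = np.all(q @ hull.equations.T <= 1e-9, axis=1)
    out[x0 : x1 + 1, y0 : y1 + 1] = inside.reshape(gx.shape)
    return out


def intrathoracic_hull(masks: OrganMaskSet, organs=DEFAULT_HULL_ORGANS, slab: tuple[int, int] | None = None) -> np.ndarray:
    """Slice-wise convex hull of the union of intrathoracic organ masks.

    The hull is computed independently on every axial slice (robust to
    cranio-caudal truncation); slices with an empty organ union get an
    empty hull.  Raises if the union is empty on every considered slice.
    """
    union = masks.union(organs)
    nz = union.shape[2]
    z_range = range(nz) if slab is None else range(slab[0], slab[1] + 1)
    hull = np.zeros_like(union)
    any_organ = False
    for z in z_range:
        if union[:, :, z].any():
            any_organ = True
            hull[:, :, z] = convex_hull_slice(union[:, :, z])
    if not any_organ:
        raise ValueError("intrathoracic organ union is empty on every considered slice")
    return hull


def vertebral_slab(masks: OrganMaskSet) -> tuple[int, int]:
    """Inclusive z-range spanned by vertebrae T5 through T11.

    All seven masks must be present and non-empty; otherwise the scan
    does not capture the entire T5-T11 range and is excluded, as in the
    study population rules.
    """
    z_min, z_max = None, None
    for level in range(5, 12):
        name = f"vertebra_T{level}"
        m = masks.get(name)
        if m is None or not m.any():
            raise VertebralCoverageError(
                f"scan did not capture the entire range between T5 and T11 vertebrae "
                f"({name} missing or empty); excluded from quantification"
            )
        zs = np.nonzero(m.any(axis=(0, 1)))[0]
        z_min = int(zs.min()) if z_min is None else min(z_min, int(zs.min()))
        z_max = int(zs.max()) if z_max is None else max(z_max, int(zs.max()))
    return z_min, z_max


def build_compartments(
    body: np.ndarray,
    hull: np.ndarray,
    bone_density: np.ndarray,
    slab: tuple[int, int],
    spacing: tuple[float, float, float],
) -> CompartmentMap:
    """Assemble the compartment labelmap within the T5-T11 slab.

    Within the slab: intrathoracic = body ∩ hull minus bone-density
    voxels; extrathoracic = the rest of the body (bone-density voxels
    are always extrathoracic).  Outside the slab every voxel is
    'outside'.
    """
    z0, z1 = slab
    nz = body.shape[2]
    if z0 < 0 or z1 >= nz or z0 > z1:
        raise ValueError(f"slab {slab} lies outside the grid (nz={nz})")
    labels = np.zeros(body.shape, dtype=np.uint8)
    sl = np.s_[:, :, z0 : z1 + 1]
    intra = body[sl] & hull[sl] & ~bone_density[sl]
    extra = body[sl] & ~intra
    region = labels[sl]
    region[intra] = COMPARTMENT_CODES["intrathoracic"]
    region[extra] = COMPARTMENT_CODES["extrathoracic"]
    labels[sl] = region
    return CompartmentMap(labels=labels, slab=(z0, z1), spacing=tuple(spacing))
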