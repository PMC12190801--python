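"""Synthetic thoracic CT phantoms with exactly known composition.

The phantom emulates the anatomy the segmentation pipeline assumes: an
elliptical body cross-section with a subcutaneous fat rim and a muscle
wall, a convex thoracic cavity containing lungs, heart, an epicardial
fat shell and visceral fat pockets, intermuscular fat pockets buried in
the muscle wall, and a 12-level vertebral column with ribs.  Every
painted voxel is recorded, so the full image-processing chain can be
validated against exact per-tissue voxel counts, volumes and mean
densities without any external data.

Geometry is slice-wise elliptical and the cavity is convex by
construction, so the per-slice convex hull of the intrathoracic organs
is provably contained in the cavity.  The mediastinal background is
painted at an attenuation outside every tissue-classification interval,
which makes zero-noise recovery of all six tissues exact.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
from pathlib import Path

import numpy as np
from scipy.spatial import Delaunay
from scipy.spatial import QhullError

from .io import CTVolume, OrganMaskSet, VERTEBRA_NAMES

__all__ = [
    "PhantomSpec",
    "GroundTruthComposition",
    "PhantomSpecError",
    "TRUTH_CODES",
    "TISSUES",
    "generate_phantom",
    "degrade_phantom",
    "boundary_spec_low",
    "boundary_spec_high",
    "points_in_hull_delaunay",
]

#: the six quantified tissues, in reporting order
TISSUES = ("sm", "bone", "sat", "imat", "vat", "eat")

#: integer codes in the ground-truth label grid.  Codes 1..6 coincide
#: with the tissue labelmap codes used by the classifier.
TRUTH_CODES = {
    "air": 0,
    "sm": 1,
    "bone": 2,
    "sat": 3,
    "imat": 4,
    "vat": 5,
    "eat": 6,
    "lung": 7,
    "heart": 8,
    "mediastinum": 9,
}


class PhantomSpecError(ValueError):
    """Raised when a phantom specification is anatomically impossible."""


Box = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]


def _default_vat_pockets() -> tuple[Box, ...]:
    # anterior mediastinum, between the lungs, inside the organ hull
    return (((74, 85), (59, 61), (55, 64)), ((88, 94), (59, 61), (45, 54)))


def _default_imat_pockets() -> tuple[Box, ...]:
    # buried in the lateral muscle wall, nowhere touching the skin rim
    return (((137, 139), (77, 82), (35, 50)), ((20, 22), (77, 82), (60, 75)))


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric and attenuation parameters of the synthetic thorax.

    Lengths are voxels (the grid is index-space; physical size comes
    from ``spacing``).  ``z`` ascends toward the head, so vertebra T1
    sits at high z and T12 at low z.  Per-tissue attenuation means must
    lie inside the HU interval of the class the tissue is meant to
    carry (fat in [-190, -30], muscle in [-29, 150], bone in
    [151, 1200]); the non-tissue backgrounds (air, lung parenchyma,
    mediastinum) must fall outside every interval.
    """

    shape: tuple[int, int, int] = (160, 160, 120)
    spacing: tuple[float, float, float] = (2.5, 2.5, 3.0)
    center: tuple[float, float] = (79.5, 79.5)
    body_radii: tuple[float, float] = (70.0, 50.0)
    sat_thickness: float = 6.0
    muscle_thickness: float = 10.0

    lung_offset_x: float = 30.0
    lung_center_y: float = -5.0          # offset from body centre
    lung_center_z: float = 60.0
    lung_radii: tuple[float, float, float] = (13.0, 20.0, 40.0)

    heart_center: tuple[float, float, float] = (0.0, 0.0, 45.0)  # offsets (x, y) + absolute z
    heart_radii: tuple[float, float, float] = (12.0, 11.0, 16.0)
    eat_radii: tuple[float, float, float] = (15.0, 14.0, 19.0)

    vat_pockets: tuple[Box, ...] = field(default_factory=_default_vat_pockets)
    imat_pockets: tuple[Box, ...] = field(default_factory=_default_imat_pockets)

    # vertebral column: 12 stacked blocks T1..T12, superior first
    vertebra_xy: tuple[tuple[int, int], tuple[int, int]] = ((75, 84), (116, 121))
    vertebra_height: int = 8
    vertebra_gap: int = 1
    vertebra_top_z: int = 118

    rib_y: tuple[int, int] = (88, 91)
    rib_x_right: tuple[int, int] = (136, 139)
    rib_x_left: tuple[int, int] = (20, 23)
    rib_z_start: int = 26
    rib_z_step: int = 9
    rib_z_thickness: int = 2
    n_rib_levels: int = 7

    # attenuation means (HU) and additive Gaussian noise SD
    sat_hu: float = -100.0
    imat_hu: float = -100.0
    vat_hu: float = -100.0
    eat_hu: float = -100.0
    sm_hu: float = 40.0
    bone_hu: float = 400.0
    heart_hu: float = 40.0
    lung_hu: float = -800.0
    mediastinum_hu: float = -250.0
    air_hu: float = -1000.0
    noise_sd: float = 0.0
    seed: int = 0

    def hu_for_code(self) -> dict[int, float]:
        c = TRUTH_CODES
        return {
            c["air"]: self.air_hu,
            c["sm"]: self.sm_hu,
            c["bone"]: self.bone_hu,
            c["sat"]: self.sat_hu,
            c["imat"]: self.imat_hu,
            c["vat"]: self.vat_hu,
            c["eat"]: self.eat_hu,
            c["lung"]: self.lung_hu,
            c["heart"]: self.heart_hu,
            c["mediastinum"]: self.mediastinum_hu,
        }

    def vertebra_z_extent(self, level: int) -> tuple[int, int]:
        """Inclusive z-range of vertebra T<level> (1..12)."""
        hi = self.vertebra_top_z - (self.vertebra_height + self.vertebra_gap) * (level - 1)
        return hi - self.vertebra_height + 1, hi


@dataclass
class GroundTruthComposition:
    """Exact per-tissue composition of a phantom within the T5-T11 slab."""

    voxel_counts: dict[str, int]
    volumes_cm3: dict[str, float]
    mean_hu: dict[str, float]
    body_voxels: int
    lung_voxels: int
    heart_voxels: int
    mediastinum_voxels: int
    cavity_voxels: int
    intrathoracic_voxels: int
    extrathoracic_voxels: int
    slab: tuple[int, int]
    spacing: tuple[float, float, float]
    label_map: np.ndarray | None = None          # full-grid truth codes
    intrathoracic_mask: np.ndarray | None = None  # full-grid, Delaunay-hull oracle

    @property
    def unassigned_voxels(self) -> int:
        return self.lung_voxels + self.heart_voxels + self.mediastinum_voxels

    def to_dict(self) -> dict:
        return {
            "voxel_counts": self.voxel_counts,
            "volumes_cm3": self.volumes_cm3,
            "mean_hu": self.mean_hu,
            "body_voxels": self.body_voxels,
            "lung_voxels": self.lung_voxels,
            "heart_voxels": self.heart_voxels,
            "mediastinum_voxels": self.mediastinum_voxels,
            "cavity_voxels": self.cavity_voxels,
            "intrathoracic_voxels": self.intrathoracic_voxels,
            "extrathoracic_voxels": self.extrathoracic_voxels,
            "slab": list(self.slab),
            "spacing": list(self.spacing),
        }

    def to_json(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path


def points_in_hull_delaunay(points: np.ndarray, query: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Membership oracle: which query points are convex combinations of ``points``.

    Uses a Delaunay triangulation with a simplex walk — a computational
    route independent of facet-equation rasterisation, which makes it a
    suitable cross-check for the pipeline's hull.  Degenerate (point or
    collinear) inputs are resolved with exact integer arithmetic.
    """
    points = np.asarray(points)
    query = np.asarray(query)
    if len(points) == 0:
        return np.zeros(len(query), dtype=bool)
    uniq = np.unique(points, axis=0)
    if len(uniq) == 1:
        return np.all(query == uniq[0], axis=1)
    d = uniq - uniq[0]
    axis = d[-1]  # nonzero: unique points in lexicographic order
    cross = d[:, 0] * axis[1] - d[:, 1] * axis[0]
    if np.all(cross == 0):  # collinear: segment membership, exact
        t = d @ axis
        qd = query - uniq[0]
        on_line = qd[:, 0] * axis[1] - qd[:, 1] * axis[0] == 0
        tq = qd @ axis
        return on_line & (tq >= t.min()) & (tq <= t.max())
    try:
        tri = Delaunay(uniq)
    except QhullError:  # pragma: no cover - guarded by collinearity test
        return np.zeros(len(query), dtype=bool)
    return tri.find_simplex(query.astype(float), tol=tol) >= 0


def _ellipse2d(shape_xy, center, radii):
    nx, ny = shape_xy
    x = np.arange(nx)[:, None] - center[0]
    y = np.arange(ny)[None, :] - center[1]
    return (x / radii[0]) ** 2 + (y / radii[1]) ** 2 <= 1.0


def _ellipsoid(shape, center, radii):
    nx, ny, nz = shape
    x = (np.arange(nx)[:, None, None] - center[0]) / radii[0]
    y = (np.arange(ny)[None, :, None] - center[1]) / radii[1]
    z = (np.arange(nz)[None, None, :] - center[2]) / radii[2]
    return x**2 + y**2 + z**2 <= 1.0


def _box_mask(shape, box: Box):
    (x0, x1), (y0, y1), (z0, z1) = box
    m = np.zeros(shape, dtype=bool)
    m[x0 : x1 + 1, y0 : y1 + 1, z0 : z1 + 1] = True
    return m


def _validate_hu(spec: PhantomSpec) -> None:
    from .tissues import HuRanges

    r = HuRanges()
    fat = {"sat": spec.sat_hu, "imat": spec.imat_hu, "vat": spec.vat_hu, "eat": spec.eat_hu}
    for name, v in fat.items():
        if not (r.adipose[0] <= v <= r.adipose[1]):
            raise PhantomSpecError(f"{name} mean HU {v} outside adipose interval {r.adipose}")
    for name, v in (("sm", spec.sm_hu), ("heart", spec.heart_hu)):
        if not (r.muscle[0] <= v <= r.muscle[1]):
            raise PhantomSpecError(f"{name} mean HU {v} outside muscle interval {r.muscle}")
    if not (r.bone[0] <= spec.bone_hu <= r.bone[1]):
        raise PhantomSpecError(f"bone mean HU {spec.bone_hu} outside bone interval {r.bone}")
    for name, v in (
        ("lung", spec.lung_hu),
        ("mediastinum", spec.mediastinum_hu),
        ("air", spec.air_hu),
    ):
        if any(lo <= v <= hi for lo, hi in (r.adipose, r.muscle, r.bone)):
            raise PhantomSpecError(f"{name} HU {v} falls inside a tissue classification interval")
    if spec.noise_sd < 0:
        raise PhantomSpecError("noise SD must be >= 0")


def _paint(truth: np.ndarray, region: np.ndarray, code: int, expect: int, what: str) -> None:
    if not region.any():
        raise PhantomSpecError(f"{what} region is empty")
    current = truth[region]
    if not np.all(current == expect):
        bad = {int(c) for c in np.unique(current) if c != expect}
        raise PhantomSpecError(
            f"{what} overlaps previously painted structures (codes {sorted(bad)}); "
            "the phantom spec is anatomically inconsistent"
        )
    truth[region] = code


def generate_phantom(spec: PhantomSpec = PhantomSpec()):
    """Build a phantom: (CTVolume, OrganMaskSet, GroundTruthComposition).

    Painting is strictly validating — any overlap between structures, or
    a structure escaping its anatomical container, aborts before image
    synthesis.  With ``noise_sd == 0`` every tissue voxel carries exactly
    its configured mean HU, and repeated calls with one seed are
    bit-identical.
    """
    _validate_hu(spec)
    c = TRUTH_CODES
    nx, ny, nz = spec.shape
    a, b = spec.body_radii
    a1, b1 = a - spec.sat_thickness, b - spec.sat_thickness
    a2, b2 = a1 - spec.muscle_thickness, b1 - spec.muscle_thickness
    if min(a1, b1) <= 0 or min(a2, b2) <= 0:
        raise PhantomSpecError(
            "SAT rim / muscle wall thicker than the body radii; no thoracic cavity remains"
        )
    cx, cy = spec.center
    if cx - a < 0.5 or cx + a > nx - 1.5 or cy - b < 0.5 or cy + b > ny - 1.5:
        raise PhantomSpecError("body ellipse does not fit inside the grid with an air margin")

    body2d = _ellipse2d((nx, ny), (cx, cy), (a, b))
    inner1 = _ellipse2d((nx, ny), (cx, cy), (a1, b1))
    cavity2d = _ellipse2d((nx, ny), (cx, cy), (a2, b2))

    truth = np.zeros(spec.shape, dtype=np.uint8)
    truth[body2d & ~inner1] = c["sat"]        # 2-D masks broadcast along z
    truth[inner1 & ~cavity2d] = c["sm"]
    truth[cavity2d] = c["mediastinum"]

    # intrathoracic organs
    lung_l = _ellipsoid(
        spec.shape, (cx - spec.lung_offset_x, cy + spec.lung_center_y, spec.lung_center_z), spec.lung_radii
    )
    lung_r = _ellipsoid(
        spec.shape, (cx + spec.lung_offset_x, cy + spec.lung_center_y, spec.lung_center_z), spec.lung_radii
    )
    lungs = lung_l | lung_r
    heart = _ellipsoid(
        spec.shape,
        (cx + spec.heart_center[0], cy + spec.heart_center[1], spec.heart_center[2]),
        spec.heart_radii,
    )
    eat = (
        _ellipsoid(
            spec.shape,
            (cx + spec.heart_center[0], cy + spec.heart_center[1], spec.heart_center[2]),
            spec.eat_radii,
        )
        & ~heart
    )
    _paint(truth, lungs, c["lung"], c["mediastinum"], "lungs")
    _paint(truth, eat, c["eat"], c["mediastinum"], "epicardial fat shell")
    _paint(truth, heart, c["heart"], c["mediastinum"], "heart")
    for i, box in enumerate(spec.vat_pockets):
        _paint(truth, _box_mask(spec.shape, box), c["vat"], c["mediastinum"], f"VAT pocket {i}")
    for i, box in enumerate(spec.imat_pockets):
        _paint(truth, _box_mask(spec.shape, box), c["imat"], c["sm"], f"IMAT pocket {i}")

    # bones: vertebral column T1..T12 + rib blocks
    (vx0, vx1), (vy0, vy1) = spec.vertebra_xy
    vert_masks = {}
    for level in range(1, 13):
        z0, z1 = spec.vertebra_z_extent(level)
        if z0 < 0 or z1 >= nz or z0 > z1:
            raise PhantomSpecError(f"vertebra T{level} z-extent ({z0}, {z1}) leaves the grid")
        box = ((vx0, vx1), (vy0, vy1), (z0, z1))
        m = _box_mask(spec.shape, box)
        _paint(truth, m, c["bone"], c["sm"], f"vertebra T{level}")
        vert_masks[f"vertebra_T{level}"] = m
    for j in range(spec.n_rib_levels):
        z0 = spec.rib_z_start + j * spec.rib_z_step
        z1 = z0 + spec.rib_z_thickness - 1
        if z1 >= nz:
            raise PhantomSpecError("rib blocks leave the grid in z")
        for side, (rx0, rx1) in (("right", spec.rib_x_right), ("left", spec.rib_x_left)):
            m = _box_mask(spec.shape, ((rx0, rx1), spec.rib_y, (z0, z1)))
            _paint(truth, m, c["bone"], c["sm"], f"{side} rib level {j}")

    # attenuation synthesis
    hu = np.empty(spec.shape, dtype=np.float64)
    for code, value in spec.hu_for_code().items():
        hu[truth == code] = value
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        hu = hu + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    volume = CTVolume(voxels=hu, spacing=spec.spacing)

    body3d = np.broadcast_to(body2d[:, :, None], spec.shape).copy()
    masks = {"lungs": lungs, "heart": heart, "eat": eat, "body": body3d, **vert_masks}
    mask_set = OrganMaskSet(masks=masks, provenance={n: "phantom" for n in masks})

    truth_gt = _ground_truth(spec, truth, lungs | heart | eat, body3d, cavity2d)
    return volume, mask_set, truth_gt


def _ground_truth(spec, truth, organs, body3d, cavity2d) -> GroundTruthComposition:
    c = TRUTH_CODES
    z_lo = min(spec.vertebra_z_extent(level)[0] for level in range(5, 12))
    z_hi = max(spec.vertebra_z_extent(level)[1] for level in range(5, 12))
    sl = np.s_[:, :, z_lo : z_hi + 1]
    tr = truth[sl]

    voxvol_cm3 = float(np.prod(spec.spacing)) / 1000.0
    hu_means = {
        "sm": spec.sm_hu,
        "bone": spec.bone_hu,
        "sat": spec.sat_hu,
        "imat": spec.imat_hu,
        "vat": spec.vat_hu,
        "eat": spec.eat_hu,
    }
    counts = {t: int(np.count_nonzero(tr == c[t])) for t in TISSUES}
    volumes = {t: counts[t] * voxvol_cm3 for t in TISSUES}

    # independent intrathoracic oracle: slice-wise Delaunay hull of organ voxels
    intra = np.zeros(spec.shape, dtype=bool)
    nx, ny = spec.shape[:2]
    grid = np.stack(np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij"), axis=-1).reshape(-1, 2)
    for z in range(z_lo, z_hi + 1):
        pts = np.argwhere(organs[:, :, z])
        if len(pts) == 0:
            continue
        member = points_in_hull_delaunay(pts, grid).reshape(nx, ny)
        member &= truth[:, :, z] != c["bone"]
        member &= body3d[:, :, z]
        intra[:, :, z] = member
    bad = truth[intra]
    if not np.all(np.isin(bad, [c["lung"], c["heart"], c["eat"], c["vat"], c["mediastinum"]])):
        raise PhantomSpecError("organ hull escapes the thoracic cavity; adjust the geometry")
    for i, box in enumerate(spec.vat_pockets):
        pocket = _box_mask(spec.shape, box)[sl]
        if not np.all(intra[sl][pocket]):
            raise PhantomSpecError(
                f"VAT pocket {i} is not fully inside the intrathoracic organ hull"
            )

    body_slab = int(np.count_nonzero(body3d[sl]))
    cavity_slab = int(np.count_nonzero(cavity2d)) * (z_hi - z_lo + 1)
    intra_slab = int(np.count_nonzero(intra[sl]))
    return GroundTruthComposition(
        voxel_counts=counts,
        volumes_cm3=volumes,
        mean_hu=hu_means,
        body_voxels=body_slab,
        lung_voxels=int(np.count_nonzero(tr == c["lung"])),
        heart_voxels=int(np.count_nonzero(tr == c["heart"])),
        mediastinum_voxels=int(np.count_nonzero(tr == c["mediastinum"])),
        cavity_voxels=cavity_slab,
        intrathoracic_voxels=intra_slab,
        extrathoracic_voxels=body_slab - intra_slab,
        slab=(z_lo, z_hi),
        spacing=spec.spacing,
        label_map=truth,
        intrathoracic_mask=intra,
    )


def degrade_phantom(volume: CTVolume, noise_sd: float, seed: int = 0) -> CTVolume:
    """Add voxelwise zero-mean Gaussian HU noise; ``noise_sd == 0`` is identity."""
    if noise_sd < 0:
        raise ValueError("noise SD must be >= 0")
    if noise_sd == 0:
        return volume
    rng = np.random.default_rng(seed)
    noisy = volume.voxels + rng.normal(0.0, noise_sd, size=volume.shape)
    return CTVolume(voxels=noisy, spacing=volume.spacing, origin=volume.origin)


def boundary_spec_low(**overrides) -> PhantomSpec:
    """Phantom with fat means at -30 HU and muscle means at -29 HU.

    Pins the closed-interval reading of the adipose/muscle boundary:
    -30 must classify as adipose, -29 as muscle.
    """
    kw = dict(sat_hu=-30.0, imat_hu=-30.0, vat_hu=-30.0, eat_hu=-30.0, sm_hu=-29.0, heart_hu=-29.0)
    kw.update(overrides)
    return PhantomSpec(**kw)


def boundary_spec_high(**overrides) -> PhantomSpec:
    """Phantom with muscle means at +150 HU and bone at +151 HU.

    Pins the muscle/bone boundary: +150 is muscle, +151 is bone.
    """
    kw = dict(sm_hu=150.0, heart_hu=150.0, bone_hu=151.0)
    kw.update(overrides)
    return PhantomSpec(**kw)


def spec_to_dict(spec: PhantomSpec) -> dict:
    return asdict(spec)


def spec_from_dict(d: dict) -> PhantomSpec:
    def _tupleize(v):
        if isinstance(v, list):
            return tuple(_tupleize(x) for x in v)
        return v

    return PhantomSpec(**{k: _tupleize(v) for k, v in d.items()})
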