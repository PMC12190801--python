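"""Standardised composition metrics: volumes, indexed volumes, densities.

Each tissue is summarised by its volume (cm^3), its volume indexed to
body surface area (cm^3/m^2, DuBois formula), its volume as a
percentage of the total thoracic volume (the sensitivity-analysis
indexing variant), and its mean attenuation (HU) over the entire tissue
volume.  Undefined quantities (empty tissue, missing height/weight) are
explicit ``None``, never silent zeros.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .compartments import CompartmentMap
from .io import CTVolume
from .tissues import TISSUE_CODES, TissueLabelMap

__all__ = ["Subject", "TissueMetrics", "CompositionMetrics", "compute_bsa", "summarize_composition"]

TISSUE_ORDER = ("sm", "bone", "sat", "imat", "vat", "eat")


def compute_bsa(height_cm: float, weight_kg: float) -> float:
    """Body surface area (m^2) by the DuBois & DuBois formula.

    BSA = 0.007184 * weight^0.425 * height^0.725, weight in kg and
    height in cm.
    """
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError(f"height and weight must be positive, got {height_cm=} {weight_kg=}")
    return 0.007184 * weight_kg**0.425 * height_cm**0.725


@dataclass(frozen=True)
class Subject:
    """Minimal per-subject record needed for indexing and thresholding."""

    id: str
    sex: str  # 'female' | 'male'
    height_cm: float | None = None
    weight_kg: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")

    @property
    def bsa_m2(self) -> float | None:
        if self.height_cm is None or self.weight_kg is None:
            return None
        return compute_bsa(self.height_cm, self.weight_kg)


@dataclass(frozen=True)
class TissueMetrics:
    volume_cm3: float
    indexed_volume_cm3_m2: float | None
    thoracic_fraction_pct: float | None
    mean_density_hu: float | None


@dataclass
class CompositionMetrics:
    """All standardised metrics for one scan."""

    tissues: dict[str, TissueMetrics]
    total_thoracic_volume_cm3: float
    lung_volume_cm3: float | None
    bsa_m2: float | None
    slab: tuple[int, int]
    extra: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        """Flatten into one table row with stable column names."""
        row: dict = {}
        for t in TISSUE_ORDER:
            m = self.tissues[t]
            row[f"{t}_vol_cm3"] = m.volume_cm3
            row[f"{t}_vol_idx"] = m.indexed_volume_cm3_m2
            row[f"{t}_thoracic_pct"] = m.thoracic_fraction_pct
            row[f"{t}_density_hu"] = m.mean_density_hu
        row["total_thoracic_cm3"] = self.total_thoracic_volume_cm3
        row["lung_vol_cm3"] = self.lung_volume_cm3
        row["bsa_m2"] = self.bsa_m2
        row.update(self.extra)
        return row


def summarize_composition(
    labels: TissueLabelMap,
    volume: CTVolume,
    compartments: CompartmentMap,
    lungs_mask: np.ndarray | None = None,
    bsa_m2: float | None = None,
) -> CompositionMetrics:
    """Turn a tissue labelmap into standardised composition metrics.

    Volume is voxel count times voxel volume; mean density is the
    arithmetic mean HU over all voxels carrying the tissue label.  The
    total thoracic volume is operationalised as the slab volume of the
    intrathoracic compartment together with the lungs (their union;
    hole-filled body extraction already places the lungs inside the
    intrathoracic compartment, so no volume is counted twice).
    """
    if labels.labels.shape != volume.shape or compartments.labels.shape != volume.shape:
        raise ValueError("labelmap, volume and compartments must share one grid")
    voxvol_cm3 = volume.voxel_volume_mm3 / 1000.0
    z0, z1 = compartments.slab
    sl = np.s_[:, :, z0 : z1 + 1]

    thoracic = compartments.intrathoracic
    if lungs_mask is not None:
        thoracic = thoracic.copy()
        thoracic[sl] |= lungs_mask[sl]
        lung_volume = float(np.count_nonzero(lungs_mask[sl])) * voxvol_cm3
    else:
        lung_volume = None
    total_thoracic = float(np.count_nonzero(thoracic[sl])) * voxvol_cm3

    tissues: dict[str, TissueMetrics] = {}
    for t in TISSUE_ORDER:
        mask = labels.labels == TISSUE_CODES[t]
        n = int(np.count_nonzero(mask))
        vol = n * voxvol_cm3
        density = float(np.mean(volume.voxels[mask])) if n else None
        indexed = vol / bsa_m2 if bsa_m2 else None
        fraction = 100.0 * vol / total_thoracic if total_thoracic > 0 else None
        tissues[t] = TissueMetrics(
            volume_cm3=vol,
            indexed_volume_cm3_m2=indexed,
            thoracic_fraction_pct=fraction,
            mean_density_hu=density,
        )
    return CompositionMetrics(
        tissues=tissues,
        total_thoracic_volume_cm3=total_thoracic,
        lung_volume_cm3=lung_volume,
        bsa_m2=bsa_m2,
        slab=(z0, z1),
    )
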