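"""End-to-end orchestration: volumes -> compartments -> tissues -> metrics -> models.

A single :class:`RunConfig` (loadable from YAML) carries every knob the
method leaves open (hull organ set, EAT density gating, body/air
threshold, HU intervals, indexing mode, competing-risk flavour), so the
sensitivity of results to any of these choices is scriptable.  Runs are
deterministic under a fixed seed and write a manifest with per-stage
wall times, voxel counts and output checksums.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import cohort as cohort_mod
from . import risk
from .compartments import (
    BODY_AIR_THRESHOLD_HU,
    DEFAULT_HULL_ORGANS,
    build_compartments,
    extract_body_mask,
    intrathoracic_hull,
    vertebral_slab,
)
from .io import CTVolume, OrganMaskSet, load_mask_sidecar, read_mask_set, read_volume, write_mask, write_volume
from .phantom import PhantomSpec, generate_phantom, spec_from_dict as phantom_spec_from_dict
from .quantify import compute_bsa, summarize_composition
from .tissues import HuRanges, assign_tissues

log = logging.getLogger("thoraxcomp")

__all__ = ["RunConfig", "SegmentationResult", "run_segmentation", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage contract violation, reported with the stage name."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    mode: str = "phantom"  # 'phantom' | 'files'
    out_dir: str = "thoraxcomp_run"
    seed: int = 0
    phantom: dict = field(default_factory=dict)  # PhantomSpec overrides
    volume_path: str | None = None
    mask_sidecar: str | None = None
    subject: dict = field(default_factory=lambda: {"id": "subject", "sex": "male"})
    hu_ranges: dict = field(default_factory=dict)
    hull_organs: tuple[str, ...] = DEFAULT_HULL_ORGANS
    eat_density_gated: bool = True
    body_air_threshold: float = BODY_AIR_THRESHOLD_HU
    indexing: str = "bsa"  # 'bsa' | 'thoracic-fraction' (both are always emitted)
    cohort: dict | None = None  # CohortSpec overrides; enables the cohort/fit stages
    model: dict | None = None  # ModelSpec fields for the fit stage
    competing_risk: str = "fine-gray"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        if "hull_organs" in data:
            data["hull_organs"] = tuple(data["hull_organs"])
        return cls(**data)


@dataclass
class SegmentationResult:
    body: np.ndarray
    hull: np.ndarray
    slab: tuple[int, int]
    compartments: object
    labels: object


def run_segmentation(
    volume: CTVolume,
    masks: OrganMaskSet,
    ranges: HuRanges = HuRanges(),
    hull_organs=DEFAULT_HULL_ORGANS,
    eat_density_gated: bool = True,
    body_air_threshold: float = BODY_AIR_THRESHOLD_HU,
) -> SegmentationResult:
    """Run body extraction, hull, slab, compartments and tissue attribution."""
    from .tissues import DENSITY_CODES, classify_hu

    body = extract_body_mask(volume, air_threshold=body_air_threshold)
    slab = vertebral_slab(masks)
    hull = intrathoracic_hull(masks, organs=hull_organs, slab=slab)
    bone_density = classify_hu(volume.voxels, ranges) == DENSITY_CODES["bone"]
    comp = build_compartments(body, hull, bone_density, slab, volume.spacing)
    labels = assign_tissues(
        volume,
        comp,
        eat_mask=masks.get("eat"),
        ranges=ranges,
        eat_density_gated=eat_density_gated,
        body_mask=body,
    )
    return SegmentationResult(body=body, hull=hull, slab=slab, compartments=comp, labels=labels)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(manifest: dict, name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            manifest["stages"].append({"name": name, "seconds": round(dt, 3)})
            if exc is not None:
                log.error("stage %s failed after %.2fs: %s", name, dt, exc)
                return False
            log.info("stage %s: done in %.2fs", name, dt)
            return False

    return _Timer()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the run manifest.

    Any stage failure is re-raised as :class:`PipelineError` carrying
    the stage name and the underlying contract violation.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_mode": config.mode, "seed": config.seed, "stages": [], "outputs": {}}
    ranges = HuRanges(**config.hu_ranges) if config.hu_ranges else HuRanges()

    current = "setup"
    try:
        truth = None
        if config.mode == "phantom":
            current = "phantom"
            with _stage(manifest, "phantom"):
                spec = phantom_spec_from_dict({"seed": config.seed, **config.phantom})
                volume, masks, truth = generate_phantom(spec)
                write_volume(volume, out / "phantom_ct.nii.gz")
                for name, m in masks.masks.items():
                    write_mask(m, volume.spacing, out / f"mask_{name}.nii.gz")
                truth.to_json(out / "ground_truth.json")
        elif config.mode == "files":
            current = "load"
            with _stage(manifest, "load"):
                if not config.volume_path or not config.mask_sidecar:
                    raise PipelineError("files mode requires volume_path and mask_sidecar")
                volume = read_volume(config.volume_path)
                masks = read_mask_set(load_mask_sidecar(config.mask_sidecar), volume)
        else:
            raise PipelineError(f"unknown mode {config.mode!r}")

        current = "segment"
        with _stage(manifest, "segment"):
            seg = run_segmentation(
                volume,
                masks,
                ranges=ranges,
                hull_organs=config.hull_organs,
                eat_density_gated=config.eat_density_gated,
                body_air_threshold=config.body_air_threshold,
            )
            write_mask(seg.compartments.labels, volume.spacing, out / "compartments.nii.gz")
            write_mask(seg.labels.labels, volume.spacing, out / "tissue_labels.nii.gz")
            manifest["slab"] = list(seg.slab)
            manifest["voxel_counts"] = {
                "body_slab": int(
                    np.count_nonzero(seg.body[:, :, seg.slab[0] : seg.slab[1] + 1])
                ),
                "intrathoracic": int(np.count_nonzero(seg.compartments.intrathoracic)),
                "extrathoracic": int(np.count_nonzero(seg.compartments.extrathoracic)),
            }
            for t in ("sm", "bone", "sat", "imat", "vat", "eat"):
                manifest["voxel_counts"][t] = seg.labels.count(t)

        current = "quantify"
        with _stage(manifest, "quantify"):
            subj = config.subject or {}
            bsa = None
            if subj.get("height_cm") and subj.get("weight_kg"):
                bsa = compute_bsa(subj["height_cm"], subj["weight_kg"])
            metrics = summarize_composition(
                seg.labels, volume, seg.compartments, lungs_mask=masks.get("lungs"), bsa_m2=bsa
            )
            row = {"subject_id": subj.get("id", "subject"), "sex": subj.get("sex"), **metrics.to_row()}
            (out / "composition.json").write_text(json.dumps(row, indent=2, default=float))
            manifest["composition"] = {
                k: (None if v is None else float(v)) for k, v in metrics.to_row().items()
            }
            if truth is not None:
                manifest["ground_truth_volumes_cm3"] = truth.volumes_cm3

        if config.cohort is not None:
            current = "cohort"
            with _stage(manifest, "cohort"):
                cspec = cohort_mod.spec_from_dict({"seed": config.seed, **config.cohort})
                sim = cohort_mod.simulate_cohort(cspec)
                table, n_imputed = cohort_mod.impute_missing_bmi(sim.table)
                sim.table = table
                sim.to_csv(out / "cohort.csv")
                sim.truth_to_json(out / "cohort_truth.json")
                manifest["cohort"] = {"n": len(table), "bmi_imputed": n_imputed}

            if config.model is not None:
                current = "fit"
                with _stage(manifest, "fit"):
                    m = dict(config.model)
                    m["covariates"] = tuple(m.get("covariates", ()))
                    if "log_transform" in m:
                        m["log_transform"] = tuple(m["log_transform"])
                    mspec = risk.ModelSpec(**m)
                    res = risk.fit_cox(sim.table, mspec)
                    res.summary.to_csv(out / "cox_summary.csv")
                    fit_info = {
                        "log_likelihood": res.log_likelihood,
                        "ll_null": res.ll_null,
                        "n": res.n,
                        "n_events": res.n_events,
                    }
                    if (sim.table["event"] == 1).any():
                        cr = risk.competing_risk_mi(sim.table, mspec, method=config.competing_risk)
                        cr.summary.to_csv(out / "competing_risk_summary.csv")
                        fit_info["competing_risk_method"] = config.competing_risk
                    manifest["fit"] = fit_info
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {current!r} failed: {exc}") from exc

    for p in sorted(out.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return manifest
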