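"""End-to-end driver: phantom → segment → register → quantify → dose.

Runs the study workflow on a synthetic animal, writing each stage's
artifact plus a single machine-readable JSON run report.  Stages execute
in order; any failure aborts with an error naming the stage.  With
``resume=True`` a stage whose outputs already exist for the same
configuration hash is skipped.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import datasets, io
from .dosimetry import (
    DoseModelParams,
    TldCorrectionParams,
    pet_fraction_of_total,
    region_dose_summary,
    total_dose,
)
from .errors import PipelineError, PulmoquantError
from .phantom import PhantomSpec, generate_phantom, truth_report
from .registration import DEFAULT_RMS_GATE_MM, fit_rigid, refine_by_worst_landmark, resample
from .segmentation import GrowParams, SeedPointSet, region_grow
from .uptake import (
    LIVER_ROI_VOLUME_MM3,
    LUNG_ROI_VOLUME_MM3,
    TUMOUR_ROI_VOLUME_MM3,
    RoiDefinition,
    quadrant_rois,
    roi_stats,
    tumour_to_nontumour_ratio,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

#: Average micro-CT dose of the companion protocol (mGy); an external input
#: used only for the PET share of the combined examination.
DEFAULT_CT_DOSE_MGY = 202.0


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one synthetic end-to-end run."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    n_seeds: int = 30
    grow: GrowParams = field(default_factory=GrowParams)
    rms_gate_mm: float = DEFAULT_RMS_GATE_MM
    lung_roi_volume_mm3: float = LUNG_ROI_VOLUME_MM3
    liver_roi_volume_mm3: float = LIVER_ROI_VOLUME_MM3
    tumour_roi_volume_mm3: float = TUMOUR_ROI_VOLUME_MM3
    dose: DoseModelParams = field(default_factory=DoseModelParams)
    ct_dose_mgy: float = DEFAULT_CT_DOSE_MGY
    seed: int = 0
    resume: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("resume", None)  # execution flag, not part of the configuration
        return d

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        phantom = PhantomSpec(**{
            **raw.pop("phantom", {}),
            **({"seed": raw["seed"]} if "seed" in raw else {}),
        })
        grow = GrowParams(**raw.pop("grow", {}))
        dose = DoseModelParams(**raw.pop("dose", {}))
        return cls(phantom=phantom, grow=grow, dose=dose, **raw)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PulmoquantError as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute all five stages and write ``report.json`` under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = config.to_dict()
    provenance = io.make_provenance(config.seed, cfg_dict)
    report_path = out / "report.json"
    if config.resume and report_path.exists():
        try:
            old = json.loads(report_path.read_text())
            if old.get("provenance", {}).get("config_hash") == provenance["config_hash"]:
                logger.info("resume: report for identical config found; skipping run")
                return old
        except (json.JSONDecodeError, KeyError):
            pass

    phantom_spec = dataclasses.replace(config.phantom, seed=config.seed)
    report: dict = {"provenance": provenance}

    # --- stage 1: phantom --------------------------------------------------
    truth = _stage("phantom")(generate_phantom)(phantom_spec)
    io.write_volume(truth.ct, out / "ct.mha")
    io.write_volume(truth.pet, out / "pet.mha")
    io.write_mask(truth.masks["aerated_lung"], out / "aerated_lung_truth.mha")
    io.write_landmarks_csv(truth.landmarks_ct, out / "landmarks_ct.csv")
    io.write_landmarks_csv(truth.landmarks_pet, out / "landmarks_pet.csv")
    truth_report(truth).to_csv(out / "truth_report.csv", index=False)
    report["phantom"] = {
        "tumour_model": phantom_spec.tumour_model,
        "aerated_volume_mm3": truth.aerated_volume_mm3,
        "tumour_to_liver_ratio": truth.tumour_to_liver_ratio,
        "true_transform": truth.transform.to_dict(),
    }
    logger.info("phantom: aerated volume %.1f mm3", truth.aerated_volume_mm3)

    # --- stage 2: segmentation --------------------------------------------
    rng = np.random.default_rng(config.seed + 1)
    aerated_idx = np.argwhere(truth.masks["aerated_lung"].data)
    pick = rng.choice(len(aerated_idx), size=min(config.n_seeds, len(aerated_idx)), replace=False)
    seeds = SeedPointSet(aerated_idx[pick].astype(float))
    mask = _stage("segmentation")(region_grow)(truth.ct, seeds, config.grow)
    io.write_mask(mask, out / "aerated_lung_segmented.mha")
    report["segmentation"] = {
        "n_seeds": len(seeds),
        "tolerance": config.grow.tolerance,
        "connectivity": config.grow.connectivity,
        "aerated_volume_mm3": mask.volume_mm3,
        "truth_volume_mm3": truth.aerated_volume_mm3,
    }
    logger.info("segmentation: %.1f mm3 (truth %.1f)", mask.volume_mm3, truth.aerated_volume_mm3)

    # --- stage 3: registration --------------------------------------------
    def register():
        rep = fit_rigid(truth.landmarks_pet, truth.landmarks_ct)
        while rep.rms_mm > config.rms_gate_mm and len(rep.used) > 3:
            rep = refine_by_worst_landmark(rep, exclude=True)
        return rep

    reg = _stage("registration")(register)()
    pet_on_ct = _stage("registration")(resample)(truth.pet, reg.transform, truth.ct)
    io.write_volume(pet_on_ct, out / "pet_on_ct.mha")
    (out / "transform.json").write_text(json.dumps(reg.transform.to_dict(), indent=2))
    report["registration"] = {
        "rms_mm": reg.rms_mm,
        "fre_mm": reg.fre_mm,
        "used": list(reg.used),
        "excluded": list(reg.excluded),
        "transform": reg.transform.to_dict(),
    }
    logger.info("registration: RMS %.4f mm over %d landmarks", reg.rms_mm, len(reg.used))

    # --- stage 4: uptake ---------------------------------------------------
    def quantify():
        rois = quadrant_rois(mask, config.lung_roi_volume_mm3)
        liver_roi = RoiDefinition(
            "liver",
            centre_mm=tuple(truth.masks["liver"].centroid_world()),
            target_volume_mm3=config.liver_roi_volume_mm3,
        )
        lv_roi = RoiDefinition(
            "left-ventricle",
            centre_mm=tuple(truth.masks["myocardium"].centroid_world()),
            target_volume_mm3=config.lung_roi_volume_mm3,
        )
        liver_stats = roi_stats(pet_on_ct, liver_roi)
        block = {
            "liver": dataclasses.asdict(liver_stats),
            "left_ventricle": dataclasses.asdict(roi_stats(pet_on_ct, lv_roi)),
            "quadrant_ratios": {},
        }
        for name, roi in rois.items():
            s = roi_stats(pet_on_ct, roi)
            block["quadrant_ratios"][name] = tumour_to_nontumour_ratio(s, liver_stats)
        if phantom_spec.tumour_model == "circumscribed":
            t_roi = RoiDefinition(
                "tumour",
                centre_mm=tuple(truth.masks["tumour"].centroid_world()),
                target_volume_mm3=config.tumour_roi_volume_mm3,
            )
            block["tumour_ratio"] = tumour_to_nontumour_ratio(
                roi_stats(pet_on_ct, t_roi), liver_stats
            )
        return block

    report["uptake"] = _stage("uptake")(quantify)()

    # --- stage 5: dose -----------------------------------------------------
    def dose():
        result = total_dose(config.dose)
        corr = TldCorrectionParams()
        regions = region_dose_summary(datasets.load_tld_records(), corr)
        return {
            "decays": result.decays,
            "positron_dose_mgy": result.positron_dose_mgy,
            "gamma_dose_mgy": result.gamma_dose_mgy,
            "total_dose_mgy": result.total_dose_mgy,
            "tld_region_doses_mgy": regions,
            "pet_fraction_percent": pet_fraction_of_total(
                result.total_dose_mgy, config.ct_dose_mgy
            ),
        }

    report["dose"] = _stage("dose")(dose)()

    report_path.write_text(json.dumps(report, indent=2))
    logger.info("report written to %s", report_path)
    return report
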