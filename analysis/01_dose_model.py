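#!/usr/bin/env python
"""Estimate the absorbed dose of one 10 MBq FDG micro-PET examination.

Evaluates the positron and annihilation-photon dose components for a
30 g mouse under complete decay, plus the sensitivity to the absorbed-
fraction rounding (exact 30 g midpoint 4.95% vs the published 4.9%).
Writes results/dose_estimates.csv.

Finding: the positron component dominates (119 mGy); photons add
~25 mGy for a total of ~144 mGy, about 41% of a combined PET+CT
examination when the companion CT protocol delivers 202 mGy.
"""

from pathlib import Path

import pandas as pd

from pulmoquant.dosimetry import (
    DoseModelParams,
    absorbed_fraction,
    pet_fraction_of_total,
    total_dose,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rows = []
    for label, override in [("interpolated_4.95%", None), ("published_4.9%", 0.049)]:
        params = DoseModelParams(absorbed_fraction_override=override)
        r = total_dose(params)
        rows.append(
            {
                "absorbed_fraction": label,
                "a_gamma": params.gamma_absorbed_fraction,
                "decays": r.decays,
                "positron_mGy": r.positron_dose_mgy,
                "gamma_mGy": r.gamma_dose_mgy,
                "total_mGy": r.total_dose_mgy,
                "pet_share_of_combined_percent": pet_fraction_of_total(
                    r.total_dose_mgy, 202.0
                ),
            }
        )
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "dose_estimates.csv", index=False)
    print(f"absorbed fraction at 30 g (interpolated): {absorbed_fraction(0.030):.4f}")
    print(df.to_string(index=False, float_format=lambda v: f"{v:.3g}"))


if __name__ == "__main__":
    main()
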