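#!/usr/bin/env python
"""Group statistics over the per-animal uptake and histology table.

Recomputes the cohort summaries from the packaged animal table: mean
lung uptake ratio per genotype, mean circumscribed-lesion ratio, the
Spearman correlation of histology score vs lung ratio in the
disseminated-tumour (SPC-raf) group, and Student/Welch tests comparing
lesion ratios against lung ratios in the circumscribed-tumour (SPC-myc)
group. Writes results/uptake_statistics.csv.

Finding: circumscribed lesions show a 2.48 mean tumour-to-non-tumour
ratio; diffuse-tumour animals average 1.47 vs 0.89 in the wildtype; the
histology-uptake Spearman correlation in the SPC-raf group is weak and
non-significant (rho ~ -0.09, exact p ~ 0.89).
"""

from pathlib import Path

import pandas as pd

from pulmoquant.datasets import load_animal_table, load_lesion_table
from pulmoquant.uptake import spearman_correlation, two_sample_tests

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    animals = load_animal_table()
    lesions = load_lesion_table()

    group_means = (
        animals.groupby("genotype").lung_ratio_mean.agg(["mean", "std", "count"])
    )
    lesion_mean = lesions.tumour_ratio.mean()

    raf = animals[animals.genotype == "SPC-raf"]
    rho, p_exact = spearman_correlation(
        raf.histology_mean.to_numpy(), raf.lung_ratio_mean.to_numpy()
    )

    myc = animals[animals.genotype == "SPC-myc"]
    p_student, p_welch = two_sample_tests(
        lesions.tumour_ratio.to_numpy(), myc.lung_ratio_mean.to_numpy()
    )

    rows = [
        {"statistic": "mean_lesion_ratio", "value": lesion_mean},
        {"statistic": "spearman_rho_raf", "value": rho},
        {"statistic": "spearman_p_exact_raf", "value": p_exact},
        {"statistic": "student_p_myc_lesion_vs_lung", "value": p_student},
        {"statistic": "welch_p_myc_lesion_vs_lung", "value": p_welch},
    ] + [
        {"statistic": f"mean_lung_ratio_{g}", "value": v}
        for g, v in group_means["mean"].items()
    ]
    OUT.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT / "uptake_statistics.csv", index=False)

    print(group_means)
    print(f"mean circumscribed-lesion ratio: {lesion_mean:.3f}")
    print(f"SPC-raf histology vs uptake: rho={rho:.3f}, exact p={p_exact:.3f}")
    print(
        "SPC-myc lesion vs lung ratios: "
        f"Student p={p_student:.3f}, Welch p={p_welch:.3f}"
    )


if __name__ == "__main__":
    main()
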