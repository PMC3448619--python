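"""Packaged study tables.

Two small CSV fixtures ship with the package: the per-animal imaging and
histology summary of the 14 examined mice (genotype, mean 4-point
histological tumour load, mean Lung ROI_max/Liver ROI_MV, and one row per
circumscribed lesion with its Tumour ROI_max/Liver ROI_MV), and the TLD
dose measurements at nine skin positions 75 minutes after administering
10 MBq of ¹⁸F-FDG.  Animal 5 carried two circumscribed tumours, hence two
lesion rows.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .dosimetry import TldRecord

__all__ = [
    "load_animal_table",
    "load_lesion_table",
    "load_tld_table",
    "load_tld_records",
]


def _read_csv(name: str) -> pd.DataFrame:
    with resources.files("pulmoquant.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_animal_table() -> pd.DataFrame:
    """Per-animal summary: genotype, histology mean, mean lung uptake ratio."""
    return _read_csv("animals.csv")


def load_lesion_table() -> pd.DataFrame:
    """One row per circumscribed lesion with its tumour-to-liver ratio."""
    return _read_csv("lesions.csv")


def load_tld_table() -> pd.DataFrame:
    """TLD positions 1-9 with mean measured dose and SD (mGy)."""
    return _read_csv("tld.csv")


def load_tld_records() -> list[TldRecord]:
    """The TLD table as dosimetry records."""
    df = load_tld_table()
    return [
        TldRecord(
            position=int(r.position),
            description=str(r.description),
            mean_dose_mgy=float(r.mean_mGy),
            sd_mgy=float(r.sd_mGy),
        )
        for r in df.itertuples()
    ]
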