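"""ROI statistics on registered PET, uptake ratios and group statistics.

Tracer uptake is quantified with spherical regions of interest placed on
the fused PET/CT grid: four lung quadrants, the liver, the left ventricle
and (where present) circumscribed tumours.  The tumour-to-non-tumour
ratio divides the maximum count rate of the lung/tumour ROI by the mean
count rate of the liver ROI (ROI_max / liver ROI_MV) — a reference-organ
normalization that cancels global scaling of the PET values.

Default ROI target volumes are 3.5 mm³ (lung quadrants), 11.9 mm³
(liver) and 11.6 mm³ (lung lesions).  Voxels belong to an ROI when their
centre falls inside the sphere; no partial-volume weighting or correction
is applied.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import RoiError, StatisticsError
from .volume import SegmentationMask, Volume3D

__all__ = [
    "LUNG_ROI_VOLUME_MM3",
    "LIVER_ROI_VOLUME_MM3",
    "TUMOUR_ROI_VOLUME_MM3",
    "QUADRANT_NAMES",
    "RoiDefinition",
    "RoiStats",
    "AnimalRecord",
    "roi_stats",
    "tumour_to_nontumour_ratio",
    "quadrant_rois",
    "summarize_animal",
    "spearman_correlation",
    "two_sample_tests",
]

LUNG_ROI_VOLUME_MM3 = 3.5
LIVER_ROI_VOLUME_MM3 = 11.9
TUMOUR_ROI_VOLUME_MM3 = 11.6

QUADRANT_NAMES = ("right-upper", "right-lower", "left-upper", "left-lower")


def sphere_radius_for_volume(volume_mm3: float) -> float:
    return (3.0 * volume_mm3 / (4.0 * math.pi)) ** (1.0 / 3.0)


@dataclass(frozen=True)
class RoiDefinition:
    """A labelled ROI: a sphere (centre + target volume) or an explicit mask.

    Spheres live in the CT-grid world frame (mm).
    """

    label: str
    centre_mm: tuple[float, float, float] | None = None
    target_volume_mm3: float | None = None
    mask: SegmentationMask | None = None

    def __post_init__(self) -> None:
        if self.mask is None:
            if self.centre_mm is None or self.target_volume_mm3 is None:
                raise RoiError(
                    f"ROI {self.label!r}: needs a centre and target volume, or a mask"
                )
            if self.target_volume_mm3 <= 0:
                raise RoiError(f"ROI {self.label!r}: target volume must be > 0")

    @property
    def radius_mm(self) -> float:
        if self.target_volume_mm3 is None:
            raise RoiError(f"ROI {self.label!r} is mask-based; no sphere radius")
        return sphere_radius_for_volume(self.target_volume_mm3)


@dataclass(frozen=True)
class RoiStats:
    """Voxel statistics inside one ROI."""

    label: str
    volume_mm3: float
    voxel_count: int
    mean: float
    sd: float
    minimum: float
    maximum: float
    target_volume_mm3: float | None = None

    def __post_init__(self) -> None:
        if not (self.minimum <= self.mean <= self.maximum):
            raise RoiError(f"ROI {self.label!r}: min <= mean <= max violated")


def _sphere_voxel_mask(volume: Volume3D, centre_mm: np.ndarray, radius_mm: float) -> np.ndarray:
    centre_idx = volume.world_to_index(centre_mm)
    spacing = np.asarray(volume.spacing_mm)
    lo = np.maximum(np.floor(centre_idx - radius_mm / spacing).astype(int) - 1, 0)
    hi = np.minimum(
        np.ceil(centre_idx + radius_mm / spacing).astype(int) + 2, np.asarray(volume.shape)
    )
    mask = np.zeros(volume.shape, dtype=bool)
    if np.any(lo >= hi):
        return mask
    ii, jj, kk = np.meshgrid(
        np.arange(lo[0], hi[0]), np.arange(lo[1], hi[1]), np.arange(lo[2], hi[2]),
        indexing="ij",
    )
    d2 = (
        ((ii - centre_idx[0]) * spacing[0]) ** 2
        + ((jj - centre_idx[1]) * spacing[1]) ** 2
        + ((kk - centre_idx[2]) * spacing[2]) ** 2
    )
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = d2 <= radius_mm**2
    return mask


def roi_stats(pet_on_ct_grid: Volume3D, roi: RoiDefinition) -> RoiStats:
    """Min/max/mean/SD of the PET values whose voxel centres fall in the ROI.

    The realized volume is the voxel count times the voxel volume and may
    differ from the sphere's target volume by discretization; both are
    reported.
    """
    if roi.mask is not None:
        if not pet_on_ct_grid.same_grid(roi.mask):
            raise RoiError(f"ROI {roi.label!r}: mask grid does not match the PET grid")
        sel = roi.mask.data
    else:
        sel = _sphere_voxel_mask(
            pet_on_ct_grid, np.asarray(roi.centre_mm, dtype=float), roi.radius_mm
        )
    values = np.asarray(pet_on_ct_grid.data)[sel]
    if values.size == 0:
        raise RoiError(f"ROI {roi.label!r} contains no voxels")
    return RoiStats(
        label=roi.label,
        volume_mm3=float(values.size) * pet_on_ct_grid.voxel_volume_mm3,
        voxel_count=int(values.size),
        mean=float(values.mean()),
        sd=float(values.std()),
        minimum=float(values.min()),
        maximum=float(values.max()),
        target_volume_mm3=roi.target_volume_mm3,
    )


def tumour_to_nontumour_ratio(numerator: RoiStats, liver: RoiStats) -> float:
    """ROI_max of the lung/tumour region over the liver mean count rate."""
    if liver.mean <= 0:
        raise RoiError(
            f"liver ROI {liver.label!r} mean count rate is {liver.mean}; "
            "cannot form a ratio (corrupt input?)"
        )
    return numerator.maximum / liver.mean


def quadrant_rois(
    lung_mask: SegmentationMask, target_volume_mm3: float = LUNG_ROI_VOLUME_MM3
) -> dict[str, RoiDefinition]:
    """Four spherical lung-quadrant ROIs from a segmented lung mask.

    The mask is split left/right at its midsagittal (x) centroid plane and
    upper/lower at its axial (z) centroid plane; each quadrant gets a
    sphere of the target volume centred at the quadrant's centroid, shrunk
    as needed to stay inside the quadrant's bounding box.  The subject's
    right is the low-x half.
    """
    if not lung_mask.data.any():
        raise RoiError("lung mask is empty")
    idx = np.argwhere(lung_mask.data)
    centroid = idx.mean(axis=0)
    if not ((idx[:, 0] < centroid[0]).any() and (idx[:, 0] >= centroid[0]).any()):
        raise RoiError("lung mask has no voxels on both sides of the midsagittal plane")

    spacing = np.asarray(lung_mask.spacing_mm)
    origin = np.asarray(lung_mask.origin_mm)
    halves = {
        "right": idx[:, 0] < centroid[0],
        "left": idx[:, 0] >= centroid[0],
        "upper": idx[:, 2] >= centroid[2],
        "lower": idx[:, 2] < centroid[2],
    }
    rois: dict[str, RoiDefinition] = {}
    empty: list[str] = []
    for name in QUADRANT_NAMES:
        side, level = name.split("-")
        sel = halves[side] & halves[level]
        if not sel.any():
            empty.append(name)
            continue
        q = idx[sel]
        q_centroid = q.mean(axis=0)
        centre = origin + q_centroid * spacing
        radius = sphere_radius_for_volume(target_volume_mm3)
        # stay inside the quadrant's bounding box (plus half a voxel)
        lo_mm = origin + (q.min(axis=0) - 0.5) * spacing
        hi_mm = origin + (q.max(axis=0) + 0.5) * spacing
        fit = float(min((centre - lo_mm).min(), (hi_mm - centre).min()))
        radius = max(min(radius, fit), float(spacing.min()) / 2.0)
        rois[name] = RoiDefinition(
            label=name,
            centre_mm=tuple(centre),
            target_volume_mm3=4.0 / 3.0 * math.pi * radius**3,
        )
    if empty:
        raise RoiError(f"lung quadrants contain no voxels: {empty}")
    return rois


@dataclass(frozen=True)
class AnimalRecord:
    """Per-animal summary mirroring one row of the study's animal table."""

    animal_id: str
    genotype: str
    quadrant_ratios: Mapping[str, float]
    histology_scores: Mapping[str, float]
    lung_ratio_mean: float
    histology_mean: float
    tumour_ratios: tuple[float, ...] = ()

    @property
    def tumour_ratio_mean(self) -> float | None:
        if not self.tumour_ratios:
            return None
        return float(np.mean(self.tumour_ratios))


def summarize_animal(
    animal_id: str,
    genotype: str,
    quadrant_ratios: Mapping[str, float],
    histology_scores: Mapping[str, float],
    tumour_ratios: Sequence[float] = (),
) -> AnimalRecord:
    """Aggregate the four quadrant measurements into one animal record.

    Per-animal means are unweighted arithmetic means over the four lung
    quadrants.  Histology scores use the 4-point scale (1 = no tumour,
    4 = complete obstruction).
    """
    missing = [q for q in QUADRANT_NAMES if q not in quadrant_ratios]
    if missing:
        raise StatisticsError(f"missing quadrant ratios: {missing}")
    missing_h = [q for q in QUADRANT_NAMES if q not in histology_scores]
    if missing_h:
        raise StatisticsError(f"missing histology scores: {missing_h}")
    for q in QUADRANT_NAMES:
        if quadrant_ratios[q] <= 0:
            raise StatisticsError(f"quadrant {q!r} ratio must be > 0")
        if not 1.0 <= histology_scores[q] <= 4.0:
            raise StatisticsError(f"quadrant {q!r} histology score outside 1-4")
    if any(r <= 0 for r in tumour_ratios):
        raise StatisticsError("tumour ratios must be > 0")
    return AnimalRecord(
        animal_id=str(animal_id),
        genotype=genotype,
        quadrant_ratios=dict(quadrant_ratios),
        histology_scores=dict(histology_scores),
        lung_ratio_mean=float(np.mean([quadrant_ratios[q] for q in QUADRANT_NAMES])),
        histology_mean=float(np.mean([histology_scores[q] for q in QUADRANT_NAMES])),
        tumour_ratios=tuple(tumour_ratios),
    )


def _rank_rho(x_ranks: np.ndarray, y_ranks: np.ndarray) -> float:
    xc = x_ranks - x_ranks.mean()
    yc = y_ranks - y_ranks.mean()
    return float((xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc)))


def spearman_correlation(
    x: Sequence[float], y: Sequence[float], exact_n_max: int = 8
) -> tuple[float, float]:
    """Tie-corrected Spearman rank correlation with a two-sided p-value.

    Ties receive average ranks.  For n ≤ ``exact_n_max`` the p-value is
    exact, from the full permutation distribution of one rank vector;
    for larger n the usual t approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatisticsError("inputs must be equal-length 1D vectors")
    n = len(x)
    if n < 3:
        raise StatisticsError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatisticsError("rank correlation is undefined for a constant vector")

    xr = stats.rankdata(x)
    yr = stats.rankdata(y)
    rho = _rank_rho(xr, yr)

    if n <= exact_n_max:
        count = 0
        total = 0
        target = abs(rho) - 1e-12
        for perm in itertools.permutations(range(n)):
            total += 1
            if abs(_rank_rho(xr, yr[list(perm)])) >= target:
                count += 1
        p = count / total
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p


def two_sample_tests(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided p-values of the Student (pooled) and Welch t-tests."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StatisticsError("each group needs at least 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise StatisticsError("groups must contain finite values")
    p_student = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
    p_welch = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return p_student, p_welch
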