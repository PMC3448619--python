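"""Hounsfield calibration and seeded region growing of the aerated lung.

In animals with diffuse multifocal lung tumours the tumour itself cannot
be delineated on CT, so the air-containing (aerated) lung volume is
measured instead and used as an inverse surrogate of tumour burden: as
tumour replaces air-filled parenchyma, the aerated volume falls.  The
segmentation expands from manually placed seed points (typically 20-40)
through face-connected voxels whose intensity stays within a tolerance
band around each seed's intensity; the per-seed regions are unioned.

The tolerance band is 2% by default.  Two readings of "2%" are supported:
a fraction of the volume's full dynamic range (default, scale-free) or a
fraction of the seed voxel's own value; the choice is recorded in the
mask's provenance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from skimage.segmentation import flood

from .errors import CalibrationError, RoiError
from .volume import SegmentationMask, Volume3D

__all__ = [
    "SeedPointSet",
    "GrowParams",
    "calibrate_hounsfield",
    "region_grow",
    "mask_volume_mm3",
]


@dataclass(frozen=True)
class SeedPointSet:
    """Seed voxel coordinates for region growing.

    ``points`` are integer voxel indices unless ``world_mm`` is set, in
    which case they are mm coordinates converted against the target
    volume's grid at use time.  Typical studies use 20-40 seeds.
    """

    points: np.ndarray
    world_mm: bool = False

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 1:
            raise ValueError("seed points must be an (n>=1, 3) array")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    def voxel_indices(self, volume: Volume3D) -> np.ndarray:
        """Integer voxel indices in the given volume's grid; bounds-checked."""
        if self.world_mm:
            idx = np.rint(volume.world_to_index(self.points)).astype(int)
        else:
            idx = np.rint(self.points).astype(int)
        shape = np.asarray(volume.shape)
        if np.any(idx < 0) or np.any(idx >= shape):
            bad = idx[(idx < 0).any(axis=1) | (idx >= shape).any(axis=1)]
            raise RoiError(f"seed(s) outside the volume grid: {bad.tolist()}")
        return idx


@dataclass(frozen=True)
class GrowParams:
    """Region-growing parameters.

    tolerance
        Half-width of the acceptance band as a fraction (default 0.02).
    connectivity
        6 (faces only, default) or 26 (faces+edges+corners) neighbours.
    reference
        What the tolerance fraction multiplies: the calibrated volume's
        full dynamic range (``"dynamic_range"``) or the absolute seed
        voxel value (``"seed_value"``).
    """

    tolerance: float = 0.02
    connectivity: int = 6
    reference: Literal["dynamic_range", "seed_value"] = "dynamic_range"

    def __post_init__(self) -> None:
        if not 0 < self.tolerance <= 1:
            raise ValueError("tolerance must lie in (0, 1]")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")
        if self.reference not in ("dynamic_range", "seed_value"):
            raise ValueError(f"unknown tolerance reference {self.reference!r}")


def calibrate_hounsfield(
    raw: Volume3D, air_reference: float, water_reference: float
) -> Volume3D:
    """Affine map of raw CT numbers onto the Hounsfield scale.

    The unique affine map sending ``air_reference`` to −1000 HU and
    ``water_reference`` to 0 HU is applied voxelwise (and extended beyond
    both references).
    """
    if air_reference == water_reference:
        raise CalibrationError(
            "air and water references are equal; calibration is degenerate"
        )
    hu = 1000.0 * (np.asarray(raw.data, dtype=float) - water_reference) / (
        water_reference - air_reference
    )
    return raw.with_data(hu, modality="CT")


def region_grow(
    volume: Volume3D, seeds: SeedPointSet, params: GrowParams = GrowParams()
) -> SegmentationMask:
    """Union of per-seed tolerance flood fills.

    Each seed claims the connected set of voxels whose intensity lies
    within ± tolerance·reference of that seed's own intensity.  Regions
    from different seeds are unioned; seed order cannot change the result.
    """
    idx = seeds.voxel_indices(volume)
    data = np.asarray(volume.data, dtype=float)
    dynamic_range = float(data.max() - data.min())
    conn = 1 if params.connectivity == 6 else 3

    mask = np.zeros(volume.shape, dtype=bool)
    # Seeds with identical intensity grow identical bands; once one of them
    # has been flooded, any co-valued seed already inside the union of that
    # value's regions would reproduce a subset of it and can be skipped.
    covered_by_value: dict[float, np.ndarray] = {}
    for i, j, k in idx:
        seed_value = float(data[i, j, k])
        prior = covered_by_value.get(seed_value)
        if prior is not None and prior[i, j, k]:
            continue
        if params.reference == "dynamic_range":
            tol = params.tolerance * dynamic_range
        else:
            tol = params.tolerance * abs(seed_value)
        region = flood(data, (i, j, k), tolerance=tol, connectivity=conn)
        mask |= region
        if prior is None:
            covered_by_value[seed_value] = region.copy()
        else:
            prior |= region

    provenance = {
        "operation": "region_grow",
        "n_seeds": len(seeds),
        "seeds_voxel": idx.tolist(),
        "tolerance": params.tolerance,
        "tolerance_reference": params.reference,
        "connectivity": params.connectivity,
        "dynamic_range": dynamic_range,
    }
    return SegmentationMask(
        data=mask,
        spacing_mm=volume.spacing_mm,
        origin_mm=volume.origin_mm,
        provenance=provenance,
    )


def mask_volume_mm3(mask: SegmentationMask) -> float:
    """Mask volume in mm³: voxel count × voxel volume."""
    return mask.volume_mm3
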