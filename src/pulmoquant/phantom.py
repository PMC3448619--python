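"""Synthetic paired CT/PET mouse-thorax volumes with exact ground truth.

The phantom is built from analytic solids (ellipsoids, spheres, a bowed
cylinder for the spine) so that every downstream quantity — aerated-lung
volume, organ masks, the PET/CT frame offset, landmark positions and the
tumour-to-liver uptake contrast — is known in closed form:

* a soft-tissue torso (elliptic cylinder) in air,
* two aerated-lung ellipsoids flanking a spherical myocardium,
* a liver ellipsoid caudal to the lungs,
* a dorsal bone spine with a slight kyphotic bow,
* optionally tumour tissue inside the lungs: many small nodules
  ("diffuse", the multifocal phenotype) or one large sphere
  ("circumscribed", the focal phenotype).

The CT volume assigns Hounsfield numbers per tissue.  The PET volume is
the per-organ FDG uptake map convolved with a Gaussian point-spread
function, optionally corrupted by counting noise (independent Poisson
draws whose variance is proportional to the local expectation, emulating
reconstructed-image noise), and finally resampled into a frame offset
from the CT frame by a known rigid transform — the misregistration a real
scanner pair exhibits.  Five anatomical landmarks (left-ventricle tip,
right-ventricle lateral border, cranial and caudal liver pole, dorsal
maximum of the spinal convexity) are reported in both frames.  The liver
poles stand in for the spleen poles used clinically, as the phantom has
no spleen.

Everything derives from a single integer seed; the same spec and seed
reproduce bit-identical volumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import GridSizingError
from .registration import resample
from .volume import LandmarkSet, RigidTransform, SegmentationMask, Volume3D

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "truth_report",
    "LANDMARK_NAMES",
]

LANDMARK_NAMES = (
    "left_ventricle_tip",
    "right_ventricle_lateral",
    "liver_cranial_pole",
    "liver_caudal_pole",
    "spine_dorsal_max",
)

#: Default Hounsfield numbers per tissue (murine ranges).
DEFAULT_HU: Mapping[str, float] = {
    "air": -1000.0,
    "aerated_lung": -650.0,
    "soft_tissue": 50.0,
    "tumour": 40.0,
    "bone": 700.0,
}

#: Default uptake map in count-rate units relative to liver = 1.0 (myocardium
#: hot, aerated lung low, resting soft tissue lower still — the usual fasted
#: FDG pattern).  Tumour uptake comes from ``tumour_to_liver_ratio``.
DEFAULT_UPTAKE: Mapping[str, float] = {
    "lung_background": 0.4,
    "liver": 1.0,
    "myocardium": 2.0,
    "soft_tissue": 0.25,
}

# Fixed anatomy (mm, offsets from the grid centre).  A mouse thorax has a
# fixed physical size; the grid must be large enough to contain it.
_TORSO_SEMI_XY = (8.3, 7.3)
_TORSO_Z_MARGIN = 0.5
_LUNG_CENTRE = (3.4, 0.4, 3.0)  # +/- x for right/left
_LUNG_SEMI = (2.8, 3.4, 4.4)
_HEART_CENTRE = (-0.9, 1.3, 1.6)
_HEART_RADIUS = 1.8
_LIVER_CENTRE = (0.4, 0.4, -4.6)
_LIVER_SEMI = (5.4, 4.4, 3.1)
_SPINE_Y = -5.6
_SPINE_RADIUS = 0.9
_SPINE_BOW = 0.012  # mm^-1; ventral displacement ~ bow * (z - zc)^2


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one synthetic CT/PET pair.

    Defaults are the study conditions: a ~19×19×22 mm thorax at 0.2 mm
    isotropic voxels (the CT acquisition used 0.094 mm; the default is
    coarsened for tractable volumes), PET blur of 1.6 mm FWHM, counting
    noise scaled to 50 expected counts per voxel at liver uptake, and a
    few-degree / few-mm PET-to-CT frame offset as left by repositioning-
    free multimodality beds.
    """

    shape: tuple[int, int, int] = (96, 96, 110)
    spacing_mm: float = 0.2
    tumour_model: str = "none"  # none | diffuse | circumscribed
    nodule_count: int = 12
    nodule_radius_range_mm: tuple[float, float] = (0.4, 0.8)
    nodule_min_gap_mm: float = 0.8
    circumscribed_radius_mm: float = 2.0
    tumour_to_liver_ratio: float = 3.0
    uptake: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_UPTAKE))
    hu: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_HU))
    pet_blur_fwhm_mm: float = 1.6
    pet_noise_counts: float = 50.0  # expected counts/voxel at liver uptake; 0 = off
    misalignment_rotation_deg: tuple[float, float, float] = (2.0, -1.5, 4.0)
    misalignment_translation_mm: tuple[float, float, float] = (1.2, -0.8, 2.0)
    landmark_jitter_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tumour_model not in ("none", "diffuse", "circumscribed"):
            raise ValueError(f"unknown tumour model {self.tumour_model!r}")
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be > 0")
        lo, hi = self.nodule_radius_range_mm
        if lo <= 0 or hi < lo:
            raise ValueError("nodule radius range must satisfy 0 < lo <= hi")
        if self.circumscribed_radius_mm <= 0:
            raise ValueError("circumscribed tumour radius must be > 0")
        if self.tumour_to_liver_ratio < 0 or any(v < 0 for v in self.uptake.values()):
            raise ValueError("uptake values must be >= 0")
        if self.pet_noise_counts < 0:
            raise ValueError("noise scale must be >= 0")
        if self.landmark_jitter_mm < 0:
            raise ValueError("landmark jitter must be >= 0")

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * self.spacing_mm for n in self.shape)  # type: ignore[return-value]


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth accompanying a generated phantom."""

    ct: Volume3D
    pet: Volume3D  # in the (misaligned) PET frame
    masks: Mapping[str, SegmentationMask]  # CT frame
    aerated_volume_mm3: float
    tumour_to_liver_ratio: float
    transform: RigidTransform  # PET frame -> CT frame
    landmarks_ct: LandmarkSet
    landmarks_pet: LandmarkSet
    organ_uptake: Mapping[str, float]
    spec: PhantomSpec


def _grids(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    s = spec.spacing_mm
    nx, ny, nz = spec.shape
    centre = np.array([(nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0]) * s
    x = (np.arange(nx) * s - centre[0])[:, None, None]
    y = (np.arange(ny) * s - centre[1])[None, :, None]
    z = (np.arange(nz) * s - centre[2])[None, None, :]
    return x, y, z, centre


def _ellipsoid(x, y, z, centre, semi) -> np.ndarray:
    cx, cy, cz = centre
    ax, ay, az = semi
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def _sphere(x, y, z, centre, radius) -> np.ndarray:
    cx, cy, cz = centre
    return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= radius**2


def _check_sizing(spec: PhantomSpec) -> None:
    ex, ey, ez = spec.extent_mm
    need_x = 2 * (_TORSO_SEMI_XY[0] + _TORSO_Z_MARGIN)
    need_y = 2 * (_TORSO_SEMI_XY[1] + _TORSO_Z_MARGIN)
    need_z = 2 * (abs(_LUNG_CENTRE[2]) + _LUNG_SEMI[2] + 2 * _TORSO_Z_MARGIN)
    if ex < need_x or ey < need_y or ez < need_z:
        raise GridSizingError(
            f"grid extent {spec.extent_mm} mm too small for the thorax anatomy "
            f"(needs at least ({need_x:.1f}, {need_y:.1f}, {need_z:.1f}) mm)"
        )


def _sphere_fits_lung(centre_rel: np.ndarray, radius: float, lung_centre: np.ndarray) -> bool:
    """Conservative containment of a sphere inside a lung ellipsoid."""
    semi = np.asarray(_LUNG_SEMI)
    rho = float(np.linalg.norm((centre_rel - lung_centre) / semi))
    return rho + radius / semi.min() <= 1.0


def _place_nodules(spec: PhantomSpec, rng: np.random.Generator) -> list[tuple[np.ndarray, float]]:
    """Sequentially sample non-coalescing nodules inside the lung fields.

    Sampling is sequential from the seeded generator, so a spec asking for
    ``n`` nodules reproduces the first ``n`` of the same sequence a larger
    count would produce — tumour load grows monotonically with the count.
    """
    lo, hi = spec.nodule_radius_range_mm
    accepted: list[tuple[np.ndarray, float]] = []
    heart = np.asarray(_HEART_CENTRE)
    attempts = 0
    while len(accepted) < spec.nodule_count:
        attempts += 1
        if attempts > 20000:
            raise GridSizingError(
                f"could not place {spec.nodule_count} nodules of "
                f"{spec.nodule_radius_range_mm} mm with {spec.nodule_min_gap_mm} mm gaps"
            )
        side = 1.0 if rng.random() < 0.5 else -1.0
        lung_centre = np.asarray(_LUNG_CENTRE) * np.array([side, 1.0, 1.0])
        u = rng.uniform(-0.8, 0.8, size=3)
        centre = lung_centre + u * np.asarray(_LUNG_SEMI)
        radius = float(rng.uniform(lo, hi))
        if not _sphere_fits_lung(centre, radius + 0.05, lung_centre):
            continue
        if np.linalg.norm(centre - heart) < radius + _HEART_RADIUS + 0.2:
            continue
        if any(
            np.linalg.norm(centre - c) < radius + r + spec.nodule_min_gap_mm
            for c, r in accepted
        ):
            continue
        accepted.append((centre, radius))
    return accepted


def generate_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Build the CT/PET pair, organ masks, landmarks and frame offset."""
    _check_sizing(spec)
    rng = np.random.default_rng(spec.seed)
    x, y, z, centre = _grids(spec)
    s = spec.spacing_mm

    torso = (
        (x / _TORSO_SEMI_XY[0]) ** 2 + (y / _TORSO_SEMI_XY[1]) ** 2 <= 1.0
    ) & (np.abs(z) <= spec.extent_mm[2] / 2 - _TORSO_Z_MARGIN)

    right_lung = _ellipsoid(x, y, z, _LUNG_CENTRE, _LUNG_SEMI)
    lc = np.asarray(_LUNG_CENTRE) * np.array([-1.0, 1.0, 1.0])
    left_lung = _ellipsoid(x, y, z, lc, _LUNG_SEMI)
    lungs = right_lung | left_lung

    heart = _sphere(x, y, z, _HEART_CENTRE, _HEART_RADIUS)
    spine_y = _SPINE_Y + _SPINE_BOW * z**2
    spine = ((x - 0.0) ** 2 + (y - spine_y) ** 2 <= _SPINE_RADIUS**2) & torso
    liver = _ellipsoid(x, y, z, _LIVER_CENTRE, _LIVER_SEMI) & ~spine

    # Tumour tissue inside the lung fields.
    tumour = np.zeros(spec.shape, dtype=bool)
    if spec.tumour_model == "circumscribed":
        t_centre = np.asarray(_LUNG_CENTRE) + np.array([0.0, 0.0, -0.8])
        if not _sphere_fits_lung(t_centre, spec.circumscribed_radius_mm, np.asarray(_LUNG_CENTRE)):
            raise GridSizingError(
                f"circumscribed tumour radius {spec.circumscribed_radius_mm} mm "
                "exceeds the lung field"
            )
        tumour = _sphere(x, y, z, t_centre, spec.circumscribed_radius_mm)
    elif spec.tumour_model == "diffuse":
        for c, r in _place_nodules(spec, rng):
            tumour |= _sphere(x, y, z, c, r)
    tumour &= lungs & ~heart

    lung_field = lungs & ~heart & ~spine
    aerated = lung_field & ~tumour

    # --- CT ---------------------------------------------------------------
    hu = spec.hu
    ct = np.full(spec.shape, hu["air"], dtype=float)
    ct[torso] = hu["soft_tissue"]
    ct[lung_field] = hu["aerated_lung"]
    ct[tumour] = hu["tumour"]
    ct[heart & torso] = hu["soft_tissue"]
    ct[liver] = hu["soft_tissue"]
    ct[spine] = hu["bone"]
    ct_vol = Volume3D(ct, (s, s, s), modality="CT")

    # --- PET --------------------------------------------------------------
    up = spec.uptake
    tumour_uptake = spec.tumour_to_liver_ratio * up["liver"]
    uptake = np.zeros(spec.shape, dtype=float)
    uptake[torso] = up["soft_tissue"]
    uptake[lung_field] = up["lung_background"]
    uptake[tumour] = tumour_uptake
    uptake[heart & torso] = up["myocardium"]
    uptake[liver] = up["liver"]
    uptake[spine] = up["soft_tissue"]

    sigma_vox = spec.pet_blur_fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0))) / s
    pet_ct_frame = ndimage.gaussian_filter(uptake, sigma=sigma_vox)
    if spec.pet_noise_counts > 0:
        scale = spec.pet_noise_counts / up["liver"]
        counts = rng.poisson(np.clip(pet_ct_frame * scale, 0.0, None))
        pet_ct_frame = counts / scale

    transform = RigidTransform.from_euler_deg(
        spec.misalignment_rotation_deg,
        spec.misalignment_translation_mm,
        centre_mm=centre,
    )
    pet_ct_vol = Volume3D(pet_ct_frame, (s, s, s), modality="PET")
    pet_vol = resample(pet_ct_vol, transform.inverse(), pet_ct_vol)

    # --- Landmarks ---------------------------------------------------------
    hc = np.asarray(_HEART_CENTRE)
    livc = np.asarray(_LIVER_CENTRE)
    rel = {
        "left_ventricle_tip": hc + np.array([-0.9, 0.3, -1.55]),
        "right_ventricle_lateral": hc + np.array([_HEART_RADIUS, 0.0, 0.0]),
        "liver_cranial_pole": livc + np.array([0.0, 0.0, _LIVER_SEMI[2]]),
        "liver_caudal_pole": livc + np.array([0.0, 0.0, -_LIVER_SEMI[2]]),
        "spine_dorsal_max": np.array([0.0, _SPINE_Y - _SPINE_RADIUS, 0.0]),
    }
    lm_ct = LandmarkSet({n: rel[n] + centre for n in LANDMARK_NAMES}, frame="CT")
    inv = transform.inverse()
    pet_points = {n: inv.apply(lm_ct[n]) for n in LANDMARK_NAMES}
    if spec.landmark_jitter_mm > 0:
        for n in pet_points:
            pet_points[n] = pet_points[n] + rng.normal(
                0.0, spec.landmark_jitter_mm, size=3
            )
    lm_pet = LandmarkSet(pet_points, frame="PET")

    def _mask(arr: np.ndarray, name: str) -> SegmentationMask:
        return SegmentationMask(
            arr, (s, s, s), provenance={"phantom_organ": name, "seed": spec.seed}
        )

    masks = {
        "torso": _mask(torso, "torso"),
        "lung_field": _mask(lung_field, "lung_field"),
        "aerated_lung": _mask(aerated, "aerated_lung"),
        "tumour": _mask(tumour, "tumour"),
        "liver": _mask(liver, "liver"),
        "myocardium": _mask(heart & torso, "myocardium"),
    }
    organ_uptake = {
        "torso": up["soft_tissue"],
        "lung_field": up["lung_background"],
        "aerated_lung": up["lung_background"],
        "tumour": tumour_uptake if spec.tumour_model != "none" else 0.0,
        "liver": up["liver"],
        "myocardium": up["myocardium"],
    }
    return PhantomTruth(
        ct=ct_vol,
        pet=pet_vol,
        masks=masks,
        aerated_volume_mm3=masks["aerated_lung"].volume_mm3,
        tumour_to_liver_ratio=spec.tumour_to_liver_ratio,
        transform=transform,
        landmarks_ct=lm_ct,
        landmarks_pet=lm_pet,
        organ_uptake=organ_uptake,
        spec=spec,
    )


def truth_report(truth: PhantomTruth) -> pd.DataFrame:
    """One row per organ: mask volume (mm³) and programmed mean uptake."""
    rows = []
    for organ, mask in truth.masks.items():
        rows.append(
            {
                "organ": organ,
                "volume_mm3": mask.volume_mm3,
                "mean_uptake": truth.organ_uptake[organ],
            }
        )
    return pd.DataFrame(rows)


def tumour_component_count(truth: PhantomTruth) -> int:
    """Number of connected tumour components (26-connectivity flood fill)."""
    _, n = ndimage.label(truth.masks["tumour"].data, structure=np.ones((3, 3, 3)))
    return int(n)
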