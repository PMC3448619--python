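"""Landmark-based rigid PET-to-CT registration.

The transform between the two scanner frames is fitted from paired
anatomical landmarks by the closed-form least-squares orthogonal
(Kabsch) solution: both point clouds are centred, the cross-covariance is
decomposed by SVD, and the determinant of the candidate rotation is
corrected so that a reflection can never be returned.  Per-landmark
residuals after alignment are the fiducial registration errors (FRE);
their root mean square summarizes the fit.

When the fit is judged insufficient the landmark with the largest FRE can
be re-picked or dropped and the transform refitted, mirroring the manual
refinement loop used with fused-display software.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import DegenerateGeometryError, PairingError
from .volume import LandmarkSet, RigidTransform, Volume3D

__all__ = [
    "RegistrationReport",
    "fit_rigid",
    "refine_by_worst_landmark",
    "resample",
]

#: Default RMS gate (mm) above which refinement is advised: one in-plane PET voxel.
DEFAULT_RMS_GATE_MM = 0.39


@dataclass(frozen=True)
class RegistrationReport:
    """Fitted transform plus per-landmark fiducial registration errors."""

    transform: RigidTransform
    fre_mm: dict[str, float]
    rms_mm: float
    used: tuple[str, ...]
    excluded: tuple[str, ...]
    moving: LandmarkSet
    fixed: LandmarkSet
    history: tuple[str, ...] = field(default_factory=tuple)

    @property
    def worst_landmark(self) -> str:
        return max(self.used, key=lambda n: self.fre_mm[n])


def _check_pairing(moving: LandmarkSet, fixed: LandmarkSet, names: list[str]) -> None:
    if set(moving.names) != set(fixed.names):
        only_m = sorted(set(moving.names) - set(fixed.names))
        only_f = sorted(set(fixed.names) - set(moving.names))
        raise PairingError(
            f"landmark names differ between sets (moving only: {only_m}, fixed only: {only_f})"
        )
    if len(names) < 3:
        raise DegenerateGeometryError(f"need >= 3 landmark pairs, got {len(names)}")


def _check_not_collinear(points: np.ndarray) -> None:
    centred = points - points.mean(axis=0)
    s = np.linalg.svd(centred, compute_uv=False)
    scale = s[0] if s[0] > 0 else 1.0
    if s[1] / scale < 1e-9:
        raise DegenerateGeometryError("landmarks are collinear; rigid fit is degenerate")


def fit_rigid(moving: LandmarkSet, fixed: LandmarkSet) -> RegistrationReport:
    """Least-squares rigid transform taking ``moving`` landmarks onto ``fixed``.

    Pairing is by landmark name; both sets must contain the same names and
    at least 3 non-collinear points.  The returned transform minimizes the
    sum of squared distances between transformed moving points and fixed
    points over all proper rigid transforms.
    """
    names = moving.names
    _check_pairing(moving, fixed, names)
    m = moving.as_array(names)
    f = fixed.as_array(names)
    _check_not_collinear(m)

    mc, fc = m.mean(axis=0), f.mean(axis=0)
    H = (m - mc).T @ (f - fc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = fc - R @ mc
    transform = RigidTransform(R, t)

    residuals = transform.apply(m) - f
    fre = {n: float(np.linalg.norm(r)) for n, r in zip(names, residuals)}
    rms = float(np.sqrt(np.mean([e**2 for e in fre.values()])))
    return RegistrationReport(
        transform=transform,
        fre_mm=fre,
        rms_mm=rms,
        used=tuple(names),
        excluded=(),
        moving=moving,
        fixed=fixed,
    )


def refine_by_worst_landmark(
    report: RegistrationReport,
    replacement: LandmarkSet | None = None,
    exclude: bool = False,
) -> RegistrationReport:
    """Re-pick or drop the worst-fitting landmark and refit.

    With ``replacement`` given, the worst landmark's moving-frame
    coordinates are replaced by the re-picked ones from that set.  With
    ``exclude=True`` the landmark is dropped entirely, which requires at
    least 4 currently used landmarks so that 3 remain.
    """
    if not exclude and replacement is None:
        raise ValueError("either a replacement set or exclude=True is required")
    worst = report.worst_landmark
    moving = report.moving.subset(report.used)
    fixed = report.fixed.subset(report.used)
    if exclude:
        if len(report.used) < 4:
            raise DegenerateGeometryError(
                "cannot exclude a landmark: fewer than 3 would remain"
            )
        keep = [n for n in report.used if n != worst]
        new = fit_rigid(moving.subset(keep), fixed.subset(keep))
        action = f"excluded {worst!r}"
        excluded = report.excluded + (worst,)
    else:
        assert replacement is not None
        moving = moving.replace(worst, replacement[worst])
        new = fit_rigid(moving, fixed)
        action = f"replaced {worst!r}"
        excluded = report.excluded
    return RegistrationReport(
        transform=new.transform,
        fre_mm=new.fre_mm,
        rms_mm=new.rms_mm,
        used=new.used,
        excluded=excluded,
        moving=new.moving,
        fixed=new.fixed,
        history=report.history + (action,),
    )


def resample(
    volume: Volume3D,
    transform: RigidTransform,
    reference: Volume3D,
    fill: float = 0.0,
    order: int = 1,
) -> Volume3D:
    """Resample ``volume`` onto the grid of ``reference``.

    ``transform`` maps the volume's frame into the reference frame.  The
    output voxel at reference-world position ``x`` takes the value of the
    input at ``transform⁻¹(x)``, interpolated trilinearly by default;
    positions outside the input field of view receive ``fill``.
    """
    inv = transform.inverse()
    s_in = np.asarray(volume.spacing_mm)
    s_ref = np.asarray(reference.spacing_mm)
    o_in = np.asarray(volume.origin_mm)
    o_ref = np.asarray(reference.origin_mm)
    # index_in = S_in^-1 (R^-1 (o_ref + S_ref idx_ref) + t_inv - o_in)
    matrix = (inv.rotation * s_ref) / s_in[:, None]
    offset = (inv.rotation @ o_ref + inv.translation_mm - o_in) / s_in
    data = ndimage.affine_transform(
        np.asarray(volume.data, dtype=float),
        matrix,
        offset=offset,
        output_shape=reference.shape,
        order=order,
        cval=fill,
        mode="constant",
    )
    return Volume3D(
        data=data,
        spacing_mm=reference.spacing_mm,
        origin_mm=reference.origin_mm,
        modality=volume.modality,
    )
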