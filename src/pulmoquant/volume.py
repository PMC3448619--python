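"""Shared spatial types: volumes, masks, landmark sets and rigid transforms.

Conventions used throughout the package:

* Volume arrays are indexed ``[i, j, k]`` along the world ``(x, y, z)`` axes.
* World coordinates are millimetres in a right-handed frame with
  ``world = origin + index * spacing`` and 0-based indices.
* CT volumes carry Hounsfield units; PET volumes carry count-rate units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError, PairingError

__all__ = [
    "Volume3D",
    "SegmentationMask",
    "LandmarkSet",
    "RigidTransform",
]

_ORTHONORMALITY_TOL = 1e-9


@dataclass(frozen=True)
class Volume3D:
    """A 3D scalar field on a regular axis-aligned grid.

    Parameters
    ----------
    data
        3D array indexed ``[i, j, k]`` along world ``(x, y, z)``.
    spacing_mm
        Voxel edge lengths in mm, one per axis.
    origin_mm
        World coordinate of the centre of voxel ``(0, 0, 0)``.
    modality
        ``"CT"`` (Hounsfield units) or ``"PET"`` (count-rate units).
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: str = "CT"

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got shape {data.shape}")
        object.__setattr__(self, "data", data)
        spacing = tuple(float(s) for s in self.spacing_mm)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive lengths, got {self.spacing_mm}")
        object.__setattr__(self, "spacing_mm", spacing)
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices to world mm coordinates."""
        return np.asarray(self.origin_mm) + np.asarray(index, dtype=float) * np.asarray(
            self.spacing_mm
        )

    def world_to_index(self, world: np.ndarray) -> np.ndarray:
        """Map world mm coordinates to fractional voxel indices."""
        return (np.asarray(world, dtype=float) - np.asarray(self.origin_mm)) / np.asarray(
            self.spacing_mm
        )

    def with_data(self, data: np.ndarray, modality: str | None = None) -> "Volume3D":
        """Copy of this volume with new voxel data on the same grid."""
        return replace(self, data=data, modality=modality or self.modality)

    def same_grid(self, other: "Volume3D | SegmentationMask") -> bool:
        return (
            self.shape == other.data.shape
            and np.allclose(self.spacing_mm, other.spacing_mm)
            and np.allclose(self.origin_mm, other.origin_mm)
        )


@dataclass(frozen=True)
class SegmentationMask:
    """Boolean voxel set sharing a :class:`Volume3D` grid.

    ``provenance`` records how the mask was produced (seeds, tolerance,
    connectivity, ...); it travels with the mask into any serialized output.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=bool)
        if data.ndim != 3:
            raise ValueError(f"mask data must be 3D, got shape {data.shape}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz

    @property
    def volume_mm3(self) -> float:
        return float(self.data.sum()) * self.voxel_volume_mm3

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    def centroid_world(self) -> np.ndarray:
        """World-coordinate centroid of the set voxels (mm)."""
        if not self.data.any():
            raise ValueError("centroid of an empty mask is undefined")
        idx = np.argwhere(self.data).mean(axis=0)
        return np.asarray(self.origin_mm) + idx * np.asarray(self.spacing_mm)


class LandmarkSet:
    """Ordered, uniquely named 3D points (mm) in a single coordinate frame."""

    def __init__(
        self,
        points: Mapping[str, Iterable[float]],
        frame: str = "unspecified",
    ) -> None:
        self._points: dict[str, np.ndarray] = {}
        for name, p in points.items():
            p = np.asarray(tuple(p), dtype=float)
            if p.shape != (3,):
                raise ValueError(f"landmark {name!r} is not a 3D point")
            if name in self._points:
                raise PairingError(f"duplicate landmark name {name!r}")
            self._points[str(name)] = p
        self.frame = frame

    @property
    def names(self) -> list[str]:
        return list(self._points)

    def __len__(self) -> int:
        return len(self._points)

    def __getitem__(self, name: str) -> np.ndarray:
        return self._points[name]

    def __contains__(self, name: str) -> bool:
        return name in self._points

    def as_array(self, names: Iterable[str] | None = None) -> np.ndarray:
        """Points stacked as an (n, 3) array in the given (or native) order."""
        names = list(names) if names is not None else self.names
        missing = [n for n in names if n not in self._points]
        if missing:
            raise PairingError(f"landmarks missing from set: {missing}")
        return np.array([self._points[n] for n in names])

    def subset(self, names: Iterable[str]) -> "LandmarkSet":
        names = list(names)
        return LandmarkSet({n: self._points[n] for n in names}, frame=self.frame)

    def replace(self, name: str, point: Iterable[float]) -> "LandmarkSet":
        if name not in self._points:
            raise PairingError(f"landmark {name!r} not in set")
        pts = dict(self._points)
        pts[name] = np.asarray(tuple(point), dtype=float)
        return LandmarkSet(pts, frame=self.frame)

    def transformed(self, transform: "RigidTransform", frame: str | None = None) -> "LandmarkSet":
        pts = transform.apply(self.as_array())
        return LandmarkSet(
            dict(zip(self.names, pts)), frame=frame if frame is not None else self.frame
        )

    def to_dict(self) -> dict[str, list[float]]:
        return {n: p.tolist() for n, p in self._points.items()}

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"LandmarkSet({len(self)} points, frame={self.frame!r})"


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid map ``x -> R x + t`` between mm frames.

    The rotation must be proper orthogonal (det = +1) to within 1e-9;
    reflections are rejected at construction.
    """

    rotation: np.ndarray
    translation_mm: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation_mm, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("rotation must be a 3x3 matrix")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise DegenerateGeometryError("rotation matrix is not orthogonal")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise DegenerateGeometryError(
                f"rotation determinant {np.linalg.det(R):.6f} != +1 (reflection?)"
            )
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation_mm", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_euler_deg(
        cls,
        angles_deg: Iterable[float],
        translation_mm: Iterable[float] = (0.0, 0.0, 0.0),
        centre_mm: Iterable[float] | None = None,
    ) -> "RigidTransform":
        """Rotation from extrinsic xyz Euler angles (degrees), optionally about a centre.

        With ``centre_mm`` given, the map is ``x -> R (x - c) + c + t``.
        """
        R = Rotation.from_euler("xyz", list(angles_deg), degrees=True).as_matrix()
        t = np.asarray(tuple(translation_mm), dtype=float)
        if centre_mm is not None:
            c = np.asarray(tuple(centre_mm), dtype=float)
            t = c - R @ c + t
        return cls(R, t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to a single 3-vector or an (n, 3) stack of points."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        out = pts @ self.rotation.T + self.translation_mm
        return out[0] if single else out

    def compose(self, inner: "RigidTransform") -> "RigidTransform":
        """``self.compose(inner)`` maps ``x -> self(inner(x))``."""
        return RigidTransform(
            self.rotation @ inner.rotation,
            self.rotation @ inner.translation_mm + self.translation_mm,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation_mm)

    def to_dict(self) -> dict[str, list[float]]:
        return {
            "rotation_row_major": self.rotation.reshape(-1).tolist(),
            "translation_mm": self.translation_mm.tolist(),
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "RigidTransform":
        R = np.asarray(d["rotation_row_major"], dtype=float).reshape(3, 3)
        t = np.asarray(d["translation_mm"], dtype=float)
        return cls(R, t)
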