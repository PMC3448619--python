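"""Reading and writing volumes, masks and the study's CSV tables.

Volumes round-trip through MetaImage (``.mha``/``.mhd``, via SimpleITK)
or NIfTI (``.nii``/``.nii.gz``, via nibabel), preserving voxel spacing,
origin and values.  Internally arrays are indexed ``[x, y, z]``; the
SimpleITK array layout (``[z, y, x]``) is transposed at the boundary.

CSV tables use a header row and are validated on read; a missing column
raises a :class:`~pulmoquant.errors.FormatError` naming the column.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd
import SimpleITK as sitk

from . import __version__
from .errors import FormatError
from .segmentation import SeedPointSet
from .volume import LandmarkSet, SegmentationMask, Volume3D

__all__ = [
    "read_volume",
    "write_volume",
    "write_mask",
    "read_mask",
    "read_landmarks_csv",
    "write_landmarks_csv",
    "read_seeds_csv",
    "write_seeds_csv",
    "read_tld_csv",
    "make_provenance",
    "config_hash",
]

_LANDMARK_COLUMNS = ("name", "x_mm", "y_mm", "z_mm", "frame")
_SEED_COLUMNS = ("x", "y", "z", "coordinate_system")
_TLD_COLUMNS = ("position", "description", "mean_mGy", "sd_mGy")


def _require_columns(df: pd.DataFrame, columns: tuple[str, ...], path: Path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")


def _read_table(path: Path, columns: tuple[str, ...]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: not a readable CSV table ({exc})") from exc
    _require_columns(df, columns, path)
    return df


def read_volume(path: str | Path, modality: str = "CT") -> Volume3D:
    """Read a MetaImage or NIfTI volume."""
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if path.suffix in (".mha", ".mhd"):
        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        spacing = tuple(img.GetSpacing())
        origin = tuple(img.GetOrigin())
    elif suffixes.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        affine = img.affine
        spacing = tuple(float(s) for s in np.abs(np.diag(affine)[:3]))
        origin = tuple(float(o) for o in affine[:3, 3])
        if any(s <= 0 for s in spacing):
            raise FormatError(f"{path}: voxel spacing missing or non-positive")
    else:
        raise FormatError(f"{path}: unsupported volume format {path.suffix!r}")
    return Volume3D(data=data, spacing_mm=spacing, origin_mm=origin, modality=modality)


def write_volume(volume: Volume3D, path: str | Path) -> Path:
    """Write a volume as MetaImage or NIfTI, preserving grid metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    suffixes = "".join(path.suffixes)
    if path.suffix in (".mha", ".mhd"):
        img = sitk.GetImageFromArray(np.ascontiguousarray(volume.data.transpose(2, 1, 0)))
        img.SetSpacing(volume.spacing_mm)
        img.SetOrigin(volume.origin_mm)
        sitk.WriteImage(img, str(path), useCompression=False)
    elif suffixes.endswith((".nii", ".nii.gz")):
        affine = np.diag(list(volume.spacing_mm) + [1.0])
        affine[:3, 3] = volume.origin_mm
        nib.save(nib.Nifti1Image(np.asarray(volume.data), affine), str(path))
    else:
        raise FormatError(f"{path}: unsupported volume format {path.suffix!r}")
    return path


def write_mask(mask: SegmentationMask, path: str | Path) -> Path:
    """Write a mask as a uint8 label volume; provenance goes to a sidecar JSON."""
    vol = Volume3D(
        data=mask.data.astype(np.uint8),
        spacing_mm=mask.spacing_mm,
        origin_mm=mask.origin_mm,
        modality="LABEL",
    )
    out = write_volume(vol, path)
    if mask.provenance:
        sidecar = out.with_suffix(out.suffix + ".json") if out.suffix != ".gz" else Path(
            str(out) + ".json"
        )
        sidecar.write_text(
            json.dumps(
                {"provenance": dict(mask.provenance), "volume_mm3": mask.volume_mm3},
                indent=2,
                default=str,
            )
        )
    return out


def read_mask(path: str | Path) -> SegmentationMask:
    vol = read_volume(path, modality="LABEL")
    return SegmentationMask(
        data=vol.data > 0, spacing_mm=vol.spacing_mm, origin_mm=vol.origin_mm
    )


def read_landmarks_csv(path: str | Path) -> LandmarkSet:
    path = Path(path)
    df = _read_table(path, _LANDMARK_COLUMNS)
    frames = df["frame"].unique()
    if len(frames) != 1:
        raise FormatError(f"{path}: expected a single frame, found {list(frames)}")
    return LandmarkSet(
        {str(r.name): (r.x_mm, r.y_mm, r.z_mm) for r in df.itertuples(index=False)},
        frame=str(frames[0]),
    )


def write_landmarks_csv(landmarks: LandmarkSet, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {"name": n, "x_mm": p[0], "y_mm": p[1], "z_mm": p[2], "frame": landmarks.frame}
        for n, p in ((n, landmarks[n]) for n in landmarks.names)
    ]
    pd.DataFrame(rows, columns=list(_LANDMARK_COLUMNS)).to_csv(path, index=False)
    return path


def read_seeds_csv(path: str | Path) -> SeedPointSet:
    path = Path(path)
    df = _read_table(path, _SEED_COLUMNS)
    systems = df["coordinate_system"].unique()
    if len(systems) != 1 or systems[0] not in ("voxel", "world"):
        raise FormatError(
            f"{path}: coordinate_system must be uniformly 'voxel' or 'world', got {list(systems)}"
        )
    return SeedPointSet(
        points=df[["x", "y", "z"]].to_numpy(dtype=float),
        world_mm=systems[0] == "world",
    )


def write_seeds_csv(seeds: SeedPointSet, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(seeds.points, columns=["x", "y", "z"])
    df["coordinate_system"] = "world" if seeds.world_mm else "voxel"
    df.to_csv(path, index=False)
    return path


def read_tld_csv(path: str | Path) -> pd.DataFrame:
    return _read_table(Path(path), _TLD_COLUMNS)


def config_hash(config: Mapping[str, object]) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def make_provenance(seed: int | None, config: Mapping[str, object] | None = None) -> dict:
    """Provenance block embedded in every pipeline artifact."""
    return {
        "tool": "pulmoquant",
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config) if config is not None else None,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
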