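"""Volume, mask, manifest and feature-table I/O.

Images and masks travel as NIfTI; feature tables and cohort manifests as
UTF-8 CSV with ``.`` decimal so that round trips are diff-stable. The two
in-memory containers (:class:`ImageVolume`, :class:`BinaryMask`) carry the
voxel grid together with its physical spacing in mm, which every geometric
operation downstream depends on.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "ImageVolume",
    "BinaryMask",
    "CohortManifest",
    "FormatError",
    "AlignmentError",
    "SchemaError",
    "DEFAULT_AXIS_LABELS",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_manifest",
    "write_feature_table",
    "read_feature_table",
]

#: Canonical anatomical convention when a header is ambiguous: array axis 0
#: runs left→right, axis 1 posterior→anterior, axis 2 inferior→superior
#: (i.e. increasing index moves toward R, A, S respectively).
DEFAULT_AXIS_LABELS = ("R", "A", "S")


class FormatError(ValueError):
    """Raised for unreadable or structurally invalid image files."""


class AlignmentError(ValueError):
    """Raised when a mask's grid does not match its reference volume."""


class SchemaError(ValueError):
    """Raised when feature records disagree on the feature-name schema."""


@dataclass
class ImageVolume:
    """A 3D scalar image with physical voxel spacing.

    Parameters
    ----------
    data:
        3D array of intensities (arbitrary units).
    spacing:
        Voxel size ``(sx, sy, sz)`` in mm along the three array axes.
    axis_labels:
        Anatomical direction of *increasing* index on each axis, one of
        R/L, A/P, S/I. Defaults to the package convention (R, A, S).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    axis_labels: tuple[str, str, str] = DEFAULT_AXIS_LABELS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(f"volume must be 3D, got {self.data.ndim}D")
        if min(self.data.shape) < 1:
            raise FormatError("every volume axis must have size >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacing must be three positive mm values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz


@dataclass
class BinaryMask:
    """A boolean lesion mask on the same grid as its companion volume."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise FormatError(f"mask must be 3D, got {self.data.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def is_empty(self) -> bool:
        return not bool(self.data.any())

    def count(self) -> int:
        return int(self.data.sum())


@dataclass
class CohortManifest:
    """Cohort bookkeeping: one row per lesion with paths per timepoint.

    Columns: lesion_id, patient_id, path_mri1, path_mask1, optionally
    path_mri2/path_mask2, and the follow-up gross tumor volume in mm³.
    """

    rows: pd.DataFrame = field(default_factory=pd.DataFrame)

    REQUIRED = ("lesion_id", "patient_id", "path_mri1", "path_mask1", "followup_volume_mm3")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.rows.columns]
        if missing:
            raise SchemaError(f"manifest missing columns: {missing}")
        ids = self.rows["lesion_id"]
        if ids.duplicated().any():
            raise SchemaError("lesion_id values must be unique")
        if (self.rows["followup_volume_mm3"] < 0).any():
            raise SchemaError("followup_volume_mm3 must be >= 0")

    def has_second_timepoint(self) -> bool:
        return (
            "path_mri2" in self.rows.columns
            and self.rows["path_mri2"].notna().all()
        )


def _spacing_from_header(img: nib.Nifti1Image) -> tuple[float, float, float]:
    zooms = img.header.get_zooms()[:3]
    return tuple(float(z) for z in zooms)


def _axis_labels_from_affine(img: nib.Nifti1Image) -> tuple[str, str, str]:
    try:
        codes = nib.aff2axcodes(img.affine)
        if all(c in "RLAPSI" for c in codes):
            return tuple(codes)
    except Exception:
        pass
    return DEFAULT_AXIS_LABELS


def read_volume(path: str | os.PathLike) -> ImageVolume:
    """Read a NIfTI scalar volume; spacing comes from the header zooms.

    Axis labels are derived from the affine orientation, falling back to
    the package's R/A/S convention when the header is degenerate.
    """
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # unreadable / wrong magic
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D image, got {data.ndim}D")
    spacing = _spacing_from_header(img)
    if any(s <= 0 for s in spacing):
        raise FormatError(f"{path}: non-positive voxel spacing {spacing}")
    return ImageVolume(
        data=np.asarray(data, dtype=np.float64),
        spacing=spacing,
        axis_labels=_axis_labels_from_affine(img),
    )


def write_volume(volume: ImageVolume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI with a diagonal RAS affine from its spacing."""
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float64), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_mask(path: str | os.PathLike, reference: ImageVolume) -> BinaryMask:
    """Read a binary mask and validate its grid against ``reference``.

    Any nonzero voxel is foreground. A shape or spacing mismatch raises
    :class:`AlignmentError` before any feature computation can occur; an
    all-zero mask is returned as a valid (empty) mask and rejected by the
    downstream region/feature operations instead.
    """
    vol = read_volume(path)
    if vol.shape != reference.shape:
        raise AlignmentError(
            f"mask shape {vol.shape} does not match reference {reference.shape}"
        )
    if not np.allclose(vol.spacing, reference.spacing, rtol=1e-6, atol=1e-9):
        raise AlignmentError(
            f"mask spacing {vol.spacing} does not match reference {reference.spacing}"
        )
    return BinaryMask(data=vol.data != 0, spacing=reference.spacing)


def write_mask(mask: BinaryMask, path: str | os.PathLike) -> None:
    affine = np.diag(list(mask.spacing) + [1.0])
    img = nib.Nifti1Image(mask.data.astype(np.uint8), affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def read_manifest(path: str | os.PathLike) -> CohortManifest:
    return CohortManifest(rows=pd.read_csv(path))


def write_feature_table(records: Sequence, path: str | os.PathLike) -> None:
    """Write feature vectors as CSV, one row per lesion-timepoint.

    All records must share an identical ordered feature-name schema; the
    id columns ``lesion_id`` and ``timepoint`` come first, then the
    canonical feature columns. Read-back reproduces values to full float64
    precision.
    """
    records = list(records)
    if not records:
        pd.DataFrame(columns=["lesion_id", "timepoint"]).to_csv(path, index=False)
        return
    schema = list(records[0].values.keys())
    rows = []
    for rec in records:
        if list(rec.values.keys()) != schema:
            raise SchemaError(
                f"record {rec.lesion_id}@{rec.timepoint} does not match the first record's schema"
            )
        row = {"lesion_id": rec.lesion_id, "timepoint": rec.timepoint}
        row.update(rec.values)
        rows.append(row)
    df = pd.DataFrame(rows, columns=["lesion_id", "timepoint"] + schema)
    df.to_csv(path, index=False)


def read_feature_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a feature table back as a DataFrame (ids + feature columns)."""
    return pd.read_csv(path)
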