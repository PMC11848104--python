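"""Gradient-derived feature maps and the 90-feature vector.

Three per-voxel quantities are derived from the 3D Sobel gradient
``G = (Gx, Gy, Gz)`` of the image:

* GM — gradient magnitude, ``sqrt(Gx² + Gy² + Gz²)``;
* RG — radial gradient, the signed scalar projection of G onto the radial
  vector ``D = com − p`` pointing from the voxel toward the lesion's center
  of mass: ``RG = (G·D)/|D|``;
* RD — radial deviation, the angle between G and D:
  ``RD = arccos(RG/|G|) ∈ [0, π]``.

For a lesion whose intensity falls off with distance from the center the
gradient points inward, so RD ≈ 0; for an intensity that rises radially,
RD ≈ π. RD is undefined where the gradient vanishes or at the center-of-mass
voxel itself (|D| = 0); such voxels are excluded from statistics rather than
imputed, and the exclusion counts are recorded as provenance.

Each of the 10 region masks is summarized with the mean, population
standard deviation, and coefficient of variation of each of GM/RG/RD,
yielding 90 named features per lesion-timepoint:
``{region}_{param}_{stat}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import BinaryMask, ImageVolume
from .regions import REGION_NAMES, EmptyRegionError, RegionMaskSet

__all__ = [
    "GradientField",
    "RadialFrame",
    "FeatureVector",
    "FEATURE_NAMES",
    "PARAMS",
    "STATS",
    "compute_gradient_field",
    "compute_gm",
    "compute_rg_rd",
    "summarize_region",
    "extract_feature_vector",
    "delta_features",
]

PARAMS = ("GM", "RG", "RD")
STATS = ("mean", "std", "cv")

#: Canonical ordered names of the 90 features: region-major, then gradient
#: parameter, then statistic.
FEATURE_NAMES = tuple(
    f"{region}_{param}_{stat}"
    for region in REGION_NAMES
    for param in PARAMS
    for stat in STATS
)

# |mean| below this is treated as zero when forming CV (sentinel NaN).
_CV_MEAN_EPS = 1e-12
# |G| or |D| below this counts as a vanishing vector for RG/RD validity.
_NORM_EPS = 1e-12


@dataclass
class GradientField:
    """Per-voxel gradient components plus derived GM/RG/RD maps.

    ``valid_rd`` marks voxels where both |G| > 0 and |D| > 0, i.e. where
    the radial deviation angle is defined. ``valid_rg`` only requires
    |D| > 0 (RG of a zero gradient is a well-defined 0).
    """

    gx: np.ndarray
    gy: np.ndarray
    gz: np.ndarray
    gm: np.ndarray
    rg: np.ndarray
    rd: np.ndarray
    valid_rg: np.ndarray
    valid_rd: np.ndarray


@dataclass
class RadialFrame:
    """Radial geometry about the lesion center of mass.

    ``d_field`` holds the per-voxel radial vector D = com − p in mm,
    stacked on the last axis; ``d_norm`` its Euclidean length.
    """

    com_mm: tuple[float, float, float]
    d_field: np.ndarray
    d_norm: np.ndarray

    @classmethod
    def for_volume(cls, volume: ImageVolume, com_mm) -> "RadialFrame":
        coords = np.meshgrid(
            *[np.arange(n, dtype=np.float64) * s for n, s in zip(volume.shape, volume.spacing)],
            indexing="ij",
        )
        d = np.stack([c0 - c for c0, c in zip(com_mm, coords)], axis=-1)
        return cls(com_mm=tuple(float(c) for c in com_mm), d_field=d, d_norm=np.linalg.norm(d, axis=-1))


@dataclass
class FeatureVector:
    """The named 90-value feature record of one lesion at one timepoint."""

    lesion_id: str
    timepoint: str  # "mri1", "mri2" or "delta"
    values: dict[str, float]
    excluded_voxels: dict[str, int] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = tuple(self.values.keys())
        if names != FEATURE_NAMES:
            raise ValueError(
                f"feature vector must contain the canonical {len(FEATURE_NAMES)} names in order"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in FEATURE_NAMES], dtype=np.float64)


def compute_gradient_field(volume: ImageVolume):
    """3D Sobel gradient components in intensity per mm.

    The separable Sobel kernel (derivative [-1, 0, 1] along the axis,
    smoothing [1, 2, 1] along the other two) is normalized by the total
    smoothing weight (16) and by twice the axis spacing, so that a linear
    ramp of slope k intensity/mm yields exactly k on interior voxels.
    Borders are handled by edge replication.
    """
    if any(s <= 0 for s in volume.spacing):
        raise ValueError(f"spacing must be positive, got {volume.spacing}")
    data = np.asarray(volume.data, dtype=np.float64)
    comps = []
    for axis in range(3):
        raw = ndimage.sobel(data, axis=axis, mode="nearest")
        comps.append(raw / (16.0 * 2.0 * volume.spacing[axis]))
    return tuple(comps)


def compute_gm(gx: np.ndarray, gy: np.ndarray, gz: np.ndarray) -> np.ndarray:
    """Voxelwise Euclidean magnitude of the gradient vector."""
    return np.sqrt(gx * gx + gy * gy + gz * gz)


def compute_rg_rd(gx, gy, gz, frame: RadialFrame):
    """Radial gradient (signed) and radial deviation angle fields.

    Returns ``(rg, rd, valid_rd)``. RG is NaN where |D| = 0 (the exact
    center-of-mass voxel); RD is additionally NaN where the gradient
    vanishes, since the angle of a zero vector is meaningless.
    """
    g = np.stack([gx, gy, gz], axis=-1)
    g_norm = np.linalg.norm(g, axis=-1)
    d_ok = frame.d_norm > _NORM_EPS
    with np.errstate(invalid="ignore", divide="ignore"):
        rg = np.einsum("...i,...i->...", g, frame.d_field) / frame.d_norm
    rg[~d_ok] = np.nan
    valid_rd = d_ok & (g_norm > _NORM_EPS)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.clip(rg / g_norm, -1.0, 1.0)
    rd = np.where(valid_rd, np.arccos(np.where(valid_rd, cosang, 0.0)), np.nan)
    return rg, rd, valid_rd


def compute_field(volume: ImageVolume, com_mm) -> GradientField:
    """Full gradient field for a volume and a lesion center of mass."""
    gx, gy, gz = compute_gradient_field(volume)
    frame = RadialFrame.for_volume(volume, com_mm)
    gm = compute_gm(gx, gy, gz)
    rg, rd, valid_rd = compute_rg_rd(gx, gy, gz, frame)
    valid_rg = frame.d_norm > _NORM_EPS
    return GradientField(gx=gx, gy=gy, gz=gz, gm=gm, rg=rg, rd=rd,
                         valid_rg=valid_rg, valid_rd=valid_rd)


def summarize_region(field: np.ndarray, valid: np.ndarray | None, region: BinaryMask,
                     name: str = "region"):
    """(mean, population std, CV) of a scalar field over a region mask.

    ``valid`` restricts to voxels where the field is defined; an effective
    region with no voxels raises :class:`EmptyRegionError` naming the
    region. CV is NaN (flagged by the caller) when |mean| is below 1e-12.
    """
    sel = region.data if valid is None else (region.data & valid)
    vals = field[sel]
    if vals.size == 0:
        raise EmptyRegionError(f"region '{name}' has no valid voxels")
    mean = float(np.mean(vals))
    std = float(np.std(vals, ddof=0))
    cv = float("nan") if abs(mean) < _CV_MEAN_EPS else std / mean
    return mean, std, cv


def extract_feature_vector(
    volume: ImageVolume,
    regions: RegionMaskSet,
    lesion_id: str = "lesion",
    timepoint: str = "mri1",
    zscore: bool = False,
) -> FeatureVector:
    """Compute the 90 canonical features of one lesion-timepoint.

    Gradients are computed once on the full volume (so region boundaries do
    not alter convolution support) and then sampled per region. RG and RD
    statistics run only over their valid voxels; per-region exclusion counts
    are kept as provenance. ``zscore`` optionally standardizes the volume
    intensities first (off by default; gradients already discard offsets).
    """
    if volume.shape != regions.core.shape:
        raise ValueError("volume and region masks are on different grids")
    if zscore:
        data = np.asarray(volume.data, dtype=np.float64)
        sd = data.std()
        data = (data - data.mean()) / (sd if sd > 0 else 1.0)
        volume = ImageVolume(data, volume.spacing, volume.axis_labels)
    fld = compute_field(volume, regions.com_mm)
    values: dict[str, float] = {}
    excluded: dict[str, int] = {}
    flags: list[str] = []
    param_fields = {
        "GM": (fld.gm, None),
        "RG": (fld.rg, fld.valid_rg),
        "RD": (fld.rd, fld.valid_rd),
    }
    for rname, rmask in regions.iter_regions():
        if rmask.is_empty():
            raise EmptyRegionError(f"region '{rname}' is empty")
        for param in PARAMS:
            arr, valid = param_fields[param]
            mean, std, cv = summarize_region(arr, valid, rmask, name=f"{rname}/{param}")
            if valid is not None:
                excluded[f"{rname}_{param}"] = int(rmask.count() - (rmask.data & valid).sum())
            if np.isnan(cv):
                flags.append(f"{rname}_{param}_cv:zero-mean")
            for stat, val in zip(STATS, (mean, std, cv)):
                values[f"{rname}_{param}_{stat}"] = val
    # enforce canonical ordering regardless of construction order
    ordered = {n: values[n] for n in FEATURE_NAMES}
    return FeatureVector(lesion_id=lesion_id, timepoint=timepoint, values=ordered,
                         excluded_voxels=excluded, flags=flags)


def delta_features(fv1: FeatureVector, fv2: FeatureVector) -> FeatureVector:
    """Per-feature temporal difference (second scan minus first).

    Both vectors must describe the same lesion under the same schema; NaN
    in either input propagates to the delta and is flagged.
    """
    if fv1.lesion_id != fv2.lesion_id:
        raise ValueError(f"lesion mismatch: {fv1.lesion_id!r} vs {fv2.lesion_id!r}")
    if tuple(fv1.values.keys()) != tuple(fv2.values.keys()):
        raise ValueError("feature schemas differ")
    values = {}
    flags = []
    for name in FEATURE_NAMES:
        v = fv2.values[name] - fv1.values[name]
        if np.isnan(v):
            flags.append(f"{name}:nan-delta")
        values[name] = v
    return FeatureVector(lesion_id=fv1.lesion_id, timepoint="delta", values=values, flags=flags)
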