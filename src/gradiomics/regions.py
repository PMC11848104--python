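"""Region segmentation: core, peritumoral margin, and anatomical octants.

A lesion mask ``M`` is expanded and contracted with spacing-aware Euclidean
distance thresholds (the physical-mm analogue of morphological dilation
``M ⊕ B_d`` and erosion ``M ⊖ B_e``), giving

* core   = contracted mask,
* margin = expanded mask minus the core,

and the margin is split into eight octants by the sign of each physical
coordinate relative to the lesion's center of mass, labeled with anatomical
directions (R/L, A/P, S/I). Ten region masks result: core, whole margin,
and octants M_1..M_8.

Morphology is defined on physical distances, not voxel counts, because the
clinically meaningful margins are given in mm (3 mm for large lesions,
1 mm for small) while clinical voxels are routinely anisotropic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import BinaryMask

__all__ = [
    "MorphParams",
    "RegionMaskSet",
    "EmptyRegionError",
    "DegenerateLesionError",
    "OCTANT_LABELS",
    "REGION_NAMES",
    "lesion_volume_mm3",
    "classify_lesion_size",
    "margin_mm_for_volume",
    "dilate_mask",
    "contract_mask",
    "build_region_masks",
    "octant_of_point",
]

# Distance comparisons tolerate one ulp-scale slack so that voxels at
# exactly the threshold distance are included regardless of sqrt rounding.
_DIST_EPS = 1e-9

#: Canonical octant order M_1..M_8. Numeric subregion indices carry no
#: anatomical meaning on their own, so a fixed order is required for
#: reproducible feature names: sign pattern (+,+,+) is R-A-S under the
#: default axis convention (axis 0 L→R, axis 1 P→A, axis 2 I→S).
OCTANT_LABELS = ("RAS", "LAS", "RPS", "LPS", "RAI", "LAI", "RPI", "LPI")

#: The ten region names in canonical feature order.
REGION_NAMES = ("core", "margin") + tuple(f"oct_{o}" for o in OCTANT_LABELS)


class EmptyRegionError(ValueError):
    """A region contains no (valid) voxels where at least one is required."""


class DegenerateLesionError(ValueError):
    """Contraction removed every voxel of the lesion core."""


@dataclass
class MorphParams:
    """Physical morphology parameters.

    ``dilate_mm`` expands the lesion outward to form the outer margin
    boundary; ``contract_mm`` retracts the lesion to form the core. The
    contraction distance is not pinned down by clinical convention, so by
    default it mirrors the dilation (symmetric shell). ``size_threshold_mm3``
    separates large from small lesions (default 4000 mm³): large lesions get
    a 3 mm margin, small ones 1 mm.
    """

    dilate_mm: float = 3.0
    contract_mm: float | None = None
    size_threshold_mm3: float = 4000.0
    margin_large_mm: float = 3.0
    margin_small_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.dilate_mm <= 0:
            raise ValueError("dilate_mm must be > 0")
        if self.contract_mm is None:
            self.contract_mm = self.dilate_mm
        if self.contract_mm < 0:
            raise ValueError("contract_mm must be >= 0")
        if self.size_threshold_mm3 <= 0:
            raise ValueError("size_threshold_mm3 must be > 0")

    @classmethod
    def for_lesion(cls, volume_mm3: float, size_threshold_mm3: float = 4000.0) -> "MorphParams":
        """Margin parameters keyed to lesion size: 3 mm large, 1 mm small."""
        base = cls(size_threshold_mm3=size_threshold_mm3)
        d = base.margin_large_mm if volume_mm3 >= size_threshold_mm3 else base.margin_small_mm
        return cls(dilate_mm=d, size_threshold_mm3=size_threshold_mm3)


@dataclass
class RegionMaskSet:
    """The 10 region masks of one lesion at one timepoint."""

    core: BinaryMask
    margin: BinaryMask
    octants: dict[str, BinaryMask] = field(default_factory=dict)
    com_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def region(self, name: str) -> BinaryMask:
        if name == "core":
            return self.core
        if name == "margin":
            return self.margin
        if name.startswith("oct_"):
            return self.octants[name[4:]]
        raise KeyError(name)

    def iter_regions(self):
        yield "core", self.core
        yield "margin", self.margin
        for label in OCTANT_LABELS:
            yield f"oct_{label}", self.octants[label]


def lesion_volume_mm3(mask: BinaryMask) -> float:
    """Lesion volume: true-voxel count times the physical voxel volume."""
    if mask.is_empty():
        raise EmptyRegionError("lesion mask is empty")
    sx, sy, sz = mask.spacing
    return float(mask.count()) * sx * sy * sz


def classify_lesion_size(volume_mm3: float, params: MorphParams | None = None) -> str:
    """Classify a lesion as ``"large"`` (GTV >= 4000 mm³) or ``"small"``."""
    if volume_mm3 < 0:
        raise ValueError("volume must be >= 0")
    params = params or MorphParams()
    return "large" if volume_mm3 >= params.size_threshold_mm3 else "small"


def margin_mm_for_volume(volume_mm3: float, params: MorphParams | None = None) -> float:
    """Margin distance by size class: 3 mm for large lesions, 1 mm for small."""
    params = params or MorphParams()
    size = classify_lesion_size(volume_mm3, params)
    return params.margin_large_mm if size == "large" else params.margin_small_mm


def _distance_to_mask_mm(data: np.ndarray, spacing) -> np.ndarray:
    # EDT of the complement: at each voxel, Euclidean mm distance to the
    # nearest mask voxel (0 inside the mask).
    return ndimage.distance_transform_edt(~data, sampling=spacing)


def dilate_mask(mask: BinaryMask, distance_mm: float) -> BinaryMask:
    """All voxels within ``distance_mm`` (Euclidean, spacing-aware) of the mask."""
    if mask.is_empty():
        raise EmptyRegionError("cannot dilate an empty mask")
    if distance_mm < 0:
        raise ValueError("distance must be >= 0")
    if distance_mm == 0:
        return BinaryMask(mask.data.copy(), mask.spacing)
    dist = _distance_to_mask_mm(mask.data, mask.spacing)
    return BinaryMask(dist <= distance_mm + _DIST_EPS, mask.spacing)


def contract_mask(mask: BinaryMask, distance_mm: float) -> BinaryMask:
    """Mask voxels strictly farther than ``distance_mm`` from the complement.

    May be empty for thin lesions; the caller decides whether that is an
    error (see :func:`build_region_masks`).
    """
    if mask.is_empty():
        raise EmptyRegionError("cannot contract an empty mask")
    if distance_mm < 0:
        raise ValueError("distance must be >= 0")
    if distance_mm == 0:
        return BinaryMask(mask.data.copy(), mask.spacing)
    dist_to_bg = ndimage.distance_transform_edt(mask.data, sampling=mask.spacing)
    return BinaryMask(mask.data & (dist_to_bg > distance_mm + _DIST_EPS), mask.spacing)


def mask_centroid_mm(mask: BinaryMask) -> tuple[float, float, float]:
    """Unweighted centroid of the true voxels in physical mm coordinates."""
    if mask.is_empty():
        raise EmptyRegionError("centroid of an empty mask is undefined")
    idx = np.argwhere(mask.data).astype(np.float64)
    com_vox = idx.mean(axis=0)
    return tuple(float(c * s) for c, s in zip(com_vox, mask.spacing))


def octant_of_point(
    point_mm,
    com_mm,
    axis_labels=("R", "A", "S"),
) -> str:
    """Octant label of a physical point relative to the center of mass.

    Labels come from {R,L}×{A,P}×{S,I} by the coordinate sign on each
    anatomical axis; a coordinate exactly equal to the center of mass
    resolves to the positive direction (R, A, S) so the partition is
    deterministic.
    """
    pos_neg = {"R": "L", "L": "R", "A": "P", "P": "A", "S": "I", "I": "S"}
    out = []
    for p, c, lab in zip(point_mm, com_mm, axis_labels):
        out.append(lab if p >= c else pos_neg[lab])
    # normalize to R/L, A/P, S/I display order
    order = {"R": 0, "L": 0, "A": 1, "P": 1, "S": 2, "I": 2}
    out.sort(key=lambda ch: order[ch])
    return "".join(out)


def _octant_sign_masks(shape, spacing, com_mm, axis_labels):
    """Boolean sign-pattern arrays per octant label; ties go positive."""
    coords = [np.arange(n, dtype=np.float64) * s for n, s in zip(shape, spacing)]
    ax_pos = []  # per-axis boolean "positive side" arrays, broadcastable
    for axis, (c, com) in enumerate(zip(coords, com_mm)):
        shape_b = [1, 1, 1]
        shape_b[axis] = -1
        ax_pos.append((c >= com).reshape(shape_b))
    pos_label = dict(zip(axis_labels, range(3)))
    # map each canonical octant label to its sign requirement per axis
    out = {}
    for label in OCTANT_LABELS:
        req = []
        for ch in label:
            if ch in pos_label:
                req.append((pos_label[ch], True))
            else:
                flip = {"L": "R", "R": "L", "P": "A", "A": "P", "I": "S", "S": "I"}[ch]
                req.append((pos_label[flip], False))
        arr = np.ones((1, 1, 1), dtype=bool)
        for axis, positive in req:
            arr = arr & (ax_pos[axis] if positive else ~ax_pos[axis])
        out[label] = np.broadcast_to(arr, shape)
    return out


def build_region_masks(mask: BinaryMask, params: MorphParams) -> RegionMaskSet:
    """Build the 10 region masks for one lesion.

    core = contract(mask); margin = dilate(mask) minus core; octants
    partition the margin by coordinate sign about the lesion centroid.
    The margin is clipped to the image grid — a dilation that exits the
    field of view emits a warning, not an error.
    """
    if mask.is_empty():
        raise EmptyRegionError("lesion mask is empty")
    core = contract_mask(mask, params.contract_mm)
    if core.is_empty():
        raise DegenerateLesionError(
            f"contraction by {params.contract_mm} mm removed all "
            f"{mask.count()} lesion voxels; lesion too thin for this core margin"
        )
    expanded = dilate_mask(mask, params.dilate_mm)
    boundary = np.zeros(expanded.shape, dtype=bool)
    boundary[[0, -1], :, :] = True
    boundary[:, [0, -1], :] = True
    boundary[:, :, [0, -1]] = True
    if (expanded.data & boundary).any():
        warnings.warn(
            "dilated margin touches the image boundary; margin is clipped to the grid",
            stacklevel=2,
        )
    margin = BinaryMask(expanded.data & ~core.data, mask.spacing)
    com = mask_centroid_mm(mask)
    signs = _octant_sign_masks(mask.shape, mask.spacing, com, ("R", "A", "S"))
    octants = {
        label: BinaryMask(margin.data & signs[label], mask.spacing)
        for label in OCTANT_LABELS
    }
    return RegionMaskSet(core=core, margin=margin, octants=octants, com_mm=com)
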