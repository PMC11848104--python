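"""Synthetic lesions and cohorts with known ground truth.

Three generators cover the testing needs of the rest of the package:

* :func:`make_lesion_phantom` — a single 3D lesion (sphere, ellipsoid, or a
  lobulated union of offset ellipsoids) with a controllable radial intensity
  profile, per-octant boundary sharpness multipliers, anisotropic spacing,
  and additive Gaussian noise;
* :func:`make_image_cohort` — a two-timepoint image cohort in which
  responders shrink between scans and at follow-up, emulating mid-treatment
  adaptation imaging;
* :func:`make_feature_cohort` — a fast table-level cohort with Gaussian
  class-conditional features and planted effect sizes, for modeling tests
  that do not need images.

Everything is deterministic given the spec's seed. Noise is additive
Gaussian; the generators aim at geometric and statistical structure, not
MR physics (no Rician noise, coil bias or acquisition artifacts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .gradients import FEATURE_NAMES, FeatureVector, delta_features, extract_feature_vector
from .io import BinaryMask, ImageVolume
from .regions import (
    OCTANT_LABELS,
    MorphParams,
    build_region_masks,
    lesion_volume_mm3,
    mask_centroid_mm,
)

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "PhantomSpecError",
    "make_lesion_phantom",
    "make_image_cohort",
    "make_feature_cohort",
]


class PhantomSpecError(ValueError):
    """Invalid phantom or cohort specification."""


@dataclass
class PhantomSpec:
    """Parameters of one synthetic lesion.

    ``octant_sharpness`` multiplies the intensity amplitude (hence the
    boundary gradient) per anatomical octant; the per-octant scale field is
    smoothed so octant seams do not create artificial gradients.
    ``radius_mm`` must leave room inside the grid for a dilation margin.
    """

    shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    geometry: str = "sphere"  # sphere | ellipsoid | lobulated
    radius_mm: float = 8.0
    axis_ratios: tuple[float, float, float] = (1.0, 0.75, 0.6)  # ellipsoid only
    profile: str = "decreasing_gaussian"  # decreasing_gaussian | increasing_radial | flat
    amplitude: float = 100.0
    octant_sharpness: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.0
    center_mm: tuple[float, float, float] | None = None
    margin_mm: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.geometry not in ("sphere", "ellipsoid", "lobulated"):
            raise PhantomSpecError(f"unknown geometry {self.geometry!r}")
        if self.profile not in ("decreasing_gaussian", "increasing_radial", "flat"):
            raise PhantomSpecError(f"unknown profile {self.profile!r}")
        bad = [k for k in self.octant_sharpness if k not in OCTANT_LABELS]
        if bad:
            raise PhantomSpecError(f"unknown octant labels {bad}")
        if any(v <= 0 for v in self.octant_sharpness.values()):
            raise PhantomSpecError("octant_sharpness values must be > 0")
        extent = [n * s for n, s in zip(self.shape, self.spacing)]
        if any(2 * (self.radius_mm + self.margin_mm) >= e for e in extent):
            raise PhantomSpecError(
                f"lesion radius {self.radius_mm} mm + margin {self.margin_mm} mm "
                f"does not fit in grid extent {extent} mm"
            )


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort (image-level or table-level).

    Defaults mirror the adaptive-radiotherapy cohort the pipeline targets:
    69 lesions of which 55 respond (>= 20% volume reduction at follow-up),
    i.e. a roughly 4:1 imbalance with the non-responder minority.
    """

    n_lesions: int = 69
    class_balance: float = 55 / 69  # fraction of responders
    planted_features: dict[str, float] = field(default_factory=dict)  # name -> effect size d
    planted_mode: str = "mri1"  # timepoint whose features carry the effect
    responder_followup_ratio: tuple[float, float] = (0.50, 0.10)  # mean, sd of V_fu/V_init
    nonresponder_followup_ratio: tuple[float, float] = (1.10, 0.15)
    responder_shrink: float = 0.85  # mri2/mri1 radius ratio for responders
    sharpness_by_class: dict[str, dict[str, float]] | None = None
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lesions < 4:
            raise PhantomSpecError("cohort needs at least 4 lesions")
        if not 0.0 < self.class_balance < 1.0:
            raise PhantomSpecError("class_balance must be in (0, 1)")
        unknown = [n for n in self.planted_features if _strip_mode(n) not in FEATURE_NAMES]
        if unknown:
            raise PhantomSpecError(f"unknown planted feature names: {unknown}")
        if any(not np.isfinite(d) for d in self.planted_features.values()):
            raise PhantomSpecError("effect sizes must be finite")


def _strip_mode(name: str) -> str:
    return name.split(":", 1)[1] if ":" in name else name


def _radial_distance(shape, spacing, center_mm, axis_ratios=(1, 1, 1)):
    coords = np.meshgrid(
        *[np.arange(n, dtype=np.float64) * s for n, s in zip(shape, spacing)],
        indexing="ij",
    )
    sq = sum(((c - c0) / r) ** 2 for c, c0, r in zip(coords, center_mm, axis_ratios))
    return np.sqrt(sq)


def _octant_scale_field(shape, spacing, center_mm, sharpness):
    """Smooth per-octant amplitude multiplier field (1.0 where unspecified)."""
    scale = np.ones(shape, dtype=np.float64)
    if not sharpness:
        return scale
    coords = np.meshgrid(
        *[np.arange(n, dtype=np.float64) * s for n, s in zip(shape, spacing)],
        indexing="ij",
    )
    pos = [c >= c0 for c, c0 in zip(coords, center_mm)]
    sign_of = {"R": (0, True), "L": (0, False), "A": (1, True), "P": (1, False),
               "S": (2, True), "I": (2, False)}
    for label, mult in sharpness.items():
        sel = np.ones(shape, dtype=bool)
        for ch in label:
            axis, positive = sign_of[ch]
            sel &= pos[axis] if positive else ~pos[axis]
        scale[sel] = mult
    # smooth seams over ~2 voxels so octant planes carry no artificial edge
    return ndimage.gaussian_filter(scale, sigma=2.0, mode="nearest")


def make_lesion_phantom(spec: PhantomSpec):
    """Build one synthetic lesion.

    Returns ``(volume, mask, ground_truth)`` where ``ground_truth`` records
    the analytically expected feature regimes: the radial-deviation regime
    ("low" for a decreasing profile — gradient aligned with the inward radial
    vector — "high" for an increasing one) and the planted per-octant
    gradient-magnitude ranking.
    """
    rng = np.random.default_rng(spec.seed)
    center = spec.center_mm or tuple(
        (n - 1) * s / 2.0 for n, s in zip(spec.shape, spec.spacing)
    )
    ratios = spec.axis_ratios if spec.geometry == "ellipsoid" else (1.0, 1.0, 1.0)
    r = _radial_distance(spec.shape, spec.spacing, center, ratios)
    mask_arr = r <= spec.radius_mm
    if spec.geometry == "lobulated":
        n_lobes = int(rng.integers(2, 5))
        for _ in range(n_lobes - 1):
            off = rng.uniform(-0.6, 0.6, size=3) * spec.radius_mm
            c2 = tuple(c + o for c, o in zip(center, off))
            rr = rng.uniform(0.4, 0.8) * spec.radius_mm
            r2 = _radial_distance(spec.shape, spec.spacing, c2, (1, 1, 1))
            mask_arr |= r2 <= rr
    if spec.profile == "decreasing_gaussian":
        sigma = spec.radius_mm / 1.5
        intensity = spec.amplitude * np.exp(-(r ** 2) / (2 * sigma ** 2))
        rd_regime = "low"
    elif spec.profile == "increasing_radial":
        intensity = spec.amplitude * np.clip(r / (2 * spec.radius_mm), 0, 1.5)
        rd_regime = "high"
    else:  # flat
        intensity = np.where(mask_arr, spec.amplitude, 0.0)
        rd_regime = "none"
    scale = _octant_scale_field(spec.shape, spec.spacing, center, spec.octant_sharpness)
    intensity = intensity * scale
    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    volume = ImageVolume(intensity, spec.spacing)
    mask = BinaryMask(mask_arr, spec.spacing)
    sharp = {o: spec.octant_sharpness.get(o, 1.0) for o in OCTANT_LABELS}
    ground_truth = {
        "center_mm": center,
        "rd_regime": rd_regime,
        "octant_sharpness": sharp,
        "octant_gm_ranking": sorted(OCTANT_LABELS, key=lambda o: -sharp[o]),
    }
    return volume, mask, ground_truth


def _cohort_labels(n: int, balance: float, rng) -> np.ndarray:
    n_resp = int(round(n * balance))
    n_resp = min(max(n_resp, 2), n - 2)
    labels = np.array(["responder"] * n_resp + ["non_responder"] * (n - n_resp))
    rng.shuffle(labels)
    return labels


def make_image_cohort(spec: CohortSpec, base: PhantomSpec | None = None):
    """Two-timepoint image cohort with class-linked volume change.

    Returns ``(lesions, manifest)`` where ``lesions`` maps lesion_id to a
    dict with keys ``mri1``/``mask1``/``mri2``/``mask2``, initial and
    follow-up volumes, and the true label. Responder lesions shrink by
    ``responder_shrink`` between scans and their follow-up ratio is drawn
    below 0.8; non-responders stay or grow.
    """
    rng = np.random.default_rng(spec.seed)
    base = base or PhantomSpec(shape=(40, 40, 40), radius_mm=6.0, margin_mm=3.0,
                               noise_sd=spec.noise_sd)
    labels = _cohort_labels(spec.n_lesions, spec.class_balance, rng)
    lesions = {}
    rows = []
    for i, label in enumerate(labels):
        lesion_id = f"lesion_{i:03d}"
        if spec.sharpness_by_class is not None:
            sharp = dict(spec.sharpness_by_class.get(
                "responder" if label == "responder" else "non_responder", {}))
        else:
            sharp = {}
        r1 = base.radius_mm * float(rng.uniform(0.85, 1.15))
        seed_i = int(rng.integers(0, 2**31 - 1))
        spec1 = PhantomSpec(shape=base.shape, spacing=base.spacing, geometry=base.geometry,
                            radius_mm=r1, profile=base.profile, amplitude=base.amplitude,
                            octant_sharpness=sharp, noise_sd=spec.noise_sd,
                            margin_mm=base.margin_mm, seed=seed_i)
        vol1, mask1, _ = make_lesion_phantom(spec1)
        r2 = r1 * (spec.responder_shrink if label == "responder"
                   else float(rng.uniform(0.98, 1.08)))
        spec2 = PhantomSpec(shape=base.shape, spacing=base.spacing, geometry=base.geometry,
                            radius_mm=r2, profile=base.profile, amplitude=base.amplitude,
                            octant_sharpness=sharp, noise_sd=spec.noise_sd,
                            margin_mm=base.margin_mm, seed=seed_i + 1)
        vol2, mask2, _ = make_lesion_phantom(spec2)
        v_init = lesion_volume_mm3(mask1)
        if label == "responder":
            mu, sd = spec.responder_followup_ratio
            ratio = float(np.clip(rng.normal(mu, sd), 0.05, 0.79))
        else:
            mu, sd = spec.nonresponder_followup_ratio
            ratio = float(np.clip(rng.normal(mu, sd), 0.80, 3.0))
        v_fu = v_init * ratio
        lesions[lesion_id] = {
            "mri1": vol1, "mask1": mask1, "mri2": vol2, "mask2": mask2,
            "initial_volume_mm3": v_init, "followup_volume_mm3": v_fu,
            "true_label": str(label),
        }
        rows.append({"lesion_id": lesion_id, "patient_id": f"pt_{i // 2:03d}",
                     "initial_volume_mm3": v_init, "followup_volume_mm3": v_fu})
    return lesions, pd.DataFrame(rows)


def extract_cohort_features(lesions: dict, params: MorphParams | None = None) -> pd.DataFrame:
    """Run region building + feature extraction for every lesion/timepoint.

    Returns a long DataFrame with lesion_id, timepoint and the 90 features;
    delta rows are included when both timepoints are present. Margin
    distances follow the lesion-size rule unless ``params`` is given.
    """
    rows = []
    for lesion_id, d in lesions.items():
        fvs = {}
        for tp, (vk, mk) in (("mri1", ("mri1", "mask1")), ("mri2", ("mri2", "mask2"))):
            if vk not in d or d[vk] is None:
                continue
            vol, mask = d[vk], d[mk]
            p = params or MorphParams.for_lesion(lesion_volume_mm3(mask))
            regions = build_region_masks(mask, p)
            fvs[tp] = extract_feature_vector(vol, regions, lesion_id=lesion_id, timepoint=tp)
        if "mri1" in fvs and "mri2" in fvs:
            fvs["delta"] = delta_features(fvs["mri1"], fvs["mri2"])
        for tp, fv in fvs.items():
            row = {"lesion_id": lesion_id, "timepoint": tp}
            row.update(fv.values)
            rows.append(row)
    return pd.DataFrame(rows)


def make_feature_cohort(spec: CohortSpec):
    """Table-level cohort: Gaussian features with planted effect sizes.

    Features are standard normal per lesion and timepoint; each planted
    feature name (optionally prefixed ``mode:`` — e.g. ``"mri1:core_GM_mean"``,
    default mode from ``spec.planted_mode``) has its class means separated by
    the stated effect size, the non-responder class sitting higher. Returns a
    :class:`~gradiomics.modeling.CohortTable`.
    """
    from .modeling import CohortTable  # local import to avoid a cycle

    rng = np.random.default_rng(spec.seed)
    labels = _cohort_labels(spec.n_lesions, spec.class_balance, rng)
    ids = [f"lesion_{i:03d}" for i in range(spec.n_lesions)]
    frames = {}
    for tp in ("mri1", "mri2"):
        frames[tp] = pd.DataFrame(
            rng.standard_normal((spec.n_lesions, len(FEATURE_NAMES))),
            index=ids, columns=FEATURE_NAMES,
        )
    planted = []
    for name, d in spec.planted_features.items():
        mode, feat = (name.split(":", 1) if ":" in name else (spec.planted_mode, name))
        planted.append((mode, feat, np.where(labels == "non_responder", d, 0.0)))
    for mode, feat, shift in planted:
        if mode != "delta":
            frames[mode][feat] = frames[mode][feat] + shift
    frames["delta"] = frames["mri2"] - frames["mri1"]
    for mode, feat, shift in planted:
        if mode == "delta":
            frames[mode][feat] = frames[mode][feat] + shift
    v_init = rng.uniform(500.0, 20000.0, size=spec.n_lesions)
    ratios = np.where(
        labels == "responder",
        np.clip(rng.normal(*spec.responder_followup_ratio, size=spec.n_lesions), 0.05, 0.79),
        np.clip(rng.normal(*spec.nonresponder_followup_ratio, size=spec.n_lesions), 0.80, 3.0),
    )
    return CohortTable(
        features={tp: frames[tp] for tp in ("mri1", "mri2", "delta")},
        initial_volume_mm3=pd.Series(v_init, index=ids),
        followup_volume_mm3=pd.Series(v_init * ratios, index=ids),
    )
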