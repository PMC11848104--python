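"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from gradiomics import (
    BinaryMask,
    CohortSpec,
    MorphParams,
    PhantomSpec,
    build_region_masks,
    make_feature_cohort,
    make_lesion_phantom,
)

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


# ---------------------------------------------------------------- oracles

def brute_force_dilate(mask: BinaryMask, distance_mm: float) -> np.ndarray:
    """Reference dilation: per-voxel min Euclidean distance to mask voxels.

    Independent of the distance-transform implementation: loops over mask
    voxels accumulating the minimum squared physical distance on the grid.
    """
    sp = np.asarray(mask.spacing)
    grids = np.meshgrid(*[np.arange(n, dtype=float) * s for n, s in zip(mask.shape, sp)],
                        indexing="ij")
    min_d2 = np.full(mask.shape, np.inf)
    for vox in np.argwhere(mask.data):
        p = vox * sp
        d2 = sum((g - c) ** 2 for g, c in zip(grids, p))
        np.minimum(min_d2, d2, out=min_d2)
    return np.sqrt(min_d2) <= distance_mm + 1e-9


def brute_force_contract(mask: BinaryMask, distance_mm: float) -> np.ndarray:
    """Reference contraction: per mask voxel, min distance to the complement."""
    sp = np.asarray(mask.spacing)
    comp = np.argwhere(~mask.data).astype(float) * sp
    out = np.zeros(mask.shape, dtype=bool)
    for vox in np.argwhere(mask.data):
        p = vox * sp
        if comp.size == 0:
            out[tuple(vox)] = True
            continue
        d2 = ((comp - p) ** 2).sum(axis=1).min()
        out[tuple(vox)] = np.sqrt(d2) > distance_mm + 1e-9
    return out


def random_blob_mask(shape, spacing, seed, target_fill=0.05) -> BinaryMask:
    """A connected-ish random mask from thresholded smoothed noise."""
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=2.0)
    thresh = np.quantile(field, 1 - target_fill)
    data = field >= thresh
    if not data.any():
        data[tuple(s // 2 for s in shape)] = True
    return BinaryMask(data, spacing)


# ---------------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def sphere_phantom():
    """Noise-free decreasing-Gaussian sphere with its region masks."""
    vol, mask, gt = make_lesion_phantom(
        PhantomSpec(shape=(40, 40, 40), radius_mm=7.0, noise_sd=0.0, seed=0)
    )
    regions = build_region_masks(mask, MorphParams(dilate_mm=3.0))
    return vol, mask, regions, gt


@pytest.fixture(scope="session")
def planted_cohort():
    """Table-level cohort with three strong planted features (d = 2)."""
    spec = CohortSpec(
        n_lesions=100,
        class_balance=0.5,
        planted_features={
            "core_GM_mean": 2.0,
            "margin_RD_std": 2.0,
            "oct_RAS_RG_mean": 2.0,
        },
        seed=11,
    )
    return spec, make_feature_cohort(spec)


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no planted signal at all."""
    return make_feature_cohort(CohortSpec(n_lesions=100, class_balance=0.5, seed=13))
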