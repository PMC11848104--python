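"""Extract the 90 gradient features and see the radial-deviation geometry.

Two phantoms with opposite radial intensity profiles: when intensity falls
away from the center the Sobel gradient points inward, aligned with the
radial vector, so the radial deviation (RD) angle is near 0; an increasing
profile flips it to near pi.
"""

import numpy as np

from gradiomics import (
    MorphParams,
    PhantomSpec,
    build_region_masks,
    extract_feature_vector,
    make_lesion_phantom,
)

for profile in ("decreasing_gaussian", "increasing_radial"):
    vol, mask, _ = make_lesion_phantom(
        PhantomSpec(radius_mm=7.0, profile=profile, noise_sd=0.0, seed=0))
    regions = build_region_masks(mask, MorphParams(dilate_mm=3.0))
    fv = extract_feature_vector(vol, regions, lesion_id="demo")
    print(f"{profile}: {len(fv.values)} features")
    print(f"  margin_GM_mean = {fv.values['margin_GM_mean']:.3f} intensity/mm")
    print(f"  margin_RG_mean = {fv.values['margin_RG_mean']:.3f} (signed projection)")
    print(f"  margin_RD_mean = {fv.values['margin_RD_mean']:.3f} rad "
          f"(0 = inward gradient, pi = {np.pi:.3f} = outward)")
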