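"""Generate the default synthetic cohort and describe its structure.

The phantom is 20 subjects x 7 quantitative maps on a 32^3 grid (2 mm),
with three white-matter territories (track-like, frontal-subcortical,
central-subcortical) carrying the published subtype fingerprints, seven
missing maps, planted age/gender effects, and additive noise.
"""

import numpy as np

from wmfp import PhantomSpec, generate_phantom_cohort
from wmfp.maps import ANALYSIS_PARAMS

records, truth = generate_phantom_cohort(PhantomSpec(seed=0))

n_maps = sum(len(r.maps) for r in records)
print(f"subjects: {len(records)}, maps: {n_maps} "
      f"(= {len(records)} x 7 - {len(PhantomSpec().missing_entries)} missing)")
print(f"ages {truth.covariates.age.min():.0f}-{truth.covariates.age.max():.0f} y,"
      f" {sum(truth.covariates.gender == 'F')} women")

print("\nmean in-core value per territory (row) and parameter (column):")
header = " ".join(f"{p:>8s}" for p in ANALYSIS_PARAMS)
print(f"{'':10s}{header}")
for c, name in enumerate(truth.geometry.names):
    core = truth.core_mask(c)
    vals = []
    for p in ANALYSIS_PARAMS:
        per_subj = [r.maps[p].data[core].mean() for r in records if p in r.maps]
        vals.append(np.mean(per_subj))
    print(f"{name:10s}" + " ".join(f"{v:8.1f}" for v in vals))
print("\nThese in-core means reproduce the planted subtype fingerprints "
      "(e.g. track AD ~ 1066 um^2/s, frontal MPF ~ 13.8%); each subject "
      "deviates from them with the designed between-subject SD.")
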