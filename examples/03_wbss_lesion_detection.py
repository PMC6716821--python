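"""Whole brain-based spatial statistics on a lesioned synthetic cohort.

Simulates the full longitudinal design (9 mutant + 9 wildtype mice,
baseline + ~5-month follow-up) with an FA-reducing lesion inserted in
the right cortex/callosum of the mutant group at follow-up only, runs
normalization and the four pre-specified voxelwise contrasts, and
compares detected clusters with the known lesion.  Runtime: a few
minutes (the cohort is 36 simulated scans).
"""

import numpy as np

import dtipipe as d
from dtipipe.phantom import atlas_landmarks
from dtipipe.pipeline import process_cohort
from dtipipe.wbss import CONTRASTS, run_wbss

spec = d.PhantomSpec.default(grid_shape=(48, 48, 20), n_per_group=9)
manifest, stacks, truths = d.simulate_cohort(spec, 42)
lm = atlas_landmarks(spec)
landmarks = {k: t.subject_landmarks(lm) for k, t in truths.items()}
config = d.PipelineConfig()

result = process_cohort(manifest, stacks, landmarks, lm, config)
print(f"template grid {result.space.shape}, "
      f"analysis mask (FA >= 0.2): "
      f"{int((result.space.fa_template >= 0.2).sum())} voxels")

lesion = spec.lesion_mask_template(result.space)
for contrast in "abcd":
    _, table = run_wbss(result.manifest, result.metric_maps["FA"],
                        result.space, "FA", contrast, config)
    line = f"contrast {contrast} ({CONTRASTS[contrast]}): {len(table)} cluster(s)"
    if len(table):
        det = table.labels > 0
        dice = 2 * np.sum(det & lesion) / (det.sum() + lesion.sum())
        peak = table.df.iloc[0]
        line += (f", largest {int(peak.size_voxels)} voxels, peak at "
                 f"({peak.bregma_cor:+.2f}, {peak.bregma_hor:+.2f}, "
                 f"{peak.bregma_sag:+.2f}) mm, Dice vs truth {dice:.2f}")
    print(line)

# Expected pattern: nothing at baseline (a), a lesion-overlapping
# cluster at follow-up (b), within mutants (c) and in the per-day
# change contrast (d) — FA falls only where the lesion was inserted.
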