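"""Deterministic tractography and tractwise statistics (TFAS).

On a lesioned cohort, tracks the callosal bundle and the descending
corticospinal-like bundle on the averaged dataset and compares radial
diffusivity (RD) over each tract between genotypes per timepoint.  The
lesion touches the callosal pathway only, so TFAS shows the
affected/spared dissociation.
"""

import dtipipe as d
from dtipipe.phantom import atlas_landmarks
from dtipipe.pipeline import process_cohort, run_tract_analysis

spec = d.PhantomSpec.default(grid_shape=(24, 24, 10), n_per_group=9)
manifest, stacks, truths = d.simulate_cohort(spec, 7)
lm = atlas_landmarks(spec)
landmarks = {k: t.subject_landmarks(lm) for k, t in truths.items()}
config = d.PipelineConfig()
result = process_cohort(manifest, stacks, landmarks, lm, config)

for name, label in (("cc", "transcallosal"), ("cst", "corticospinal")):
    tract, per_subject, tests = run_tract_analysis(
        result, spec, name, config, metric="RD", seed_stride=7)
    print(f"\n{label} tract: {len(tract)} streamlines")
    for r in tests.itertuples():
        print(f"  {r.timepoint:9s} RD mutant {r.mean_mutant * 1e3:.3f}"
              f" +- {r.sem_mutant * 1e3:.3f}  wildtype "
              f"{r.mean_wildtype * 1e3:.3f} +- {r.sem_wildtype * 1e3:.3f} "
              f"(x1e-3 mm^2/s)  p = {r.p:.2g}")

# RD rises in the mutant group at follow-up for the callosal tract
# (p << 0.05) while the corticospinal tract shows no significant
# group difference at either timepoint.
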