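"""Motion screening of a DWI scan.

Corrupts five diffusion-weighted volumes with a rigid displacement plus
slice dropout, then scores every volume against its tensor-model
prediction.  Corrupted volumes fall to the bottom of the ranking and
tip the scan's verdict to fail.
"""

import numpy as np

import dtipipe as d

spec = d.PhantomSpec.default(grid_shape=(24, 24, 10))
rng = np.random.default_rng(1)
stack, _ = d.simulate_subject(spec, "wildtype", "baseline", rng)

verdict, scores = d.quality_check(stack)
print(f"clean scan:     verdict={verdict}, min score {scores.min():.3f}")

bad, idx = d.corrupt_with_motion(stack, 5, rng)
verdict, scores = d.quality_check(bad)
dw = np.flatnonzero(stack.scheme.dw_mask)
bad_pos = [int(np.where(dw == i)[0][0]) for i in idx]
print(f"corrupted scan: verdict={verdict}")
print(f"scores of corrupted volumes: {np.round(scores[bad_pos], 3)}")
print(f"lowest-scoring volumes are the corrupted ones: "
      f"{sorted(np.argsort(scores)[:5].tolist()) == sorted(bad_pos)}")

# A score near 1 means the volume deviates from the consensus tensor
# fit only by noise; displaced/dropout volumes score far lower.
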