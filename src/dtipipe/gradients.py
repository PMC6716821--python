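"""Diffusion gradient schemes.

The default acquisition scheme mirrors a single-shell rodent protocol:
30 diffusion-weighted directions at b = 1000 s/mm^2 plus 5 unweighted
(b = 0) reference volumes.  Vendor gradient tables are generally not
published, so the directions shipped here were obtained once by
minimising the antipodally-symmetric electrostatic (Coulomb) energy of
30 points on the unit sphere; the worst-case angle between any two
directions (treating g and -g as equivalent) is ~25.7 degrees, i.e. the
set is well spread.
"""

from __future__ import annotations

import numpy as np

__all__ = ["GradientScheme", "default_scheme", "ELECTROSTATIC_30"]

# 30 unit vectors, antipodal electrostatic-repulsion optimum (z >= 0 hemisphere).
ELECTROSTATIC_30 = np.array(
    [
        [-0.98824711, -0.03852595, 0.14793037],
        [-0.81797838, 0.42600839, 0.38655948],
        [-0.81209547, 0.02621229, 0.58293556],
        [-0.80014191, -0.41322391, 0.43476307],
        [-0.65415356, 0.74916570, 0.10408585],
        [-0.55764805, -0.80175174, 0.21499491],
        [-0.50502973, -0.21139852, 0.83681279],
        [-0.49900313, 0.29606477, 0.81445781],
        [-0.44350211, -0.62711019, 0.64034264],
        [-0.44316667, 0.69736792, 0.56327727],
        [-0.24762987, 0.94573520, 0.21039101],
        [-0.16118342, -0.98659455, 0.02551669],
        [-0.13401985, 0.01145979, 0.99091238],
        [-0.09167480, -0.86134568, 0.49967924],
        [-0.08854935, 0.53729440, 0.83873341],
        [-0.06840408, -0.46716029, 0.88152263],
        [0.07768212, 0.86098358, 0.50266565],
        [0.25335396, 0.22559856, 0.94070030],
        [0.28960926, -0.92362738, 0.25107557],
        [0.32089173, -0.65690565, 0.68227814],
        [0.34845254, -0.23728020, 0.90679597],
        [0.39649217, 0.59490883, 0.69919772],
        [0.50694571, 0.82228298, 0.25856671],
        [0.66009219, 0.12768447, 0.74025332],
        [0.66028659, -0.66352090, 0.35179772],
        [0.73544739, -0.30488809, 0.60511188],
        [0.76309889, 0.46954861, 0.44407679],
        [0.87041847, 0.49215820, 0.01232876],
        [0.92524192, -0.36767941, 0.09348386],
        [0.94394784, 0.04770778, 0.32662890],
    ]
)


class GradientScheme:
    """Per-volume gradient directions and b-values.

    Parameters
    ----------
    bvecs : (N, 3) array
        Unit direction per volume; zero vectors for b = 0 volumes.
    bvals : (N,) array
        b-value in s/mm^2 per volume.
    """

    def __init__(self, bvecs: np.ndarray, bvals: np.ndarray):
        bvecs = np.asarray(bvecs, dtype=float)
        bvals = np.asarray(bvals, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise ValueError(f"bvecs must be (N, 3), got {bvecs.shape}")
        if bvals.shape != (bvecs.shape[0],):
            raise ValueError(
                f"bvals length {bvals.shape} does not match bvecs {bvecs.shape}"
            )
        norms = np.linalg.norm(bvecs, axis=1)
        nonzero = bvals > 0
        if np.any(nonzero & (norms == 0)):
            raise ValueError("nonzero b-value with zero direction vector")
        # normalize nonzero directions to unit length, keep b0 rows as zeros
        out = np.zeros_like(bvecs)
        out[nonzero] = bvecs[nonzero] / norms[nonzero, None]
        bad = nonzero & (np.abs(norms - 1.0) > 1e-2)
        if np.any(np.abs(np.linalg.norm(out[nonzero], axis=1) - 1.0) > 1e-6):
            raise ValueError("direction normalization failed")
        del bad
        self.bvecs = out
        self.bvals = bvals

    @property
    def n_volumes(self) -> int:
        return len(self.bvals)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def n_b0(self) -> int:
        return int(np.sum(self.b0_mask))

    @property
    def dw_mask(self) -> np.ndarray:
        return ~self.b0_mask

    @property
    def n_directions(self) -> int:
        return int(np.sum(self.dw_mask))

    def rotated(self, rotation: np.ndarray) -> "GradientScheme":
        """Scheme with all directions rotated by a 3x3 rotation matrix."""
        return GradientScheme(self.bvecs @ np.asarray(rotation).T, self.bvals)

    def __eq__(self, other) -> bool:  # exact equality, used in round-trip tests
        return (
            isinstance(other, GradientScheme)
            and np.array_equal(self.bvecs, other.bvecs)
            and np.array_equal(self.bvals, other.bvals)
        )


def default_scheme(b: float = 1000.0, n_b0: int = 5) -> GradientScheme:
    """5 leading b = 0 volumes followed by the 30-direction shell."""
    bvecs = np.vstack([np.zeros((n_b0, 3)), ELECTROSTATIC_30])
    bvals = np.concatenate([np.zeros(n_b0), np.full(len(ELECTROSTATIC_30), b)])
    return GradientScheme(bvecs, bvals)
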