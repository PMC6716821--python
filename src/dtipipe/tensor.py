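"""Diffusion tensor estimation and scalar metric maps.

The tensor is fitted voxelwise by log-linear ordinary least squares on
the mono-exponential signal model

    S_k = S0 * exp(-b_k * g_k^T D g_k)

with S0 taken as the arithmetic mean of the b = 0 volumes.  At a single
shell of b = 1000 s/mm^2 this estimator is deterministic, fast and
adequate; an optional weighted fit (weights S_k^2, the usual
first-order noise propagation) is available behind a flag.  Negative
eigenvalues are clamped to zero before metric computation (this keeps
FA <= 1) and counted for quality control.

Scalar metrics, with eigenvalues l1 >= l2 >= l3 and lbar their mean:

    FA = sqrt(3/2) * sqrt(sum (li - lbar)^2) / sqrt(sum li^2)
    MD = lbar,  AD = l1,  RD = (l2 + l3) / 2
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .gradients import GradientScheme

__all__ = [
    "DWIStack",
    "TensorField",
    "MetricMap",
    "fit_tensor",
    "compute_metrics",
    "metrics_from_eigenvalues",
    "tensor_from_eigen",
]

METRICS = ("FA", "AD", "RD", "MD")


@dataclass
class DWIStack:
    """One subject-timepoint 4-D diffusion-weighted acquisition."""

    data: np.ndarray                  # (x, y, z, n_volumes), >= 0
    voxel_size_um: tuple              # native voxel size
    scheme: GradientScheme
    subject_id: str = ""
    timepoint: str = ""
    scan_date: Optional[datetime.date] = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("DWI data must be 4-D (x, y, z, volume)")
        if self.data.shape[3] != self.scheme.n_volumes:
            raise ValueError(
                f"volume count mismatch: data has {self.data.shape[3]} volumes "
                f"but gradient table has {self.scheme.n_volumes} entries"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("DWI intensities must be finite")
        if self.data.min() < 0:
            raise ValueError("DWI intensities must be non-negative")
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.asarray(self.voxel_size_um) / 1000.0

    @property
    def shape(self) -> tuple:
        return self.data.shape[:3]


@dataclass
class TensorField:
    """Voxelwise symmetric tensor, lower-triangular component order
    (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz), plus S0 and a validity mask."""

    components: np.ndarray            # (x, y, z, 6), mm^2/s
    s0: np.ndarray                    # (x, y, z)
    valid: np.ndarray                 # (x, y, z) bool
    n_clamped: int = 0                # voxels with negative eigenvalues clamped

    def as_matrices(self) -> np.ndarray:
        """(x, y, z, 3, 3) dense symmetric tensors."""
        c = self.components
        m = np.zeros(c.shape[:-1] + (3, 3))
        m[..., 0, 0] = c[..., 0]
        m[..., 1, 1] = c[..., 1]
        m[..., 2, 2] = c[..., 2]
        m[..., 0, 1] = m[..., 1, 0] = c[..., 3]
        m[..., 0, 2] = m[..., 2, 0] = c[..., 4]
        m[..., 1, 2] = m[..., 2, 1] = c[..., 5]
        return m

    def eigensystem(self, clamp: bool = True):
        """Eigenvalues (descending) and matching eigenvectors.

        Returns ``(evals, evecs)`` with evals (x, y, z, 3) sorted
        l1 >= l2 >= l3 and evecs[..., :, i] the eigenvector of evals[..., i].
        """
        w, v = np.linalg.eigh(self.as_matrices())   # ascending
        w = w[..., ::-1]
        v = v[..., ::-1]
        if clamp:
            w = np.clip(w, 0.0, None)
        return w, v


@dataclass
class MetricMap:
    """A 3-D scalar DTI metric field (FA dimensionless, others mm^2/s)."""

    values: np.ndarray
    metric: str
    space: str = "native"             # "native" | "template"
    valid: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}")
        self.values = np.asarray(self.values, dtype=float)


def _design_matrix(scheme: GradientScheme) -> np.ndarray:
    g = scheme.bvecs[scheme.dw_mask]
    b = scheme.bvals[scheme.dw_mask]
    return b[:, None] * np.column_stack(
        [
            g[:, 0] ** 2,
            g[:, 1] ** 2,
            g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            2 * g[:, 1] * g[:, 2],
        ]
    )


def fit_tensor(stack: DWIStack, s0_floor: float = 1e-8,
               weighted: bool = False) -> TensorField:
    """Log-linear least-squares tensor fit per voxel.

    Voxels whose mean-b0 S0 falls below ``s0_floor`` are masked invalid
    rather than raising.  Requires >= 6 independent diffusion directions
    and >= 1 b = 0 volume.
    """
    scheme = stack.scheme
    if scheme.n_b0 < 1:
        raise ValueError("tensor fit requires at least one b = 0 volume")
    g = scheme.bvecs[scheme.dw_mask]
    if g.shape[0] < 6 or np.linalg.matrix_rank(_design_matrix(scheme)) < 6:
        raise ValueError(
            "tensor fit requires at least 6 independent diffusion directions"
        )

    shape = stack.shape
    s0 = stack.data[..., scheme.b0_mask].mean(axis=-1)
    dwi = stack.data[..., scheme.dw_mask]
    valid = s0 > s0_floor

    B = _design_matrix(scheme)                      # (n_dw, 6)
    flat_s0 = s0.reshape(-1)
    flat = dwi.reshape(-1, B.shape[0])
    comps = np.zeros((flat.shape[0], 6))
    vmask = valid.reshape(-1)
    if np.any(vmask):
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = flat[vmask] / flat_s0[vmask, None]
        ratio = np.clip(ratio, 1e-12, None)
        y = -np.log(ratio)                           # (n_valid, n_dw)
        if weighted:
            # per-voxel weighted LSQ, weights = observed-signal squared
            w = np.clip(flat[vmask], 1e-12, None) ** 2
            A = np.einsum("vk,ki,kj->vij", w, B, B)
            rhs = np.einsum("vk,ki->vi", w * y, B)
            comps[vmask] = np.linalg.solve(A, rhs[..., None])[..., 0]
        else:
            pinv = np.linalg.pinv(B)                 # (6, n_dw)
            comps[vmask] = y @ pinv.T
    comps = comps.reshape(shape + (6,))
    vmask3 = valid & np.all(np.isfinite(comps), axis=-1)

    field = TensorField(comps, s0, vmask3)
    w_raw, _ = field.eigensystem(clamp=False)
    field.n_clamped = int(np.sum(np.any(w_raw < 0, axis=-1) & vmask3))
    return field


def metrics_from_eigenvalues(evals: np.ndarray) -> dict:
    """Closed-form FA/AD/RD/MD from (..., 3) descending eigenvalues."""
    lam = np.asarray(evals, dtype=float)
    md = lam.mean(axis=-1)
    ad = lam[..., 0]
    rd = (lam[..., 1] + lam[..., 2]) / 2.0
    dev = lam - md[..., None]
    num = np.sqrt(np.sum(dev**2, axis=-1))
    den = np.sqrt(np.sum(lam**2, axis=-1))
    with np.errstate(divide="ignore", invalid="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den > 0, fa, 0.0)
    fa = np.clip(fa, 0.0, 1.0)
    return {"FA": fa, "AD": ad, "RD": rd, "MD": md}


def compute_metrics(field: TensorField, space: str = "native") -> dict:
    """FA/AD/RD/MD maps from a fitted tensor field.

    Invalid voxels carry zeros and are flagged through each map's
    ``valid`` mask.
    """
    evals, _ = field.eigensystem(clamp=True)
    vals = metrics_from_eigenvalues(evals)
    out = {}
    for name in METRICS:
        v = np.where(field.valid, vals[name], 0.0)
        out[name] = MetricMap(v, metric=name, space=space, valid=field.valid.copy())
    return out


def tensor_from_eigen(evals, direction) -> np.ndarray:
    """Symmetric tensor with principal axis ``direction`` and the given
    (l1, l2, l3); the two minor axes are an arbitrary orthonormal
    completion (isotropic in the plane when l2 == l3)."""
    e1 = np.asarray(direction, dtype=float)
    e1 = e1 / np.linalg.norm(e1)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(e1 @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e2 = np.cross(e1, helper)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    R = np.column_stack([e1, e2, e3])
    return R @ np.diag(np.asarray(evals, dtype=float)) @ R.T
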