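"""Stereotaxic normalization: isogrid resampling, landmark-based linear
registration, nonlinear refinement and iterative study-specific
template construction, plus the per-scan motion quality check.

Template building follows the classic iterative scheme: subjects are
first brought into the template grid by an affine computed from
manually set landmark pairs and arithmetically averaged (iteration 1);
subsequent iterations add a small-deformation nonlinear refinement of
each subject towards the current FA template and re-average, until the
Pearson correlation between every subject's warped FA map and the FA
template exceeds the configured stop value (default 0.7) or the
iteration cap is reached.

The nonlinear step is a demons-style gradient descent on the
sum-of-squared-differences cost with Gaussian regularization of the
displacement field after every update — deliberately the simplest
scheme that satisfies the contract "improve the FA/template
correlation"; it is not diffeomorphic and no tensor reorientation is
performed (only scalar maps are warped).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .config import PipelineConfig
from .space import TemplateSpace
from .tensor import DWIStack

__all__ = [
    "SubjectScan",
    "SubjectTransform",
    "resample_isogrid",
    "landmark_affine",
    "apply_affine",
    "nonlinear_refine",
    "warp_to_template",
    "build_templates",
    "quality_check",
    "select_best_scan",
]


# ---------------------------------------------------------------------------
# resampling

def native_voxel_to_mm_offset(shape) -> np.ndarray:
    """Native grids put bregma at the volume center: voxel i maps to
    (i - (n - 1)/2) * voxel_size mm."""
    return (np.asarray(shape, dtype=float) - 1) / 2


def resample_isogrid(
    values: np.ndarray,
    voxel_size_mm: Sequence[float],
    target: Optional[TemplateSpace] = None,
    spacing_mm: float = 0.05,
    order: int = 0,
) -> Tuple[np.ndarray, TemplateSpace]:
    """Resample a native-grid volume onto an isotropic grid.

    Default interpolation is nearest neighbor (order 0), which
    guarantees the output value set is a subset of the input's.  When no
    target space is given, the grid is sized ``ceil(extent / spacing)``
    so it always covers the source extent.
    """
    values = np.asarray(values, dtype=float)
    vs = np.asarray(voxel_size_mm, dtype=float)
    extent = np.asarray(values.shape[:3]) * vs
    if target is None:
        dims = np.ceil(extent / spacing_mm - 1e-9).astype(int)
        target = TemplateSpace(tuple(dims), spacing_mm)
    else:
        tgt_extent = np.asarray(target.shape) * target.spacing_mm
        if np.any(tgt_extent < extent - 1e-9):
            raise ValueError(
                f"target grid extent {tuple(np.round(tgt_extent, 3))} mm does "
                f"not cover source extent {tuple(np.round(extent, 3))} mm"
            )
    mm = target.voxel_center_grid()
    src = mm / vs + native_voxel_to_mm_offset(values.shape[:3])
    out = ndimage.map_coordinates(
        values, [src[..., i] for i in range(3)], order=order, mode="nearest"
    )
    return out, target


# ---------------------------------------------------------------------------
# linear landmark registration

def apply_affine(affine: np.ndarray, points: np.ndarray) -> np.ndarray:
    p = np.asarray(points, dtype=float)
    return p @ affine[:3, :3].T + affine[:3, 3]


def landmark_affine(
    moving_landmarks: np.ndarray, fixed_landmarks: np.ndarray
) -> Tuple[np.ndarray, float]:
    """Least-squares affine A with A @ moving ~= fixed.

    Requires >= 4 non-coplanar landmark pairs.  Returns the 4x4 affine
    and the residual RMS in mm.
    """
    m = np.asarray(moving_landmarks, dtype=float)
    f = np.asarray(fixed_landmarks, dtype=float)
    if m.shape != f.shape or m.ndim != 2 or m.shape[1] != 3:
        raise ValueError("landmark sets must both be (N, 3)")
    if m.shape[0] < 4:
        raise ValueError("need at least 4 landmark pairs")
    X = np.column_stack([m, np.ones(len(m))])
    if np.linalg.matrix_rank(X) < 4:
        raise ValueError("landmarks are coplanar or otherwise degenerate")
    sol, *_ = np.linalg.lstsq(X, f, rcond=None)
    A = np.eye(4)
    A[:3, :3] = sol[:3].T
    A[:3, 3] = sol[3]
    resid = apply_affine(A, m) - f
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return A, rms


# ---------------------------------------------------------------------------
# nonlinear refinement (demons-style)

def _pearson(a: np.ndarray, b: np.ndarray, mask: Optional[np.ndarray] = None) -> float:
    if mask is not None:
        a, b = a[mask], b[mask]
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 and nb == 0:
        return 1.0
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def _warp_by_displacement(moving: np.ndarray, disp_vox: np.ndarray) -> np.ndarray:
    idx = np.stack(
        np.meshgrid(*[np.arange(s) for s in moving.shape], indexing="ij"), axis=-1
    ).astype(float)
    coords = idx + disp_vox
    return ndimage.map_coordinates(
        moving, [coords[..., i] for i in range(3)], order=1, mode="nearest"
    )


def _demons_level(moving, fixed, disp, sigma, n_iter, max_step=1.0):
    for _ in range(n_iter):
        warped = _warp_by_displacement(moving, disp)
        diff = warped - fixed
        grad = np.stack(np.gradient(warped), axis=-1)
        g2 = np.sum(grad**2, axis=-1)
        denom = g2 + diff**2 + 1e-12
        upd = -(diff / denom)[..., None] * grad
        norm = np.linalg.norm(upd, axis=-1)
        scale = np.where(norm > max_step, max_step / (norm + 1e-12), 1.0)
        upd *= scale[..., None]
        # fluid-like regularization: smooth the update, then accumulate
        # (smoothing the accumulated field contracts it toward zero)
        for i in range(3):
            upd[..., i] = ndimage.gaussian_filter(
                upd[..., i], sigma, mode="constant"
            )
        disp = disp + upd
    return disp


def nonlinear_refine(
    moving: np.ndarray,
    fixed: np.ndarray,
    smooth_sigma_vox: float = 2.0,
    n_iter: int = 30,
    spacing_mm: float = 0.05,
    init_disp_mm: Optional[np.ndarray] = None,
    mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Dense displacement field (mm, pull-back convention) registering
    ``moving`` to ``fixed`` on a shared isotropic grid.

    Two-level coarse-to-fine demons descent.  If the refined field does
    not improve the Pearson correlation with ``fixed``, the zero field
    (or the initial field) is returned instead, so the operation never
    degrades alignment.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape:
        raise ValueError("moving and fixed must share a grid")
    if not (np.all(np.isfinite(moving)) and np.all(np.isfinite(fixed))):
        raise ValueError("non-finite values in registration inputs")

    disp0 = (np.zeros(moving.shape + (3,)) if init_disp_mm is None
             else np.asarray(init_disp_mm, dtype=float) / spacing_mm)
    base_corr = _pearson(_warp_by_displacement(moving, disp0), fixed, mask)

    # coarse-to-fine pyramid: displacements found at coarse scale carry
    # large shifts cheaply, the fine level refines them
    disp = disp0.copy()
    for factor in (2, 1):
        if factor > 1 and min(moving.shape) < 4 * factor:
            continue
        if factor > 1:
            mv = ndimage.zoom(moving, 1.0 / factor, order=1)
            fx = ndimage.zoom(fixed, 1.0 / factor, order=1)
            dd = np.stack(
                [ndimage.zoom(disp[..., i], np.asarray(mv.shape)
                              / np.asarray(moving.shape), order=1) / factor
                 for i in range(3)],
                axis=-1,
            )
            dd = _demons_level(mv, fx, dd,
                               max(smooth_sigma_vox / factor, 0.5), n_iter)
            disp = np.stack(
                [ndimage.zoom(dd[..., i], np.asarray(moving.shape)
                              / np.asarray(mv.shape), order=1) * factor
                 for i in range(3)],
                axis=-1,
            )
        else:
            disp = _demons_level(moving, fixed, disp, smooth_sigma_vox, n_iter)

    new_corr = _pearson(_warp_by_displacement(moving, disp), fixed, mask)
    if new_corr < base_corr:
        disp = disp0
    return disp * spacing_mm


# ---------------------------------------------------------------------------
# subject transforms and template construction

@dataclass
class SubjectScan:
    """Native-space inputs to template building for one scan."""

    subject_id: str
    fa: np.ndarray
    b0: np.ndarray
    voxel_size_mm: Sequence[float]
    landmarks_mm: np.ndarray


@dataclass
class SubjectTransform:
    """Composition: native --(affine)--> template --(displacement)--> template.

    ``displacement_mm`` follows the pull-back convention: the warped map
    at template location x samples the affinely-aligned map at
    x + u(x)."""

    affine: np.ndarray                      # native mm -> template mm, 4x4
    displacement_mm: Optional[np.ndarray] = None
    correlation: float = np.nan

    def template_to_native_mm(self, pts_template_mm, space: TemplateSpace):
        p = np.asarray(pts_template_mm, dtype=float)
        if self.displacement_mm is not None:
            vox = space.mm_to_voxel(p)
            u = np.stack(
                [
                    ndimage.map_coordinates(
                        self.displacement_mm[..., i],
                        [vox[..., j] for j in range(3)],
                        order=1, mode="nearest",
                    )
                    for i in range(3)
                ],
                axis=-1,
            )
            p = p + u
        inv = np.linalg.inv(self.affine)
        return apply_affine(inv, p)


def template_sample_coords(
    transform: SubjectTransform,
    space: TemplateSpace,
    voxel_size_mm: Sequence[float],
    native_shape,
) -> np.ndarray:
    """Continuous native voxel coordinates sampled by each template voxel.

    Computing these once per scan lets all of a scan's volumes be warped
    without re-evaluating the transform."""
    mm = space.voxel_center_grid()
    native_mm = transform.template_to_native_mm(mm, space)
    return native_mm / np.asarray(voxel_size_mm, dtype=float) + \
        native_voxel_to_mm_offset(native_shape)


def _clamp_edge(c: np.ndarray, n: int, eps: float = 1e-6) -> np.ndarray:
    """Snap coordinates within float tolerance of the volume edge back
    onto it, so exact-identity transforms do not fall off the grid."""
    c = np.where((c >= -eps) & (c < 0), 0.0, c)
    return np.where((c > n - 1) & (c <= n - 1 + eps), float(n - 1), c)


def warp_with_coords(values_native: np.ndarray, src_coords: np.ndarray,
                     order: int = 1) -> np.ndarray:
    v = np.asarray(values_native, dtype=float)
    coords = [_clamp_edge(src_coords[..., i], v.shape[i]) for i in range(3)]
    return ndimage.map_coordinates(v, coords, order=order,
                                   mode="constant", cval=0.0)


def warp_to_template(
    values_native: np.ndarray,
    voxel_size_mm: Sequence[float],
    transform: SubjectTransform,
    space: TemplateSpace,
    order: int = 1,
) -> np.ndarray:
    """Pull a native-space scalar map onto the template grid."""
    src = template_sample_coords(transform, space, voxel_size_mm,
                                 values_native.shape)
    return warp_with_coords(values_native, src, order=order)


def build_templates(
    scans: List[SubjectScan],
    template_landmarks: np.ndarray,
    config: PipelineConfig,
    grid_shape: Optional[Tuple[int, int, int]] = None,
):
    """Iterative study-specific template construction.

    Returns ``(space, transforms, info)``: the template space carrying
    the final b0 and FA templates, one :class:`SubjectTransform` per
    scan, and a dict with the iteration count, per-subject correlations
    and a convergence flag.
    """
    if len(scans) < 1:
        raise ValueError("at least one scan required")
    if grid_shape is None:
        _, space = resample_isogrid(
            scans[0].fa, scans[0].voxel_size_mm, spacing_mm=config.iso_spacing_mm
        )
        grid_shape = space.shape
    space = TemplateSpace(grid_shape, config.iso_spacing_mm)

    transforms = []
    for s in scans:
        A, _ = landmark_affine(s.landmarks_mm, template_landmarks)
        transforms.append(SubjectTransform(affine=A))

    def averages():
        fa_w = [warp_to_template(s.fa, s.voxel_size_mm, t, space)
                for s, t in zip(scans, transforms)]
        b0_w = [warp_to_template(s.b0, s.voxel_size_mm, t, space)
                for s, t in zip(scans, transforms)]
        return fa_w, np.mean(fa_w, axis=0), np.mean(b0_w, axis=0)

    fa_warped, fa_tpl, b0_tpl = averages()
    mask = b0_tpl > 0.1 * b0_tpl.max() if b0_tpl.max() > 0 else None
    corrs = np.array([_pearson(w, fa_tpl, mask) for w in fa_warped])
    iteration = 1
    converged = bool(corrs.min() > config.template_corr_stop)

    while not converged and iteration < config.template_max_iter:
        iteration += 1
        for s, t in zip(scans, transforms):
            aligned = warp_to_template(
                s.fa, s.voxel_size_mm,
                SubjectTransform(affine=t.affine), space,
            )
            t.displacement_mm = nonlinear_refine(
                aligned, fa_tpl,
                smooth_sigma_vox=config.nonlinear_smooth_sigma_vox,
                n_iter=config.nonlinear_iterations,
                spacing_mm=config.iso_spacing_mm,
                init_disp_mm=t.displacement_mm,
                mask=mask,
            )
        fa_warped, fa_tpl, b0_tpl = averages()
        mask = b0_tpl > 0.1 * b0_tpl.max() if b0_tpl.max() > 0 else None
        corrs = np.array([_pearson(w, fa_tpl, mask) for w in fa_warped])
        converged = bool(corrs.min() > config.template_corr_stop)

    for t, c in zip(transforms, corrs):
        t.correlation = float(c)
    space.fa_template = np.clip(fa_tpl, 0.0, 1.0)
    space.b0_template = b0_tpl
    info = {
        "iterations": iteration,
        "correlations": corrs,
        "converged": converged,
    }
    return space, transforms, info


# ---------------------------------------------------------------------------
# quality check

def quality_check(
    stack: DWIStack,
    score_threshold: float = 0.8,
    max_bad_fraction: float = 0.1,
) -> Tuple[str, np.ndarray]:
    """Motion screening scored against the tensor-model prediction.

    The whole stack is tensor-fitted and each diffusion-weighted volume
    is compared with its model prediction through the root-mean-square
    residual over valid voxels.  The score is the ratio of the median
    residual to the volume's residual, capped at 1: clean volumes
    deviate from the model only by noise and score near 1, while a
    displaced or dropout-corrupted volume disagrees spatially with the
    fit driven by the remaining volumes, inflating its residual and
    deflating its score.  (Simple volume-to-volume correlation scores
    fail on diffusion data: anisotropic structures reverse contrast
    between gradient directions, and volumes with little tissue
    contrast correlate with nothing even when perfectly clean.)
    A scan fails when the fraction of volumes scoring below
    ``score_threshold`` exceeds ``max_bad_fraction``.  Deterministic.
    """
    from .tensor import fit_tensor  # local import, avoids cycle at module load

    field = fit_tensor(stack)
    scheme = stack.scheme
    g, b = scheme.bvecs, scheme.bvals
    design = b[:, None] * np.column_stack(
        [g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
         2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2],
         2 * g[:, 1] * g[:, 2]]
    )
    expo = field.components.reshape(-1, 6) @ design.T
    pred = field.s0.reshape(-1, 1) * np.exp(-expo)
    dw_idx = np.flatnonzero(scheme.dw_mask)
    vmask = field.valid.reshape(-1)
    obs = stack.data.reshape(-1, scheme.n_volumes)
    if not np.any(vmask):
        return "fail", np.zeros(len(dw_idx))
    resid = obs[vmask][:, dw_idx] - pred[vmask][:, dw_idx]
    rmse = np.sqrt(np.mean(resid**2, axis=0))
    med = np.median(rmse)
    if med == 0:
        # noise-free (e.g. constant) stacks: any nonzero residual flags
        scores = np.where(rmse == 0, 1.0, 0.0)
    else:
        scores = np.minimum(1.0, med / rmse)
    n_bad = int(np.sum(scores < score_threshold))
    verdict = "fail" if n_bad / len(scores) > max_bad_fraction else "pass"
    return verdict, scores


def select_best_scan(candidates: List[DWIStack], **qc_kwargs) -> Optional[int]:
    """Index of the best passing scan (highest mean volume score) among
    repeated acquisitions of one subject-timepoint; None if all fail."""
    best, best_score = None, -np.inf
    for i, st in enumerate(candidates):
        verdict, scores = quality_check(st, **qc_kwargs)
        if verdict == "pass" and scores.mean() > best_score:
            best, best_score = i, float(scores.mean())
    return best
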