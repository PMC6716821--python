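"""Deterministic streamline tractography and tractwise metric statistics.

Fiber tracking runs on an averaged dataset: subject tensor fields in
template space are averaged componentwise, the mean tensor is
eigen-decomposed, and streamlines are integrated bidirectionally along
the trilinearly interpolated principal eigenvector with fixed step
length, stopping at an FA threshold (default 0.2), a turning-angle
limit, or the grid boundary.  Eigenvector sign ambiguity is handled by
aligning each contributing voxel's vector to the current propagation
direction before interpolation.

Tractwise fractional anisotropy statistics (TFAS) then averages any
scalar DTI metric per subject over the tract's voxel-occupancy mask
(a subject's voxels below the FA threshold are excluded from its
average) and compares groups with a two-sample t-test per timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .space import TemplateSpace
from .tensor import TensorField, metrics_from_eigenvalues

__all__ = [
    "DirectionField",
    "Tract",
    "average_dataset",
    "seeds_from_region",
    "track_streamlines",
    "select_tract",
    "tfas",
]


@dataclass
class DirectionField:
    """Principal eigenvector field (zero where FA < threshold) plus FA."""

    directions: np.ndarray            # (x, y, z, 3)
    fa: np.ndarray                    # (x, y, z)
    space: TemplateSpace
    fa_threshold: float = 0.2

    def __post_init__(self):
        norms = np.linalg.norm(self.directions, axis=-1)
        sub = self.fa < self.fa_threshold
        if np.any(norms[sub] > 0):
            raise ValueError("direction vectors must be zero below FA threshold")
        nz = norms > 0
        if np.any(np.abs(norms[nz] - 1.0) > 1e-6):
            raise ValueError("nonzero direction vectors must be unit length")


def average_dataset(
    tensor_comps: List[np.ndarray],
    space: TemplateSpace,
    fa_threshold: float = 0.2,
) -> DirectionField:
    """Voxelwise mean of subject tensor fields, then eigen-decomposition.

    ``tensor_comps`` holds per-subject (x, y, z, 6) lower-triangular
    component arrays in template space.
    """
    if len(tensor_comps) == 0:
        raise ValueError("cannot average an empty cohort")
    mean = np.mean([np.asarray(c, dtype=float) for c in tensor_comps], axis=0)
    f = TensorField(mean, s0=np.ones(mean.shape[:-1]),
                    valid=np.ones(mean.shape[:-1], dtype=bool))
    evals, evecs = f.eigensystem(clamp=True)
    fa = metrics_from_eigenvalues(evals)["FA"]
    dirs = evecs[..., :, 0].copy()
    dirs[fa < fa_threshold] = 0.0
    return DirectionField(dirs, fa, space, fa_threshold)


def seeds_from_region(field: DirectionField, region) -> np.ndarray:
    """Seed points (mm): centers of region voxels with FA >= threshold."""
    pts = field.space.voxel_center_grid()
    mask = region.contains(pts.reshape(-1, 3)).reshape(field.fa.shape)
    mask &= field.fa >= field.fa_threshold
    return pts[mask]


def _interp_direction(field: DirectionField, vox: np.ndarray,
                      prev_dir: np.ndarray) -> Tuple[np.ndarray, float]:
    """Trilinear interpolation of sign-aligned eigenvectors and FA at a
    continuous voxel coordinate; returns (direction, fa)."""
    base = np.floor(vox).astype(int)
    frac = vox - base
    shape = np.asarray(field.fa.shape)
    d_acc = np.zeros(3)
    fa_acc = 0.0
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                idx = base + (dx, dy, dz)
                if np.any(idx < 0) or np.any(idx >= shape):
                    continue
                w = ((frac[0] if dx else 1 - frac[0])
                     * (frac[1] if dy else 1 - frac[1])
                     * (frac[2] if dz else 1 - frac[2]))
                if w == 0:
                    continue
                v = field.directions[tuple(idx)]
                if v @ prev_dir < 0:
                    v = -v
                d_acc += w * v
                fa_acc += w * field.fa[tuple(idx)]
    norm = np.linalg.norm(d_acc)
    if norm > 0:
        d_acc = d_acc / norm
    return d_acc, fa_acc


def _integrate(field: DirectionField, start_mm: np.ndarray, d0: np.ndarray,
               step_mm: float, angle_max_deg: float, fa_stop: float,
               max_steps: int) -> List[np.ndarray]:
    space = field.space
    cos_max = np.cos(np.radians(angle_max_deg))
    pts = []
    x = start_mm.astype(float).copy()
    d = d0 / (np.linalg.norm(d0) + 1e-300)
    for _ in range(max_steps):
        vox = space.mm_to_voxel(x)
        hi = np.asarray(space.shape) - 1
        if np.any(vox < 0) or np.any(vox > hi):
            break
        nd, fa = _interp_direction(field, vox, d)
        if fa < fa_stop or np.linalg.norm(nd) == 0:
            break
        if nd @ d < cos_max:
            break
        x = x + step_mm * nd
        d = nd
        pts.append(x.copy())
    return pts


@dataclass
class Tract:
    """A streamline bundle with its voxel-occupancy mask."""

    streamlines: List[np.ndarray]     # each (n_points, 3) mm
    space: TemplateSpace
    seed_label: str = ""
    target_label: str = ""
    _mask: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def occupancy_mask(self) -> np.ndarray:
        """Voxels containing at least one streamline point."""
        if self._mask is None:
            m = np.zeros(self.space.shape, dtype=bool)
            hi = np.asarray(self.space.shape) - 1
            for sl in self.streamlines:
                vox = np.round(self.space.mm_to_voxel(sl)).astype(int)
                vox = np.clip(vox, 0, hi)
                m[vox[:, 0], vox[:, 1], vox[:, 2]] = True
            self._mask = m
        return self._mask

    def __len__(self) -> int:
        return len(self.streamlines)


def track_streamlines(
    field: DirectionField,
    seeds_mm: np.ndarray,
    step_mm: float = 0.025,
    angle_max_deg: float = 45.0,
    fa_stop: float = 0.2,
    min_length_mm: float = 0.5,
    max_steps: int = 10000,
) -> Tract:
    """Bidirectional deterministic streamline integration from each seed.

    From a seed the principal direction is followed in both
    orientations; the two half-lines are concatenated.  Streamlines
    shorter than ``min_length_mm`` are discarded.  Fully deterministic:
    identical field, seeds and parameters give identical streamlines.
    """
    seeds_mm = np.atleast_2d(np.asarray(seeds_mm, dtype=float))
    streamlines = []
    if seeds_mm.size == 0:
        return Tract([], field.space)
    for seed in seeds_mm:
        vox = field.space.mm_to_voxel(seed)
        hi = np.asarray(field.space.shape) - 1
        if np.any(vox < 0) or np.any(vox > hi):
            continue
        d0, fa = _interp_direction(field, vox, np.array([1.0, 0.0, 0.0]))
        if fa < fa_stop or np.linalg.norm(d0) == 0:
            continue
        fwd = _integrate(field, seed, d0, step_mm, angle_max_deg, fa_stop,
                         max_steps)
        bwd = _integrate(field, seed, -d0, step_mm, angle_max_deg, fa_stop,
                         max_steps)
        line = bwd[::-1] + [seed.copy()] + fwd
        if len(line) < 2:
            continue
        arr = np.asarray(line)
        length = float(np.sum(np.linalg.norm(np.diff(arr, axis=0), axis=1)))
        if length >= min_length_mm:
            streamlines.append(arr)
    return Tract(streamlines, field.space)


def select_tract(
    tract: Tract,
    must_pass: Sequence = (),
    endpoints: Optional[Tuple] = None,
) -> Tract:
    """Keep streamlines that traverse every ``must_pass`` region and,
    if ``endpoints`` is given, have one endpoint in each of the two
    regions (order-free)."""
    kept = []
    for sl in tract.streamlines:
        ok = all(np.any(r.contains(sl)) for r in must_pass)
        if ok and endpoints is not None:
            r1, r2 = endpoints
            e1, e2 = sl[0], sl[-1]
            ok = ((r1.contains(e1[None])[0] and r2.contains(e2[None])[0])
                  or (r2.contains(e1[None])[0] and r1.contains(e2[None])[0]))
        if ok:
            kept.append(sl)
    return Tract(kept, tract.space, tract.seed_label, tract.target_label)


def tfas(
    tract: Tract,
    subject_maps: Dict[Tuple[str, str], np.ndarray],
    subject_fa: Dict[Tuple[str, str], np.ndarray],
    manifest: pd.DataFrame,
    metric: str = "FA",
    fa_threshold: float = 0.2,
    equal_var: bool = True,
):
    """Tractwise statistics of one metric over a tract.

    Per subject-timepoint, the metric is averaged over occupancy-mask
    voxels where that subject's FA >= ``fa_threshold``; groups are then
    compared per timepoint with a two-sample t-test.  Returns
    ``(per_subject, group_tests)`` DataFrames; group tests carry means
    and SEM per group.
    """
    mask = tract.occupancy_mask
    if not np.any(mask):
        raise ValueError("tract occupancy mask is empty")
    rows = []
    inc = manifest[manifest["included"]]
    for r in inc.itertuples():
        key = (r.subject_id, r.timepoint)
        if key not in subject_maps:
            continue
        vox = mask & (np.asarray(subject_fa[key]) >= fa_threshold)
        value = float(np.mean(np.asarray(subject_maps[key])[vox])) if np.any(vox) else np.nan
        rows.append({"subject_id": r.subject_id, "genotype": r.genotype,
                     "timepoint": r.timepoint, "metric": metric,
                     "value": value})
    per_subject = pd.DataFrame(rows)

    tests = []
    for tp in sorted(per_subject.timepoint.unique()):
        sub = per_subject[per_subject.timepoint == tp].dropna(subset=["value"])
        a = sub[sub.genotype == "mutant"].value.to_numpy()
        b = sub[sub.genotype == "wildtype"].value.to_numpy()
        if len(a) >= 2 and len(b) >= 2:
            if np.var(a) == 0 and np.var(b) == 0:
                t, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
            else:
                t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        else:
            t, p = np.nan, np.nan
        tests.append({
            "timepoint": tp, "metric": metric,
            "mean_mutant": a.mean() if len(a) else np.nan,
            "sem_mutant": stats.sem(a) if len(a) > 1 else np.nan,
            "n_mutant": len(a),
            "mean_wildtype": b.mean() if len(b) else np.nan,
            "sem_wildtype": stats.sem(b) if len(b) > 1 else np.nan,
            "n_wildtype": len(b),
            "t": float(t), "p": float(p),
        })
    return per_subject, pd.DataFrame(tests)
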