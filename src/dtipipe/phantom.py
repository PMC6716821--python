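"""Synthetic DWI cohorts with known tensor-field ground truth.

The phantom emulates a two-genotype (wildtype / mutant), two-timepoint
(baseline / follow-up) longitudinal mouse study.  Anatomy is idealized:
an isotropic "parenchyma" background, two laterally placed mildly
anisotropic "cortex" boxes joined by a highly anisotropic midline
"corpus callosum" (CC) cylinder running along the sagittal axis, and a
separate descending "corticospinal tract" (CST) cylinder along the
horizontal axis.  A focal lesion — multiplicative perturbation of the
radial eigenvalues, so FA drops while RD and MD rise together — can be
restricted to one genotype at one timepoint, which encodes the
cortex/callosum-affected, CST-spared contrast the pipeline is meant to
detect.

Signal model per volume k: S_k = S0 * exp(-b_k g_k^T D g_k), corrupted
by Rician noise  S~ = sqrt((S + e1)^2 + e2^2),  e1, e2 ~ N(0, sigma^2),
the magnitude-MR noise law (upward-biased at low SNR).  Each scan gets
a small random rigid pose offset (within +-1 native voxel and +-3 deg
by default) so that stereotaxic normalization is exercised
non-trivially.  Lesions only perturb voxels inside anisotropic
structures: the model is microstructural damage to tissue, and an
eigenvalue perturbation of the isotropic background would not represent
anything physical.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .gradients import GradientScheme, default_scheme
from .space import Box, Cylinder, Sphere, TemplateSpace
from .tensor import DWIStack, metrics_from_eigenvalues, tensor_from_eigen

__all__ = [
    "Structure",
    "Lesion",
    "PhantomSpec",
    "GroundTruth",
    "simulate_subject",
    "simulate_cohort",
    "corrupt_with_motion",
    "atlas_landmarks",
]

GENOTYPES = ("wildtype", "mutant")
TIMEPOINTS = ("baseline", "followup")
BASE_DATE = datetime.date(2020, 1, 6)


@dataclass
class Structure:
    """An anisotropic tissue compartment: a region, its diffusion
    eigenvalues (mm^2/s, descending) and principal direction."""

    name: str
    region: object                    # Box | Cylinder | Sphere
    eigenvalues: Tuple[float, float, float]
    direction: Tuple[float, float, float]

    def __post_init__(self):
        lam = np.asarray(self.eigenvalues, dtype=float)
        if not (lam[0] >= lam[1] >= lam[2] > 0):
            raise ValueError(
                f"structure {self.name!r}: eigenvalues must satisfy "
                f"l1 >= l2 >= l3 > 0, got {tuple(lam)}"
            )


@dataclass
class Lesion:
    """Focal eigenvalue perturbation applied to one (genotype, timepoint)."""

    region: object
    genotype: str = "mutant"
    timepoint: str = "followup"
    factors: Tuple[float, float, float] = (1.0, 1.35, 1.25)

    def applies(self, genotype: str, timepoint: str) -> bool:
        return genotype == self.genotype and timepoint == self.timepoint


@dataclass
class PhantomSpec:
    """Everything needed to generate one synthetic cohort."""

    grid_shape: Tuple[int, int, int] = (96, 96, 40)
    voxel_size_um: Tuple[float, float, float] = (102.0, 102.0, 250.0)
    background_diffusivity: float = 0.7e-3       # mm^2/s, isotropic
    structures: List[Structure] = field(default_factory=list)
    lesions: List[Lesion] = field(default_factory=list)
    noise_sigma: float = 0.02                    # relative to S0 = 1
    s0: float = 1.0
    n_per_group: int = 9
    scan_interval_days: int = 150                # ~5 months
    scan_interval_jitter_days: int = 10
    jitter_translation_vox: float = 1.0          # per-scan rigid pose offset
    jitter_rotation_deg: float = 3.0
    scheme: Optional[GradientScheme] = None

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.background_diffusivity <= 0:
            raise ValueError("background diffusivity must be positive")
        if self.scheme is None:
            self.scheme = default_scheme()
        ext = self.extent_mm
        for les in self.lesions:
            c = _region_bbox_center(les.region)
            if np.any(np.abs(c) > ext / 2):
                raise ValueError("lesion region lies outside the grid")
            for st in self.structures:
                lam = np.asarray(st.eigenvalues) * np.asarray(les.factors)
                if not (lam[0] >= lam[1] >= lam[2] > 0):
                    raise ValueError(
                        f"lesion factors {les.factors} break eigenvalue "
                        f"ordering for structure {st.name!r}"
                    )

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.asarray(self.voxel_size_um, dtype=float) / 1000.0

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.grid_shape) * self.voxel_size_mm

    def voxel_centers_mm(self) -> np.ndarray:
        """(nx, ny, nz, 3) voxel-center coordinates, bregma at grid center."""
        axes = [
            (np.arange(n) - (n - 1) / 2) * d
            for n, d in zip(self.grid_shape, self.voxel_size_mm)
        ]
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)

    # -- default anatomy --------------------------------------------------
    @classmethod
    def default(cls, grid_shape=(96, 96, 40), **overrides) -> "PhantomSpec":
        """The standard phantom: cortex boxes + CC + CST, one focal
        FA-reducing lesion in the right cortex/callosum at follow-up in
        the mutant group.  Structure placement scales with grid extent."""
        spec = cls(grid_shape=grid_shape, **{k: v for k, v in overrides.items()
                                             if k not in ("structures", "lesions")})
        ex, ey, ez = spec.extent_mm
        r = 0.09 * min(ex, ey)
        cc_evals = (1.7e-3, 0.3e-3, 0.3e-3)
        ctx_evals = (1.0e-3, 0.55e-3, 0.45e-3)
        sag = (0.0, 0.0, 1.0)
        structures = [
            Structure("cortex_left", Box((0.0, -0.1 * ey, -0.38 * ez),
                                         (0.20 * ex, 0.15 * ey, 0.10 * ez)),
                      ctx_evals, sag),
            Structure("cortex_right", Box((0.0, -0.1 * ey, 0.38 * ez),
                                          (0.20 * ex, 0.15 * ey, 0.10 * ez)),
                      ctx_evals, sag),
            Structure("cc", Cylinder((0.0, -0.1 * ey, -0.36 * ez),
                                     (0.0, -0.1 * ey, 0.36 * ez), r),
                      cc_evals, sag),
            Structure("cst", Cylinder((0.25 * ex, -0.35 * ey, 0.0),
                                      (0.25 * ex, 0.35 * ey, 0.0), r),
                      cc_evals, (0.0, 1.0, 0.0)),
        ]
        lesions = overrides.get(
            "lesions",
            [Lesion(Sphere((0.0, -0.1 * ey, 0.33 * ez), 0.20 * ez))],
        )
        spec.structures = overrides.get("structures", structures)
        spec.lesions = []
        validated = replace(spec, structures=spec.structures, lesions=lesions)
        return validated

    # -- ground-truth masks on arbitrary grids ----------------------------
    def structure_union_mask(self, points_mm: np.ndarray) -> np.ndarray:
        m = np.zeros(points_mm.shape[:-1], dtype=bool)
        for st in self.structures:
            m |= st.region.contains(points_mm)
        return m

    def lesion_mask(self, points_mm: np.ndarray) -> np.ndarray:
        """Voxels whose microstructure a lesion perturbs (lesion region
        intersected with anisotropic tissue)."""
        m = np.zeros(points_mm.shape[:-1], dtype=bool)
        for les in self.lesions:
            m |= les.region.contains(points_mm)
        return m & self.structure_union_mask(points_mm)

    def lesion_mask_template(self, space: TemplateSpace) -> np.ndarray:
        return self.lesion_mask(space.voxel_center_grid())


def _region_bbox_center(region) -> np.ndarray:
    if isinstance(region, Box):
        return np.asarray(region.center, dtype=float)
    if isinstance(region, Sphere):
        return np.asarray(region.center, dtype=float)
    if isinstance(region, Cylinder):
        return (np.asarray(region.p0, dtype=float)
                + np.asarray(region.p1, dtype=float)) / 2
    raise TypeError(f"unsupported region type {type(region)}")


@dataclass
class GroundTruth:
    """Per-subject-scan generating truth: eigenvalues, principal
    directions, ideal metric maps, lesion mask and the rigid pose."""

    eigenvalues: np.ndarray            # (x, y, z, 3) descending
    principal_direction: np.ndarray    # (x, y, z, 3)
    tensors: np.ndarray                # (x, y, z, 6) lower-tri comps
    metrics: dict                      # name -> (x, y, z) ideal values
    lesion_mask: np.ndarray            # (x, y, z) bool, subject space
    tissue_mask: np.ndarray            # union of structures, subject space
    rotation: np.ndarray               # 3x3, atlas -> subject
    translation_mm: np.ndarray         # (3,)

    def subject_landmarks(self, atlas_points_mm: np.ndarray) -> np.ndarray:
        return atlas_points_mm @ self.rotation.T + self.translation_mm


def atlas_landmarks(spec: PhantomSpec) -> np.ndarray:
    """Eight non-coplanar landmark points (box corners at 30% extent)."""
    e = spec.extent_mm
    corners = np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)],
        dtype=float,
    )
    return corners * (0.3 * e)


def _rotation_matrix(angles_deg: np.ndarray) -> np.ndarray:
    ax, ay, az = np.radians(np.asarray(angles_deg, dtype=float))
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rx @ ry @ rz


def _comps_from_matrix(m: np.ndarray) -> np.ndarray:
    return np.array([m[0, 0], m[1, 1], m[2, 2], m[0, 1], m[0, 2], m[1, 2]])


def simulate_subject(
    spec: PhantomSpec,
    genotype: str,
    timepoint: str,
    rng: np.random.Generator,
    subject_id: str = "",
    scan_date: Optional[datetime.date] = None,
    jitter: bool = True,
) -> Tuple[DWIStack, GroundTruth]:
    """Render one subject-timepoint DWI stack plus its generating truth.

    The anatomy is posed with a per-scan random rigid transform
    (disabled with ``jitter=False`` or zero jitter amplitudes in the
    spec); lesions are applied only when (genotype, timepoint) matches.
    """
    if genotype not in GENOTYPES or timepoint not in TIMEPOINTS:
        raise ValueError(f"unknown genotype/timepoint {genotype!r}/{timepoint!r}")
    scheme = spec.scheme

    if jitter and (spec.jitter_translation_vox or spec.jitter_rotation_deg):
        t = rng.uniform(-1, 1, 3) * spec.jitter_translation_vox * spec.voxel_size_mm
        ang = rng.uniform(-1, 1, 3) * spec.jitter_rotation_deg
        R = _rotation_matrix(ang)
    else:
        t = np.zeros(3)
        R = np.eye(3)

    pts = spec.voxel_centers_mm()                       # subject-space coords
    atlas_pts = (pts - t) @ R                           # R^-1 = R^T column action

    shape = tuple(spec.grid_shape)
    evals = np.full(shape + (3,), spec.background_diffusivity)
    dirs = np.zeros(shape + (3,))
    comps = np.zeros(shape + (6,))
    iso = _comps_from_matrix(np.eye(3) * spec.background_diffusivity)
    comps[:] = iso
    tissue = np.zeros(shape, dtype=bool)

    active = [l for l in spec.lesions if l.applies(genotype, timepoint)]
    lesion_vox = np.zeros(shape, dtype=bool)
    for les in active:
        lesion_vox |= les.region.contains(atlas_pts)

    for st in spec.structures:
        inside = st.region.contains(atlas_pts)
        tissue |= inside
        d_sub = R @ np.asarray(st.direction, dtype=float)
        base = _comps_from_matrix(
            R @ tensor_from_eigen(st.eigenvalues, st.direction) @ R.T
        )
        evals[inside] = st.eigenvalues
        dirs[inside] = d_sub
        comps[inside] = base
        for les in active:
            hit = inside & les.region.contains(atlas_pts)
            if np.any(hit):
                lam = np.asarray(st.eigenvalues) * np.asarray(les.factors)
                evals[hit] = lam
                comps[hit] = _comps_from_matrix(
                    R @ tensor_from_eigen(lam, st.direction) @ R.T
                )
    lesion_vox &= tissue

    # noise-free signal: exponent column k = b_k g_k^T D g_k
    g, b = scheme.bvecs, scheme.bvals
    design = b[:, None] * np.column_stack(
        [g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
         2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2]]
    )                                                   # (n_vol, 6)
    expo = comps.reshape(-1, 6) @ design.T              # (n_vox, n_vol)
    signal = spec.s0 * np.exp(-expo)
    if spec.noise_sigma > 0:
        e1 = rng.normal(0.0, spec.noise_sigma, signal.shape)
        e2 = rng.normal(0.0, spec.noise_sigma, signal.shape)
        signal = np.sqrt((signal + e1) ** 2 + e2**2)
    data = signal.reshape(shape + (scheme.n_volumes,))

    stack = DWIStack(data, spec.voxel_size_um, scheme,
                     subject_id=subject_id, timepoint=timepoint,
                     scan_date=scan_date)
    truth = GroundTruth(
        eigenvalues=evals,
        principal_direction=dirs,
        tensors=comps,
        metrics=metrics_from_eigenvalues(evals),
        lesion_mask=lesion_vox,
        tissue_mask=tissue,
        rotation=R,
        translation_mm=t,
    )
    return stack, truth


def simulate_cohort(spec: PhantomSpec, master_seed: int):
    """Generate the full 2 genotypes x 2 timepoints x n_per_group design.

    Returns ``(manifest, stacks, truths)`` where ``manifest`` is a
    DataFrame with one row per scan and ``stacks`` / ``truths`` are
    dicts keyed by ``(subject_id, timepoint)``.
    """
    if spec.n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    rng = np.random.default_rng(master_seed)
    rows, stacks, truths = [], {}, {}
    for genotype in GENOTYPES:
        tag = "wt" if genotype == "wildtype" else "mut"
        for i in range(spec.n_per_group):
            sid = f"{tag}{i + 1:02d}"
            base = BASE_DATE + datetime.timedelta(days=int(rng.integers(0, 14)))
            jit = int(rng.integers(-spec.scan_interval_jitter_days,
                                   spec.scan_interval_jitter_days + 1))
            dates = {
                "baseline": base,
                "followup": base + datetime.timedelta(
                    days=spec.scan_interval_days + jit),
            }
            for tp in TIMEPOINTS:
                stack, truth = simulate_subject(
                    spec, genotype, tp, rng, subject_id=sid,
                    scan_date=dates[tp])
                stacks[(sid, tp)] = stack
                truths[(sid, tp)] = truth
                rows.append({
                    "subject_id": sid,
                    "genotype": genotype,
                    "timepoint": tp,
                    "scan_date": dates[tp].isoformat(),
                    "dwi_path": "",
                    "included": True,
                })
    manifest = pd.DataFrame(rows)
    return manifest, stacks, truths


def corrupt_with_motion(
    stack: DWIStack, n_bad_volumes: int, rng: np.random.Generator
) -> Tuple[DWIStack, np.ndarray]:
    """Inject motion artefacts into ``n_bad_volumes`` diffusion-weighted
    volumes: a rigid in-plane displacement of >= 2 native voxels plus a
    slab of dropped-intensity slices.  Returns the corrupted stack and
    the affected volume indices (for validating quality control)."""
    dw_idx = np.flatnonzero(stack.scheme.dw_mask)
    if not 0 <= n_bad_volumes < len(dw_idx):
        raise ValueError("n_bad_volumes must lie in [0, number of DW volumes)")
    data = stack.data.copy()
    bad = rng.choice(dw_idx, size=n_bad_volumes, replace=False)
    for k in bad:
        shift = rng.choice([-3, -2, 2, 3], size=2)
        vol = np.roll(data[..., k], shift=tuple(shift), axis=(0, 1))
        nz = data.shape[2]
        z0 = int(rng.integers(0, max(nz - max(nz // 5, 1), 1)))
        vol[:, :, z0:z0 + max(nz // 5, 1)] *= 0.3
        data[..., k] = vol
    out = DWIStack(data, stack.voxel_size_um, stack.scheme,
                   subject_id=stack.subject_id, timepoint=stack.timepoint,
                   scan_date=stack.scan_date)
    return out, np.sort(bad)
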