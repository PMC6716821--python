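"""Stereotaxic template space and geometric region primitives.

Axis convention used throughout the package: array axis 0 is the
coronal (rostro-caudal) stereotaxic axis, axis 1 the horizontal
(dorso-ventral) axis and axis 2 the sagittal (left-right) axis.
Stereotaxic millimetre coordinates are offsets of voxel centers from
the bregma voxel, positive along increasing array index (the sign of
the sagittal axis therefore distinguishes hemispheres: +sagittal is the
"right" side).  Cluster peaks and ROI centers are reported as
(coronal, horizontal, sagittal) mm triples relative to bregma.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "TemplateSpace",
    "Box",
    "Cylinder",
    "Sphere",
]


@dataclass
class TemplateSpace:
    """An isotropic analysis grid with a bregma-anchored mm coordinate frame.

    Parameters
    ----------
    shape : (3,) ints
        Grid dimensions in voxels.
    spacing_mm : float
        Isotropic voxel spacing (default 0.05 mm = 50 um).
    bregma_voxel : (3,) floats, optional
        Voxel coordinate of bregma; defaults to the grid center
        ``(shape - 1) / 2`` so that the center voxel maps to (0, 0, 0) mm.
    b0_template, fa_template : 3-D arrays, optional
        Study-specific templates living on this grid.
    """

    shape: tuple
    spacing_mm: float = 0.05
    bregma_voxel: Optional[np.ndarray] = None
    b0_template: Optional[np.ndarray] = None
    fa_template: Optional[np.ndarray] = None

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be positive")
        if self.bregma_voxel is None:
            self.bregma_voxel = (np.asarray(self.shape, dtype=float) - 1) / 2
        else:
            self.bregma_voxel = np.asarray(self.bregma_voxel, dtype=float)
        if self.fa_template is not None:
            fa = np.asarray(self.fa_template)
            if fa.min() < 0 or fa.max() > 1:
                raise ValueError("FA template values must lie in [0, 1]")

    # -- coordinate transforms -------------------------------------------
    def voxel_to_mm(self, voxels: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices to stereotaxic mm (voxel centers)."""
        v = np.asarray(voxels, dtype=float)
        return (v - self.bregma_voxel) * self.spacing_mm

    def mm_to_voxel(self, mm: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`voxel_to_mm` (continuous voxel coordinates)."""
        return np.asarray(mm, dtype=float) / self.spacing_mm + self.bregma_voxel

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> mm affine (for NIfTI headers)."""
        a = np.eye(4)
        a[:3, :3] = np.eye(3) * self.spacing_mm
        a[:3, 3] = -self.bregma_voxel * self.spacing_mm
        return a

    def voxel_center_grid(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of stereotaxic mm coordinates of all voxels."""
        idx = np.stack(
            np.meshgrid(*[np.arange(s) for s in self.shape], indexing="ij"),
            axis=-1,
        )
        return self.voxel_to_mm(idx)

    def contains_mm(self, mm: np.ndarray) -> np.ndarray:
        v = self.mm_to_voxel(mm)
        hi = np.asarray(self.shape) - 1
        return np.all((v >= -0.5) & (v <= hi + 0.5), axis=-1)


# -- region primitives (mm coordinates, bregma-relative) -----------------

@dataclass
class Box:
    center: Sequence[float]
    half_sizes: Sequence[float]

    def contains(self, points_mm: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points_mm, dtype=float))
        d = np.abs(p - np.asarray(self.center, dtype=float))
        out = np.all(d <= np.asarray(self.half_sizes, dtype=float), axis=-1)
        return out.reshape(np.asarray(points_mm).shape[:-1])


@dataclass
class Sphere:
    center: Sequence[float]
    radius: float

    def contains(self, points_mm: np.ndarray) -> np.ndarray:
        p = np.asarray(points_mm, dtype=float)
        d2 = np.sum((p - np.asarray(self.center, dtype=float)) ** 2, axis=-1)
        return d2 <= self.radius**2


@dataclass
class Cylinder:
    """Finite cylinder from p0 to p1 with the given radius."""

    p0: Sequence[float]
    p1: Sequence[float]
    radius: float

    def __post_init__(self):
        self._p0 = np.asarray(self.p0, dtype=float)
        self._p1 = np.asarray(self.p1, dtype=float)
        axis = self._p1 - self._p0
        self._len = float(np.linalg.norm(axis))
        if self._len == 0:
            raise ValueError("cylinder endpoints coincide")
        self._axis = axis / self._len

    @property
    def axis(self) -> np.ndarray:
        return self._axis

    def contains(self, points_mm: np.ndarray) -> np.ndarray:
        p = np.asarray(points_mm, dtype=float)
        rel = p - self._p0
        t = rel @ self._axis
        radial = rel - t[..., None] * self._axis
        r2 = np.sum(radial**2, axis=-1)
        return (t >= 0) & (t <= self._len) & (r2 <= self.radius**2)


def region_mask(region, space: TemplateSpace) -> np.ndarray:
    """Boolean voxel mask of a region on a template grid (voxel centers)."""
    pts = space.voxel_center_grid()
    return region.contains(pts.reshape(-1, 3)).reshape(space.shape)
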