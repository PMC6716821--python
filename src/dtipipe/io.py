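"""Readers and writers for the standard formats the pipeline touches.

Volumes are NIfTI-1; gradient tables are FSL-dialect bval/bvec (bval:
one whitespace-separated line, bvec: 3 rows x N columns); streamlines
are TrackVis TRK or MRtrix TCK; tables (manifest, landmarks, ROI specs)
are TSV; statistics outputs are CSV.  No scientific computation lives
here.

NIfTI affines follow the package convention: voxel indices are 0-based,
coordinates refer to voxel centers, and the origin sits at bregma
(volume center for native scans).
"""

from __future__ import annotations

import datetime
import logging
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd

from .gradients import GradientScheme
from .normalize import native_voxel_to_mm_offset
from .space import TemplateSpace
from .tensor import DWIStack
from .tracking import Tract
from .wbss import ClusterTable

logger = logging.getLogger("dtipipe")

__all__ = [
    "read_dwi", "write_dwi",
    "read_manifest", "write_manifest", "validate_manifest",
    "write_cluster_table", "read_cluster_table",
    "write_streamlines", "read_streamlines",
    "read_landmarks", "write_landmarks",
    "read_roi_specs",
    "write_metric_nifti", "read_metric_nifti",
]


# ---------------------------------------------------------------------------
# DWI volumes + gradient tables

def _native_affine(shape, voxel_size_mm) -> np.ndarray:
    a = np.eye(4)
    a[:3, :3] = np.diag(voxel_size_mm)
    a[:3, 3] = -native_voxel_to_mm_offset(shape) * voxel_size_mm
    return a


def read_dwi(path, bval_path, bvec_path) -> DWIStack:
    """Load a 4-D NIfTI plus FSL bval/bvec into a :class:`DWIStack`.

    Raises on a volume-count / gradient-table mismatch, naming both
    counts.  Gradient directions are normalized to unit length (zero
    vectors kept for b = 0 entries).
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D volume, got {data.ndim}-D")
    bvals = np.loadtxt(str(bval_path), ndmin=1).ravel()
    bvecs = np.loadtxt(str(bvec_path), ndmin=2)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        bvecs = bvecs.T            # FSL stores 3 rows x N columns
    if len(bvals) != data.shape[3]:
        raise ValueError(
            f"{path}: volume count {data.shape[3]} does not match "
            f"gradient table with {len(bvals)} entries"
        )
    if bvecs.shape != (len(bvals), 3):
        raise ValueError(
            f"{bvec_path}: expected 3 x {len(bvals)} directions, got "
            f"{bvecs.T.shape}"
        )
    zooms = img.header.get_zooms()[:3]
    scheme = GradientScheme(bvecs, bvals)
    return DWIStack(data, tuple(z * 1000.0 for z in zooms), scheme)


def write_dwi(stack: DWIStack, path, bval_path, bvec_path) -> Path:
    """Write NIfTI + FSL bval/bvec; inverse of :func:`read_dwi`."""
    affine = _native_affine(stack.shape, stack.voxel_size_mm)
    img = nib.Nifti1Image(stack.data.astype(np.float32), affine)
    img.header.set_zooms(tuple(stack.voxel_size_mm) + (1.0,))
    nib.save(img, str(path))
    np.savetxt(str(bval_path), stack.scheme.bvals[None], fmt="%.1f")
    np.savetxt(str(bvec_path), stack.scheme.bvecs.T, fmt="%.8f")
    return Path(path)


# ---------------------------------------------------------------------------
# cohort manifest

MANIFEST_COLUMNS = ["subject_id", "genotype", "timepoint", "scan_date",
                    "dwi_path", "included"]


def validate_manifest(df: pd.DataFrame, check_paths: bool = False) -> pd.DataFrame:
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    bad_gt = set(df.genotype) - {"mutant", "wildtype"}
    if bad_gt:
        raise ValueError(f"unknown genotype labels: {sorted(bad_gt)}")
    bad_tp = set(df.timepoint) - {"baseline", "followup"}
    if bad_tp:
        raise ValueError(f"unknown timepoint labels: {sorted(bad_tp)}")
    dup = df.duplicated(subset=["subject_id", "timepoint"])
    if dup.any():
        raise ValueError(
            f"duplicate subject/timepoint rows: "
            f"{df.loc[dup, ['subject_id', 'timepoint']].to_dict('records')}"
        )
    for d in df.scan_date:
        datetime.date.fromisoformat(str(d))
    if check_paths:
        for r in df[df.included].itertuples():
            img = nib.load(str(r.dwi_path))
            if len(img.shape) != 4:
                raise ValueError(f"{r.dwi_path}: not a 4-D volume")
    return df


def read_manifest(path, check_paths: bool = False) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    df["included"] = df["included"].astype(bool)
    df["dwi_path"] = df["dwi_path"].fillna("").astype(str)
    return validate_manifest(df, check_paths=check_paths)


def write_manifest(df: pd.DataFrame, path) -> Path:
    validate_manifest(df)
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


# ---------------------------------------------------------------------------
# cluster tables

CLUSTER_COLUMNS = ["id", "size_voxels", "bregma_cor", "bregma_hor",
                   "bregma_sag", "p", "mean_t", "label"]


def write_cluster_table(clusters: ClusterTable, path,
                        config_hash: Optional[str] = None) -> Path:
    """CSV in the standard report format: one row per cluster, sorted by
    descending size, peak coordinates as bregma-relative mm."""
    path = Path(path)
    df = clusters.df[CLUSTER_COLUMNS].sort_values(
        "size_voxels", ascending=False)
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# dtipipe config={config_hash}\n")
        df.to_csv(fh, index=False, float_format="%.6g")
    return path


def read_cluster_table(path) -> ClusterTable:
    df = pd.read_csv(path, comment="#")
    return ClusterTable(df=df)


# ---------------------------------------------------------------------------
# streamlines

def write_streamlines(tract: Tract, path, fmt: str = "trk") -> Path:
    """Write a tract as TrackVis TRK (default) or MRtrix TCK.

    Point coordinates are template-space mm; the TRK header records the
    template grid's voxel size, dimensions and voxel-to-mm affine so
    read-back reproduces coordinates within float tolerance.
    """
    path = Path(path)
    if len(tract) == 0:
        logger.warning("writing empty tract to %s", path)
    tractogram = nib.streamlines.Tractogram(
        [s.astype(np.float32) for s in tract.streamlines],
        affine_to_rasmm=np.eye(4),
    )
    space = tract.space
    if fmt == "trk":
        header = {
            "voxel_sizes": (np.float32(space.spacing_mm),) * 3,
            "dimensions": space.shape,
            "voxel_to_rasmm": space.affine.astype(np.float32),
            "voxel_order": "RAS",
        }
        nib.streamlines.save(tractogram, str(path), header=header)
    elif fmt == "tck":
        nib.streamlines.save(nib.streamlines.tck.TckFile(tractogram), str(path))
    else:
        raise ValueError("fmt must be 'trk' or 'tck'")
    return path


def read_streamlines(path, space: TemplateSpace) -> Tract:
    obj = nib.streamlines.load(str(path))
    sls = [np.asarray(s, dtype=float) for s in obj.tractogram.streamlines]
    return Tract(sls, space)


# ---------------------------------------------------------------------------
# landmarks and ROI specs

def read_landmarks(path) -> pd.DataFrame:
    """TSV with columns (name, x, y, z), coordinates in mm."""
    df = pd.read_csv(path, sep="\t")
    need = {"name", "x", "y", "z"}
    if not need <= set(df.columns):
        raise ValueError(f"landmark file needs columns {sorted(need)}")
    return df


def write_landmarks(names, points_mm, path) -> Path:
    pts = np.asarray(points_mm, dtype=float)
    df = pd.DataFrame({"name": list(names), "x": pts[:, 0],
                       "y": pts[:, 1], "z": pts[:, 2]})
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_roi_specs(path):
    """TSV with columns (name, cor, hor, sag, radius_mm, side)."""
    from .roistats import ROISpec

    df = pd.read_csv(path, sep="\t")
    need = {"name", "cor", "hor", "sag", "radius_mm", "side"}
    if not need <= set(df.columns):
        raise ValueError(f"ROI spec file needs columns {sorted(need)}")
    return [
        ROISpec(r.name, (r.cor, r.hor, r.sag), r.radius_mm, r.side)
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# scalar maps

def write_metric_nifti(values: np.ndarray, space: TemplateSpace, path) -> Path:
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float32), space.affine)
    nib.save(img, str(path))
    return Path(path)


def read_metric_nifti(path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.affine
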