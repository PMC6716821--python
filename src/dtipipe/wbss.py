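"""Whole brain-based spatial statistics (WBSS).

Normalized metric maps are smoothed with a 200 um FWHM Gaussian,
compared voxelwise with Student's t-test inside an FA >= 0.2 template
mask, corrected for multiple comparisons with the Benjamini-Hochberg
false-discovery-rate procedure at q = 0.05, and finally thresholded at
a minimum cluster size of 256 voxels (26-connectivity) — the spatial
correction in the size range of the smoothing kernel.

Longitudinal change is expressed per metric DM as the per-day rate

    dDM = (DM(t1) - DM(t2)) / (t1 - t2) * 1 day

with t1, t2 the baseline and follow-up scan dates, so that cohorts with
slightly different scan intervals are compared on a common scale.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .space import TemplateSpace
from .tensor import MetricMap

__all__ = [
    "StatMap",
    "ClusterTable",
    "smooth_map",
    "voxelwise_ttest",
    "delta_map",
    "fdr_correct",
    "cluster_filter",
    "run_wbss",
    "CONTRASTS",
]

CONTRASTS = {
    "a": "cross-sectional mutant vs wildtype at baseline",
    "b": "cross-sectional mutant vs wildtype at follow-up",
    "c": "mutant follow-up vs baseline (paired)",
    "d": "longitudinal per-day change, mutant vs wildtype",
}


@dataclass
class StatMap:
    t: np.ndarray
    p: np.ndarray
    mask: np.ndarray
    contrast: str
    metric: str
    df: int


@dataclass
class ClusterTable:
    """Suprathreshold clusters, sorted by descending size."""

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["id", "size_voxels", "bregma_cor", "bregma_hor",
                 "bregma_sag", "p", "mean_t", "label"]))
    labels: Optional[np.ndarray] = None     # labeled volume, 0 = background

    def __len__(self) -> int:
        return len(self.df)


def smooth_map(
    values: np.ndarray,
    spacing_mm: float,
    fwhm_mm: float,
    mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Gaussian smoothing, sigma = FWHM / (2 sqrt(2 ln 2)).

    With a mask, a normalized (masked) convolution excludes off-mask
    voxels and renormalizes the kernel weights, so edge voxels are not
    diluted by zeros; output is defined on the mask only.
    """
    if fwhm_mm <= 0:
        raise ValueError("FWHM must be positive")
    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / spacing_mm
    v = np.asarray(values, dtype=float)
    if mask is None:
        return ndimage.gaussian_filter(v, sigma_vox, mode="nearest")
    m = mask.astype(float)
    num = ndimage.gaussian_filter(v * m, sigma_vox, mode="constant")
    den = ndimage.gaussian_filter(m, sigma_vox, mode="constant")
    out = np.zeros_like(v)
    inside = mask & (den > 1e-12)
    out[inside] = num[inside] / den[inside]
    return out


def _two_sample_t(a: np.ndarray, b: np.ndarray, equal_var: bool):
    """Vectorized two-sample t over axis 0; returns (t, p, df-like)."""
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    if equal_var:
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        dfs = np.full(ma.shape, float(df))
    else:
        se2a, se2b = va / na, vb / nb
        denom = np.sqrt(se2a + se2b)
        with np.errstate(divide="ignore", invalid="ignore"):
            dfs = (se2a + se2b) ** 2 / (
                se2a**2 / (na - 1) + se2b**2 / (nb - 1)
            )
        dfs = np.where(np.isfinite(dfs), dfs, na + nb - 2)
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
    # zero-variance voxels: equal means -> t = 0, p = 1; unequal -> +-inf
    zero = denom == 0
    t = np.where(zero & (diff == 0), 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), dfs)
    p = np.where(np.isinf(t), 0.0, p)
    p = np.where(zero & (diff == 0), 1.0, p)
    return t, p, dfs


def voxelwise_ttest(
    group_a: List[np.ndarray],
    group_b: List[np.ndarray],
    mask: np.ndarray,
    equal_var: bool = True,
    paired: bool = False,
    contrast: str = "",
    metric: str = "FA",
) -> StatMap:
    """Two-sided voxelwise Student t-test of group A vs group B on a mask.

    ``paired=True`` treats the two lists as matched per-subject pairs
    (one-sample t-test on the differences).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 maps")
    A = np.stack([np.asarray(m)[mask] for m in group_a])
    B = np.stack([np.asarray(m)[mask] for m in group_b])
    if paired:
        if A.shape[0] != B.shape[0]:
            raise ValueError("paired test requires equal group sizes")
        D = A - B
        n = D.shape[0]
        sd = D.std(axis=0, ddof=1)
        mean = D.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / (sd / np.sqrt(n))
        t = np.where((sd == 0) & (mean == 0), 0.0, t)
        df = n - 1
        p = 2.0 * stats.t.sf(np.abs(t), df)
        p = np.where(np.isinf(t), 0.0, p)
        p = np.where((sd == 0) & (mean == 0), 1.0, p)
    else:
        t, p, dfs = _two_sample_t(A, B, equal_var)
        df = int(A.shape[0] + B.shape[0] - 2)
    t_map = np.zeros(mask.shape)
    p_map = np.ones(mask.shape)
    t_map[mask] = t
    p_map[mask] = p
    return StatMap(t=t_map, p=p_map, mask=mask, contrast=contrast,
                   metric=metric, df=int(df))


def delta_map(
    baseline: np.ndarray,
    followup: np.ndarray,
    t1: datetime.date,
    t2: datetime.date,
) -> np.ndarray:
    """Per-day longitudinal change: (DM(t1) - DM(t2)) / (t1 - t2) * 1 d."""
    if t1 == t2:
        raise ValueError("baseline and follow-up dates must differ")
    days = (t1 - t2).days if hasattr(t1 - t2, "days") else float(t1 - t2)
    return (np.asarray(baseline, dtype=float)
            - np.asarray(followup, dtype=float)) / days


def fdr_correct(p: np.ndarray, q: float, mask: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up over all mask voxels.

    Returns a boolean rejection field of the mask's shape.
    """
    reject = np.zeros(mask.shape, dtype=bool)
    pv = np.asarray(p, dtype=float)[mask]
    if pv.size == 0:
        return reject
    reject[mask] = multipletests(pv, alpha=q, method="fdr_bh")[0]
    return reject


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError("connectivity must be 6 or 26")


def cluster_filter(
    reject: np.ndarray,
    min_size: int,
    space: Optional[TemplateSpace] = None,
    p: Optional[np.ndarray] = None,
    t: Optional[np.ndarray] = None,
    connectivity: int = 26,
) -> ClusterTable:
    """Connected-component filtering of a rejection field.

    Components smaller than ``min_size`` voxels are discarded; survivors
    are reported with size, peak (minimum-p) voxel in stereotaxic mm,
    minimum p and mean t, sorted by descending size.
    """
    labels, n = ndimage.label(reject, structure=_connectivity_structure(connectivity))
    rows = []
    keep = np.zeros_like(labels)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    new_id = 0
    order = np.argsort(sizes)[::-1]
    for comp in order:
        size = int(sizes[comp])
        if size < min_size:
            continue
        new_id += 1
        comp_mask = labels == comp + 1
        keep[comp_mask] = new_id
        if p is not None:
            pv = np.where(comp_mask, p, np.inf)
            peak = np.unravel_index(np.argmin(pv), pv.shape)
            min_p = float(p[peak])
        else:
            idx = np.argwhere(comp_mask)
            peak = tuple(idx[0])
            min_p = np.nan
        mean_t = float(np.mean(t[comp_mask])) if t is not None else np.nan
        mm = (space.voxel_to_mm(np.asarray(peak)) if space is not None
              else np.full(3, np.nan))
        rows.append({
            "id": new_id,
            "size_voxels": size,
            "bregma_cor": float(mm[0]),
            "bregma_hor": float(mm[1]),
            "bregma_sag": float(mm[2]),
            "p": min_p,
            "mean_t": mean_t,
            "label": "",
        })
    df = pd.DataFrame(rows, columns=["id", "size_voxels", "bregma_cor",
                                     "bregma_hor", "bregma_sag", "p",
                                     "mean_t", "label"])
    return ClusterTable(df=df, labels=keep)


def run_wbss(
    manifest: pd.DataFrame,
    maps: Dict[Tuple[str, str], np.ndarray],
    space: TemplateSpace,
    metric: str,
    contrast: str,
    config: PipelineConfig,
    presmoothed: bool = False,
) -> Tuple[StatMap, ClusterTable]:
    """Dispatch one of the four pre-specified analyses.

    Contrasts: ``a`` mutant vs wildtype at baseline, ``b`` mutant vs
    wildtype at follow-up, ``c`` mutant follow-up vs baseline (paired by
    subject), ``d`` per-day change (dDM) mutant vs wildtype.  ``maps``
    holds template-space metric maps keyed by (subject_id, timepoint).
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; pick from {sorted(CONTRASTS)}")
    if space.fa_template is None:
        raise ValueError("template space carries no FA template for masking")
    mask = space.fa_template >= config.fa_threshold
    inc = manifest[manifest["included"]]

    def smoothed(key):
        m = maps[key]
        if presmoothed:
            return m
        return smooth_map(m, space.spacing_mm, config.smoothing_fwhm_mm, mask=mask)

    def subjects(genotype, timepoint):
        sel = inc[(inc.genotype == genotype) & (inc.timepoint == timepoint)]
        return list(sel.subject_id)

    def dates(genotype):
        rows = inc[inc.genotype == genotype]
        return {
            (r.subject_id, r.timepoint): datetime.date.fromisoformat(str(r.scan_date))
            for r in rows.itertuples()
        }

    paired = config.paired_longitudinal
    if contrast in ("a", "b"):
        tp = "baseline" if contrast == "a" else "followup"
        A = [smoothed((s, tp)) for s in subjects("mutant", tp)]
        B = [smoothed((s, tp)) for s in subjects("wildtype", tp)]
        stat = voxelwise_ttest(A, B, mask, equal_var=config.equal_variance_ttest,
                               contrast=contrast, metric=metric)
    elif contrast == "c":
        both = sorted(set(subjects("mutant", "baseline"))
                      & set(subjects("mutant", "followup")))
        A = [smoothed((s, "followup")) for s in both]
        B = [smoothed((s, "baseline")) for s in both]
        stat = voxelwise_ttest(A, B, mask, equal_var=config.equal_variance_ttest,
                               paired=paired, contrast=contrast, metric=metric)
    else:  # "d"
        groups = {}
        for genotype in ("mutant", "wildtype"):
            dd = dates(genotype)
            both = sorted(set(subjects(genotype, "baseline"))
                          & set(subjects(genotype, "followup")))
            groups[genotype] = [
                delta_map(smoothed((s, "baseline")), smoothed((s, "followup")),
                          dd[(s, "baseline")], dd[(s, "followup")])
                for s in both
            ]
        stat = voxelwise_ttest(groups["mutant"], groups["wildtype"], mask,
                               equal_var=config.equal_variance_ttest,
                               contrast=contrast, metric=metric)

    reject = fdr_correct(stat.p, config.fdr_q, mask)
    table = cluster_filter(reject, config.cluster_min_voxels, space=space,
                           p=stat.p, t=stat.t,
                           connectivity=config.cluster_connectivity)
    return stat, table
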