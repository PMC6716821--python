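"""Hypothesis-guided spherical ROI analysis and histology statistics.

ROIs are spheres in stereotaxic (coronal, horizontal, sagittal) mm
coordinates relative to bregma; ``side='bilateral'`` takes the union of
the sphere and its sagittal mirror image.  The mean of a metric map
over the voxels whose centers fall inside the ROI is the per-subject
summary.

The histology analysis is a 2 x 2 (genotype x age) between-subjects
ANOVA with Type III (contrast-based) sums of squares — appropriate for
unbalanced cell sizes — and Tukey-Kramer post-hoc comparison of the
four cell means against the pooled error.  It runs either from raw
per-animal values or directly from per-cell summary statistics
(n, mean, SD), which is what published tables provide; the two paths
are algebraically identical because every Type III quantity in a 2 x 2
design depends on the data only through the cell means, variances and
counts:

    MSE        = sum (n_ij - 1) s_ij^2 / sum (n_ij - 1)
    contrast c = w . m          (w = (1,1,-1,-1)/2, (1,-1,1,-1)/2, (1,-1,-1,1))
    F          = c^2 / (MSE * sum w_ij^2 / n_ij),   df = (1, sum (n_ij - 1))
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .space import Sphere, TemplateSpace

__all__ = [
    "ROISpec",
    "CellSummary",
    "AnovaResult",
    "roi_means",
    "anova_two_way",
    "summaries_from_raw",
    "group_bar_stats",
]


@dataclass
class ROISpec:
    """A named spherical ROI in bregma-relative mm."""

    name: str
    center: Tuple[float, float, float]      # (coronal, horizontal, sagittal)
    radius_mm: float
    side: str = "bilateral"                 # left | right | bilateral

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ValueError("ROI radius must be positive")
        if self.side not in ("left", "right", "bilateral"):
            raise ValueError("side must be left, right or bilateral")

    def voxel_mask(self, space: TemplateSpace) -> np.ndarray:
        c = np.asarray(self.center, dtype=float)
        centers = [c]
        if self.side == "bilateral":
            mirror = c.copy()
            mirror[2] = -mirror[2]
            if not np.allclose(mirror, c):
                centers.append(mirror)
        elif self.side == "left":
            centers = [np.array([c[0], c[1], -abs(c[2])])]
        elif self.side == "right":
            centers = [np.array([c[0], c[1], abs(c[2])])]
        pts = space.voxel_center_grid()
        mask = np.zeros(space.shape, dtype=bool)
        for cc in centers:
            mask |= Sphere(cc, self.radius_mm).contains(pts.reshape(-1, 3)).reshape(space.shape)
        return mask


def roi_means(
    maps: Dict[str, np.ndarray], roi: ROISpec, space: TemplateSpace
) -> pd.Series:
    """Mean metric value inside the ROI for each subject map."""
    mask = roi.voxel_mask(space)
    if not np.any(mask):
        raise ValueError(f"ROI {roi.name!r} voxelizes to an empty region")
    return pd.Series(
        {k: float(np.mean(np.asarray(v)[mask])) for k, v in maps.items()},
        name=roi.name,
    )


# ---------------------------------------------------------------------------
# two-way ANOVA (2 x 2, Type III) from cell summaries

@dataclass
class CellSummary:
    """Summary of one design cell: factor levels, n, mean, dispersion."""

    factor1: str                     # e.g. genotype level
    factor2: str                     # e.g. age level
    n: int
    mean: float
    dispersion: float
    dispersion_kind: str = "sd"      # "sd" | "sem"

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("each cell needs n >= 2")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.dispersion_kind not in ("sd", "sem"):
            raise ValueError("dispersion_kind must be 'sd' or 'sem'")

    @property
    def sd(self) -> float:
        if self.dispersion_kind == "sd":
            return self.dispersion
        return self.dispersion * np.sqrt(self.n)


@dataclass
class AnovaResult:
    effects: pd.DataFrame        # rows factor1/factor2/interaction: F, df1, df2, p
    posthoc: pd.DataFrame        # Tukey-Kramer pairwise comparisons
    mse: float
    df_error: int


def summaries_from_raw(
    data: pd.DataFrame,
    value: str = "value",
    factor1: str = "genotype",
    factor2: str = "age",
) -> List[CellSummary]:
    """Collapse a raw per-subject table into the four cell summaries."""
    cells = []
    for (l1, l2), grp in data.groupby([factor1, factor2], sort=True):
        v = grp[value].to_numpy(dtype=float)
        cells.append(CellSummary(str(l1), str(l2), len(v), float(v.mean()),
                                 float(v.std(ddof=1)), "sd"))
    return cells


def anova_two_way(cells: Sequence[CellSummary]) -> AnovaResult:
    """2 x 2 between-subjects ANOVA, Type III sums of squares, with
    Tukey-Kramer post-hoc comparison of the four cell means.

    Main effects are contrasts of unweighted marginal means; with a
    balanced design this reduces to the classical textbook two-way
    ANOVA.  The error term pools the within-cell variances.
    """
    if len(cells) != 4:
        raise ValueError("exactly four cells required (2 x 2 design)")
    lv1 = sorted({c.factor1 for c in cells})
    lv2 = sorted({c.factor2 for c in cells})
    if len(lv1) != 2 or len(lv2) != 2:
        raise ValueError("cells must span a full 2 x 2 design")
    grid = {(c.factor1, c.factor2): c for c in cells}
    order = [(a, b) for a in lv1 for b in lv2]      # (1,1),(1,2),(2,1),(2,2)
    m = np.array([grid[k].mean for k in order])
    n = np.array([grid[k].n for k in order])
    s = np.array([grid[k].sd for k in order])

    df_err = int(np.sum(n - 1))
    mse = float(np.sum((n - 1) * s**2) / df_err)

    contrasts = {
        "factor1": np.array([0.5, 0.5, -0.5, -0.5]),
        "factor2": np.array([0.5, -0.5, 0.5, -0.5]),
        "interaction": np.array([1.0, -1.0, -1.0, 1.0]),
    }
    rows = []
    for name, w in contrasts.items():
        c = float(w @ m)
        varfac = float(np.sum(w**2 / n))
        if mse == 0:
            F = 0.0 if c == 0 else np.inf
        else:
            F = c**2 / (varfac * mse)
        p = float(stats.f.sf(F, 1, df_err)) if np.isfinite(F) else 0.0
        if F == 0:
            p = 1.0
        rows.append({"effect": name, "F": F, "df1": 1, "df2": df_err, "p": p})
    effects = pd.DataFrame(rows).set_index("effect")

    # Tukey-Kramer on the four cells
    ph = []
    k = len(order)
    for (i, j) in combinations(range(k), 2):
        diff = m[i] - m[j]
        se = np.sqrt(mse / 2.0 * (1.0 / n[i] + 1.0 / n[j]))
        if se == 0:
            q = 0.0 if diff == 0 else np.inf
        else:
            q = abs(diff) / se
        p_adj = float(stats.studentized_range.sf(q, k, df_err)) if np.isfinite(q) else 0.0
        if q == 0:
            p_adj = 1.0
        t = diff / (np.sqrt(mse * (1.0 / n[i] + 1.0 / n[j])) or np.inf)
        p_raw = float(2 * stats.t.sf(abs(t), df_err)) if np.isfinite(t) else 0.0
        ph.append({
            "cell_a": "/".join(order[i]), "cell_b": "/".join(order[j]),
            "diff": diff, "p_tukey": min(p_adj, 1.0), "p_unadjusted": p_raw,
        })
    return AnovaResult(effects=effects, posthoc=pd.DataFrame(ph),
                       mse=mse, df_error=df_err)


def group_bar_stats(
    values: Dict[Tuple[str, str], Sequence[float]],
    comparisons: Optional[List[Tuple[Tuple[str, str], Tuple[str, str]]]] = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-cell mean and SEM plus two-sample t-tests for the displayed
    comparisons (default: mutant vs wildtype at each timepoint).

    ``values`` maps (genotype, timepoint) to per-subject scalars.
    """
    cells = {}
    rows = []
    for key, v in values.items():
        arr = np.asarray(list(v), dtype=float)
        if len(arr) < 2:
            raise ValueError(f"cell {key} needs at least 2 values")
        cells[key] = arr
        rows.append({"genotype": key[0], "timepoint": key[1],
                     "n": len(arr), "mean": arr.mean(),
                     "sem": arr.std(ddof=1) / np.sqrt(len(arr))})
    summary = pd.DataFrame(rows)

    if comparisons is None:
        tps = sorted({k[1] for k in cells})
        comparisons = [
            (("mutant", tp), ("wildtype", tp))
            for tp in tps
            if ("mutant", tp) in cells and ("wildtype", tp) in cells
        ]
    comps = []
    for a, b in comparisons:
        va, vb = cells[a], cells[b]
        if np.array_equal(va, vb):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(va, vb, equal_var=True)
        comps.append({"cell_a": "/".join(a), "cell_b": "/".join(b),
                      "t": float(t), "p": float(p),
                      "significant": bool(p < alpha)})
    out = summary.copy()
    out.attrs["comparisons"] = pd.DataFrame(comps)
    return out
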