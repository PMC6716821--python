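"""Cohort-level orchestration: simulate -> fit -> normalize -> analyze.

These functions wire the module-level operations into the standard
processing cascade and define the run-directory layout the CLI uses.
Tensors are fitted in native space and scalar maps are warped into
template space (affine from landmarks, optional nonlinear refinement);
tensor components are warped the same way for the averaged tractography
dataset.  Pose offsets between scans are small rigid transforms, so no
tensor reorientation is applied to the warped components.
"""

from __future__ import annotations

import dataclasses
import datetime
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .normalize import (SubjectScan, SubjectTransform, build_templates,
                        quality_check, template_sample_coords,
                        warp_with_coords, warp_to_template)
from .phantom import PhantomSpec, atlas_landmarks, simulate_cohort
from .space import TemplateSpace
from .tensor import METRICS, DWIStack, compute_metrics, fit_tensor
from .tracking import (average_dataset, seeds_from_region, select_tract,
                       tfas, track_streamlines)
from .wbss import run_wbss

__all__ = ["CohortResult", "process_cohort", "structure_region",
           "run_tract_analysis"]


@dataclass
class CohortResult:
    """Template-space products of one cohort run."""

    space: TemplateSpace
    transforms: Dict[Tuple[str, str], SubjectTransform]
    metric_maps: Dict[str, Dict[Tuple[str, str], np.ndarray]]
    tensor_maps: Dict[Tuple[str, str], np.ndarray]
    manifest: pd.DataFrame
    template_info: dict
    qc: Dict[Tuple[str, str], Tuple[str, np.ndarray]] = field(default_factory=dict)


def structure_region(spec: PhantomSpec, name: str):
    for st in spec.structures:
        if st.name == name:
            return st.region
    raise KeyError(f"no phantom structure named {name!r}")


def process_cohort(
    manifest: pd.DataFrame,
    stacks: Dict[Tuple[str, str], DWIStack],
    landmarks: Dict[Tuple[str, str], np.ndarray],
    template_landmarks: np.ndarray,
    config: PipelineConfig,
    nonlinear: bool = False,
    run_qc: bool = True,
) -> CohortResult:
    """Fit tensors, build the study template and warp all maps into it.

    ``nonlinear=False`` stops template building after the landmark
    affine + averaging iteration (sufficient when scans differ by small
    rigid pose offsets); ``nonlinear=True`` runs the full iterative
    refinement until the FA correlation criterion is met.
    """
    keys: List[Tuple[str, str]] = []
    qc: Dict[Tuple[str, str], Tuple[str, np.ndarray]] = {}
    manifest = manifest.copy()
    for r in manifest.itertuples():
        key = (r.subject_id, r.timepoint)
        if not r.included or key not in stacks:
            continue
        if run_qc:
            verdict, scores = quality_check(
                stacks[key], config.qc_score_threshold,
                config.qc_max_bad_fraction)
            qc[key] = (verdict, scores)
            if verdict == "fail":
                manifest.loc[
                    (manifest.subject_id == r.subject_id)
                    & (manifest.timepoint == r.timepoint), "included"] = False
                continue
        keys.append(key)

    fields = {k: fit_tensor(stacks[k], s0_floor=config.s0_floor,
                            weighted=config.weighted_fit) for k in keys}
    native_metrics = {k: compute_metrics(f) for k, f in fields.items()}

    scans = [
        SubjectScan(
            subject_id=f"{k[0]}:{k[1]}",
            fa=native_metrics[k]["FA"].values,
            b0=fields[k].s0,
            voxel_size_mm=stacks[k].voxel_size_mm,
            landmarks_mm=landmarks[k],
        )
        for k in keys
    ]
    cfg = config if nonlinear else dataclasses.replace(config, template_max_iter=1)
    space, transforms, info = build_templates(scans, template_landmarks, cfg)
    tmap = dict(zip(keys, transforms))

    metric_maps: Dict[str, Dict[Tuple[str, str], np.ndarray]] = {m: {} for m in METRICS}
    tensor_maps: Dict[Tuple[str, str], np.ndarray] = {}
    for k in keys:
        vs = stacks[k].voxel_size_mm
        coords = template_sample_coords(tmap[k], space, vs, stacks[k].shape)
        for m in METRICS:
            metric_maps[m][k] = warp_with_coords(
                native_metrics[k][m].values, coords)
        comps = fields[k].components
        tensor_maps[k] = np.stack(
            [warp_with_coords(comps[..., i], coords) for i in range(6)],
            axis=-1,
        )
    return CohortResult(space=space, transforms=tmap, metric_maps=metric_maps,
                        tensor_maps=tensor_maps, manifest=manifest,
                        template_info=info, qc=qc)


def run_tract_analysis(
    result: CohortResult,
    spec: PhantomSpec,
    tract_name: str,
    config: PipelineConfig,
    metric: str = "RD",
    seed_stride: int = 1,
    endpoint_regions: Optional[Tuple] = None,
):
    """Track one named phantom structure on the averaged dataset and run
    TFAS for ``metric``; returns (tract, per_subject, group_tests)."""
    field_ = average_dataset(list(result.tensor_maps.values()), result.space,
                             fa_threshold=config.fa_threshold)
    region = structure_region(spec, tract_name)
    seeds = seeds_from_region(field_, region)[::max(seed_stride, 1)]
    tract = track_streamlines(
        field_, seeds, step_mm=config.track_step_mm,
        angle_max_deg=config.track_angle_max_deg,
        fa_stop=config.fa_threshold,
        min_length_mm=config.track_min_length_mm,
    )
    tract = select_tract(tract, must_pass=[region],
                         endpoints=endpoint_regions)
    per_subject, tests = tfas(
        tract, result.metric_maps[metric], result.metric_maps["FA"],
        result.manifest, metric=metric, fa_threshold=config.fa_threshold,
        equal_var=config.equal_variance_ttest,
    )
    return tract, per_subject, tests
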