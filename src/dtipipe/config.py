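"""Pipeline configuration: a single flat record serialized to YAML.

Defaults follow the acquisition and analysis conventions the pipeline
was designed around: a 50 um isotropic analysis grid, 200 um FWHM
Gaussian smoothing, an FA threshold of 0.2 for both the statistics mask
and the tracking stop criterion, FDR control at q = 0.05, a 256-voxel
minimum cluster size, and an iterative template build that stops once
every subject's FA map correlates > 0.7 with the FA template.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # grid / preprocessing
    iso_spacing_mm: float = 0.05          # 50 um isogrid
    smoothing_fwhm_mm: float = 0.2        # 200 um FWHM Gaussian
    # statistics
    fa_threshold: float = 0.2             # analysis mask + tracking stop
    fdr_q: float = 0.05
    cluster_min_voxels: int = 256
    cluster_connectivity: int = 26        # 26 or 6
    equal_variance_ttest: bool = True     # Welch when False
    paired_longitudinal: bool = True      # follow-up vs baseline within genotype
    # template build
    template_corr_stop: float = 0.7
    template_max_iter: int = 10
    nonlinear_smooth_sigma_vox: float = 2.0
    nonlinear_iterations: int = 30
    # quality check
    qc_score_threshold: float = 0.8
    qc_max_bad_fraction: float = 0.1
    # tractography
    track_step_mm: float = 0.025          # half an isogrid voxel
    track_angle_max_deg: float = 45.0
    track_min_length_mm: float = 0.5
    track_seed_per_voxel: int = 1
    # tensor fit
    weighted_fit: bool = False
    fit_after_warp: bool = False
    s0_floor: float = 1e-8
    # randomness
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("iso_spacing_mm", "smoothing_fwhm_mm", "track_step_mm",
                     "track_min_length_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 <= self.fa_threshold < 1:
            raise ValueError("fa_threshold must lie in [0, 1)")
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must lie in (0, 1)")
        if self.cluster_connectivity not in (6, 26):
            raise ValueError("cluster_connectivity must be 6 or 26")
        if self.cluster_min_voxels < 1:
            raise ValueError("cluster_min_voxels must be >= 1")

    # -- serialization ----------------------------------------------------
    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        """Short stable digest recorded in output headers for provenance."""
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
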