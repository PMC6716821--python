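import numpy as np
import pytest

import dtipipe as d
from dtipipe.phantom import atlas_landmarks
from dtipipe.pipeline import process_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def clean_spec():
    """Small noise-free, jitter-free phantom for exact-recovery oracles."""
    return d.PhantomSpec.default(
        grid_shape=(24, 24, 10), noise_sigma=0.0,
        jitter_translation_vox=0.0, jitter_rotation_deg=0.0, n_per_group=2,
    )


@pytest.fixture
def noisy_spec():
    """Small phantom at default noise/jitter (desk-scale cohort)."""
    return d.PhantomSpec.default(grid_shape=(24, 24, 10), n_per_group=5)


@pytest.fixture(scope="session")
def lesion_cohort():
    """One processed desk-scale lesioned cohort, shared across tests.

    n = 9 per group (the study design) on a 24 x 24 x 10 native grid; landmark-affine
    normalization (scans differ by rigid jitter only).
    """
    spec = d.PhantomSpec.default(grid_shape=(24, 24, 10), n_per_group=9)
    manifest, stacks, truths = d.simulate_cohort(spec, 20260929)
    lm = atlas_landmarks(spec)
    landmarks = {k: t.subject_landmarks(lm) for k, t in truths.items()}
    config = d.PipelineConfig()
    result = process_cohort(manifest, stacks, landmarks, lm, config)
    return {"spec": spec, "manifest": manifest, "stacks": stacks,
            "truths": truths, "config": config, "result": result}


@pytest.fixture(scope="session")
def study_cohort():
    """One processed cohort at study-like conditions: n = 9 per group on
    a 48 x 48 x 20 native grid (structures span enough voxels that
    partial-volume effects no longer dominate between-subject variance).
    Shared by the end-to-end detection tests and the acceptance suite.
    """
    spec = d.PhantomSpec.default(grid_shape=(48, 48, 20), n_per_group=9)
    manifest, stacks, truths = d.simulate_cohort(spec, 42)
    lm = atlas_landmarks(spec)
    landmarks = {k: t.subject_landmarks(lm) for k, t in truths.items()}
    config = d.PipelineConfig()
    result = process_cohort(manifest, stacks, landmarks, lm, config)
    return {"spec": spec, "manifest": manifest, "stacks": stacks,
            "truths": truths, "config": config, "result": result}
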