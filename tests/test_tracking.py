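"""Deterministic streamline tracking, tract selection and TFAS."""

import numpy as np
import pandas as pd
import pytest

from dtipipe.space import Box, Cylinder, TemplateSpace
from dtipipe.tensor import metrics_from_eigenvalues, tensor_from_eigen
from dtipipe.tracking import (DirectionField, Tract, average_dataset,
                              seeds_from_region, select_tract, tfas,
                              track_streamlines)


def _uniform_field(shape=(21, 21, 21), axis=(1.0, 0.0, 0.0), fa=0.8):
    space = TemplateSpace(shape, 0.05)
    dirs = np.zeros(shape + (3,))
    dirs[:] = np.asarray(axis) / np.linalg.norm(axis)
    return DirectionField(dirs, np.full(shape, fa), space)


class TestTrackStreamlines:
    def test_straight_field_spans_grid_along_x(self):
        field = _uniform_field()
        seed = np.zeros((1, 3))
        tract = track_streamlines(field, seed, step_mm=0.025, fa_stop=0.2,
                                  min_length_mm=0.5)
        assert len(tract) == 1
        sl = tract.streamlines[0]
        # analytic line: y = z = 0 throughout, x spans nearly the grid
        assert np.abs(sl[:, 1:]).max() < 0.05          # < 1 voxel deviation
        assert sl[:, 0].max() > 0.45 and sl[:, 0].min() < -0.45

    def test_sharp_corner_terminates(self):
        """A 90-degree direction change beyond the 45-degree angle
        threshold stops propagation at the interface."""
        shape = (21, 21, 21)
        space = TemplateSpace(shape, 0.05)
        dirs = np.zeros(shape + (3,))
        dirs[:10] = (1.0, 0.0, 0.0)
        dirs[10:] = (0.0, 1.0, 0.0)
        field = DirectionField(dirs, np.full(shape, 0.8), space)
        tract = track_streamlines(field, np.array([[-0.25, 0.0, 0.0]]),
                                  step_mm=0.025, angle_max_deg=45.0,
                                  fa_stop=0.2, min_length_mm=0.1)
        sl = tract.streamlines[0]
        assert sl[:, 0].max() < 0.05      # never crosses far into the y-field

    def test_quarter_circle_arc_length(self):
        """Tangent field on a quarter annulus: integrated arc length
        within 5% of (pi/2) R."""
        shape = (81, 81, 5)
        space = TemplateSpace(shape, 0.05)
        pts = space.voxel_center_grid()
        x, y = pts[..., 0], pts[..., 1]
        r = np.hypot(x, y)
        R = 1.2
        quad = (x > 0.02) & (y > 0.02)
        ann = quad & (np.abs(r - R) < 0.25)
        dirs = np.zeros(shape + (3,))
        with np.errstate(invalid="ignore", divide="ignore"):
            tx, ty = -y / r, x / r
        dirs[..., 0] = np.where(ann, tx, 0.0)
        dirs[..., 1] = np.where(ann, ty, 0.0)
        fa = np.where(ann, 0.8, 0.0)
        field = DirectionField(dirs, fa, space)
        seed = np.array([[R / np.sqrt(2), R / np.sqrt(2), 0.0]])
        tract = track_streamlines(field, seed, step_mm=0.01, fa_stop=0.2,
                                  min_length_mm=0.1)
        sl = tract.streamlines[0]
        length = np.sum(np.linalg.norm(np.diff(sl, axis=0), axis=1))
        assert length == pytest.approx(np.pi / 2 * R, rel=0.05)

    def test_determinism(self):
        field = _uniform_field()
        seeds = np.array([[0.0, 0.0, 0.0], [0.0, 0.1, 0.0]])
        t1 = track_streamlines(field, seeds)
        t2 = track_streamlines(field, seeds)
        assert len(t1) == len(t2)
        for a, b in zip(t1.streamlines, t2.streamlines):
            assert np.array_equal(a, b)

    def test_seed_subset_monotonicity(self):
        field = _uniform_field()
        seeds = np.array([[0.0, 0.0, 0.0], [0.0, 0.1, 0.0], [0.0, -0.1, 0.1]])
        full = track_streamlines(field, seeds)
        sub = track_streamlines(field, seeds[:2])
        reprs = [s.tobytes() for s in full.streamlines]
        for s in sub.streamlines:
            assert s.tobytes() in reprs

    def test_eigenvector_sign_invariance(self, rng):
        """Random per-voxel sign flips leave streamlines unchanged: the
        tracker sign-aligns before interpolating."""
        f1 = _uniform_field()
        dirs = f1.directions.copy()
        flips = rng.random(f1.fa.shape) > 0.5
        dirs[flips] *= -1
        f2 = DirectionField(dirs, f1.fa.copy(), f1.space)
        seeds = np.array([[0.0, 0.05, -0.03]])
        t1 = track_streamlines(f1, seeds)
        t2 = track_streamlines(f2, seeds)
        for a, b in zip(t1.streamlines, t2.streamlines):
            assert np.allclose(a, b, atol=1e-12)

    def test_empty_seeds_empty_tract(self):
        tract = track_streamlines(_uniform_field(), np.empty((0, 3)))
        assert len(tract) == 0

    def test_consecutive_points_within_step(self):
        tract = track_streamlines(_uniform_field(), np.zeros((1, 3)),
                                  step_mm=0.025)
        for sl in tract.streamlines:
            gaps = np.linalg.norm(np.diff(sl, axis=0), axis=1)
            assert gaps.max() <= 0.025 + 1e-12


class TestAverageDataset:
    def _comps(self, D, shape=(8, 8, 8)):
        c = np.array([D[0, 0], D[1, 1], D[2, 2], D[0, 1], D[0, 2], D[1, 2]])
        out = np.zeros(shape + (6,))
        out[:] = c
        return out

    def test_single_subject_identity(self):
        space = TemplateSpace((8, 8, 8), 0.05)
        D = tensor_from_eigen([1.7e-3, 0.3e-3, 0.3e-3], [1, 0, 0])
        field = average_dataset([self._comps(D)], space)
        assert np.allclose(np.abs(field.directions[..., 0]), 1.0, atol=1e-9)
        assert np.allclose(field.fa, 0.799, atol=1e-3)

    def test_two_identical_subjects_unchanged(self):
        space = TemplateSpace((8, 8, 8), 0.05)
        D = tensor_from_eigen([1.5e-3, 0.4e-3, 0.2e-3], [0, 1, 1])
        one = average_dataset([self._comps(D)], space)
        two = average_dataset([self._comps(D)] * 2, space)
        assert np.allclose(one.fa, two.fa)
        assert np.allclose(np.abs(np.einsum("...i,...i->...", one.directions,
                                            two.directions)), 1.0, atol=1e-9)

    def test_perpendicular_sticks_average_oblate(self):
        """Equal prolate tensors along x and y average to an oblate
        tensor whose FA is below either input (closed-form check)."""
        space = TemplateSpace((6, 6, 6), 0.05)
        Dx = np.diag([1.7e-3, 0.3e-3, 0.3e-3])
        Dy = np.diag([0.3e-3, 1.7e-3, 0.3e-3])
        field = average_dataset([self._comps(Dx), self._comps(Dy)], space)
        ref = metrics_from_eigenvalues(np.array([1.0e-3, 1.0e-3, 0.3e-3]))
        assert np.allclose(field.fa, ref["FA"], atol=1e-9)
        assert field.fa[0, 0, 0] < 0.7       # below single-stick FA 0.799

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            average_dataset([], TemplateSpace((4, 4, 4), 0.05))


class TestSelectTract:
    def _line(self, y):
        x = np.linspace(-0.4, 0.4, 33)
        return np.column_stack([x, np.full_like(x, y), np.zeros_like(x)])

    def _tract(self):
        space = TemplateSpace((21, 21, 21), 0.05)
        return Tract([self._line(0.0), self._line(0.2)], space)

    def test_no_match_empty(self):
        tract = self._tract()
        out = select_tract(tract, must_pass=[Box((0, -0.4, 0), (0.05, 0.05, 0.05))])
        assert len(out) == 0

    def test_whole_grid_must_pass_keeps_all(self):
        tract = self._tract()
        out = select_tract(tract, must_pass=[Box((0, 0, 0), (1, 1, 1))])
        assert len(out) == 2

    def test_midline_and_endpoint_selection(self):
        """Only the streamline crossing the midline cylinder with
        endpoints in both lateral boxes survives; the other is excluded."""
        tract = self._tract()
        mid = Cylinder((0.0, -0.05, -0.1), (0.0, -0.05, 0.1), 0.08)
        left = Box((-0.4, 0.0, 0.0), (0.05, 0.1, 0.2))
        right = Box((0.4, 0.0, 0.0), (0.05, 0.1, 0.2))
        out = select_tract(tract, must_pass=[mid], endpoints=(left, right))
        assert len(out) == 1
        assert np.allclose(out.streamlines[0][:, 1], 0.0)


class TestTfas:
    def _setup(self):
        space = TemplateSpace((5, 5, 5), 0.05)
        line = np.array([[-0.05, 0, 0], [0.0, 0, 0]])   # two voxels
        tract = Tract([line], space)
        manifest = pd.DataFrame([
            {"subject_id": "m1", "genotype": "mutant", "timepoint": "baseline",
             "scan_date": "2020-01-01", "dwi_path": "", "included": True},
        ])
        return space, tract, manifest

    def test_two_voxel_mean(self):
        space, tract, manifest = self._setup()
        fa = np.zeros((5, 5, 5))
        vox = np.round(space.mm_to_voxel(tract.streamlines[0])).astype(int)
        fa[tuple(vox[0])] = 0.3
        fa[tuple(vox[1])] = 0.5
        per, _ = tfas(tract, {("m1", "baseline"): fa},
                      {("m1", "baseline"): fa}, manifest, fa_threshold=0.2)
        assert per.value.iloc[0] == pytest.approx(0.4)

    def test_subthreshold_voxels_excluded(self):
        space, tract, manifest = self._setup()
        fa = np.zeros((5, 5, 5))
        vox = np.round(space.mm_to_voxel(tract.streamlines[0])).astype(int)
        fa[tuple(vox[0])] = 0.1          # below threshold: excluded
        fa[tuple(vox[1])] = 0.5
        per, _ = tfas(tract, {("m1", "baseline"): fa},
                      {("m1", "baseline"): fa}, manifest, fa_threshold=0.2)
        assert per.value.iloc[0] == pytest.approx(0.5)

    def test_identical_groups_null(self, lesion_cohort):
        res = lesion_cohort["result"]
        space = res.space
        line = np.array([[-0.1, -0.2, 0.0], [0.1, -0.2, 0.0]])
        tract = Tract([line], space)
        maps = {k: np.full(space.shape, 0.5) for k in res.metric_maps["FA"]}
        per, tests = tfas(tract, maps, maps, res.manifest, fa_threshold=0.2)
        assert np.allclose(tests.t, 0.0) and np.allclose(tests.p, 1.0)

    def test_value_within_contributing_range(self, lesion_cohort):
        res = lesion_cohort["result"]
        tract = Tract([np.array([[0.0, -0.24, -0.5], [0.0, -0.24, 0.5]])],
                      res.space)
        fa_maps = res.metric_maps["FA"]
        per, _ = tfas(tract, fa_maps, fa_maps, res.manifest)
        mask = tract.occupancy_mask
        for r in per.itertuples():
            vals = fa_maps[(r.subject_id, r.timepoint)][mask]
            vals = vals[vals >= 0.2]
            assert vals.min() - 1e-12 <= r.value <= vals.max() + 1e-12

    def test_empty_mask_rejected(self):
        space, tract, manifest = self._setup()
        empty = Tract([], space)
        with pytest.raises(ValueError):
            tfas(empty, {}, {}, manifest)

    def test_group_dissociation_cc_vs_cst(self, lesion_cohort):
        """Lesion on the callosal pathway, spared descending tract: TFAS
        finds a follow-up group difference for CC only."""
        from dtipipe.pipeline import run_tract_analysis
        res = lesion_cohort["result"]
        spec = lesion_cohort["spec"]
        cfg = lesion_cohort["config"]
        _, _, cc = run_tract_analysis(res, spec, "cc", cfg, metric="RD",
                                      seed_stride=7)
        _, _, cst = run_tract_analysis(res, spec, "cst", cfg, metric="RD",
                                       seed_stride=7)
        cc_fu = cc[cc.timepoint == "followup"].iloc[0]
        cst_fu = cst[cst.timepoint == "followup"].iloc[0]
        assert cc_fu.p < 0.05
        assert cst_fu.p > 0.05
        # affected tract: mutant RD elevated at follow-up
        assert cc_fu.mean_mutant > cc_fu.mean_wildtype
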