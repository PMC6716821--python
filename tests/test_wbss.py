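"""Smoothing, voxelwise tests, per-day change maps, FDR and clustering."""

import datetime

import numpy as np
import pytest
from scipy import ndimage

import dtipipe as d
from dtipipe.space import TemplateSpace
from dtipipe.wbss import (cluster_filter, delta_map, fdr_correct, run_wbss,
                          smooth_map, voxelwise_ttest)


# -- independent oracles -----------------------------------------------------

def bh_bruteforce(p, q):
    """All-k scan of the Benjamini-Hochberg step-up rule."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ps = p[order]
    kmax = 0
    for k in range(1, m + 1):
        if ps[k - 1] <= k * q / m:
            kmax = k
    reject = np.zeros(m, dtype=bool)
    if kmax:
        reject[order[:kmax]] = True
    return reject


def flood_fill_labels(field, connectivity=26):
    """Breadth-first connected-component labeling, independent of
    scipy.ndimage.label."""
    field = np.asarray(field, dtype=bool)
    offs = [
        (i, j, k)
        for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
        and (connectivity == 26 or abs(i) + abs(j) + abs(k) == 1)
    ]
    labels = np.zeros(field.shape, dtype=int)
    nxt = 0
    for start in map(tuple, np.argwhere(field)):
        if labels[start]:
            continue
        nxt += 1
        stack = [start]
        labels[start] = nxt
        while stack:
            x, y, z = stack.pop()
            for i, j, k in offs:
                n = (x + i, y + j, z + k)
                if (0 <= n[0] < field.shape[0] and 0 <= n[1] < field.shape[1]
                        and 0 <= n[2] < field.shape[2]
                        and field[n] and not labels[n]):
                    labels[n] = nxt
                    stack.append(n)
    return labels, nxt


# -- smoothing ---------------------------------------------------------------

class TestSmoothing:
    def test_constant_map_unchanged(self):
        m = np.full((20, 20, 20), 0.4)
        out = smooth_map(m, 0.05, 0.2)
        assert np.allclose(out, 0.4, rtol=1e-12)

    def test_impulse_matches_sampled_gaussian(self):
        """A central unit impulse smooths to the sampled 3-D Gaussian
        with sigma = FWHM / 2.3548 (about 1.70 voxels at 50 um), sum 1."""
        n = 31
        m = np.zeros((n, n, n))
        m[15, 15, 15] = 1.0
        out = smooth_map(m, 0.05, 0.2)
        sigma = 0.2 / (2 * np.sqrt(2 * np.log(2))) / 0.05
        assert sigma == pytest.approx(1.6986, abs=1e-3)
        idx = np.stack(np.meshgrid(*[np.arange(n)] * 3, indexing="ij"), axis=-1)
        ref = np.exp(-np.sum((idx - 15.0) ** 2, axis=-1) / (2 * sigma**2))
        ref /= ref.sum()
        assert out.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.abs(out - ref).max() < 1e-4

    def test_semigroup_property(self):
        rng = np.random.default_rng(1)
        m = ndimage.gaussian_filter(rng.random((24, 24, 24)), 1.0)
        twice = smooth_map(smooth_map(m, 0.05, 0.2), 0.05, 0.2)
        once = smooth_map(m, 0.05, 0.2 * np.sqrt(2))
        inner = (slice(4, -4),) * 3
        assert np.abs(twice[inner] - once[inner]).max() < 2e-3

    def test_masked_smoothing_ignores_off_mask(self):
        m = np.zeros((16, 16, 16))
        mask = np.zeros_like(m, dtype=bool)
        mask[4:12, 4:12, 4:12] = True
        m[mask] = 0.5
        m[~mask] = 99.0      # junk off the mask must not leak in
        out = smooth_map(m, 0.05, 0.2, mask=mask)
        assert np.allclose(out[mask], 0.5, rtol=1e-9)
        assert np.all(out[~mask] == 0)

    def test_nonpositive_fwhm_rejected(self):
        with pytest.raises(ValueError):
            smooth_map(np.zeros((4, 4, 4)), 0.05, 0.0)


# -- voxelwise t-tests -------------------------------------------------------

class TestVoxelwiseTTest:
    def _mask(self, shape=(3, 3, 3)):
        return np.ones(shape, dtype=bool)

    def test_identical_groups_give_null(self):
        maps = [np.full((3, 3, 3), 0.3), np.full((3, 3, 3), 0.5)]
        stat = voxelwise_ttest(maps, list(maps), self._mask())
        assert np.allclose(stat.t, 0.0)
        assert np.allclose(stat.p, 1.0)

    def test_hand_computed_pooled_variance_case(self):
        """A = {1,2,3}, B = {4,5,6}: t = -3.674, p = 0.0214 at df 4
        (hand-computed pooled-variance oracle)."""
        A = [np.full((2, 2, 2), v) for v in (1.0, 2.0, 3.0)]
        B = [np.full((2, 2, 2), v) for v in (4.0, 5.0, 6.0)]
        stat = voxelwise_ttest(A, B, self._mask((2, 2, 2)))
        assert stat.df == 4
        assert stat.t[0, 0, 0] == pytest.approx(-3.6742, abs=1e-3)
        assert stat.p[0, 0, 0] == pytest.approx(0.02131, abs=2e-4)

    def test_agrees_with_scipy_on_random_data(self, rng):
        from scipy import stats as ss
        A = [rng.random((4, 4, 4)) for _ in range(5)]
        B = [rng.random((4, 4, 4)) for _ in range(6)]
        stat = voxelwise_ttest(A, B, self._mask((4, 4, 4)))
        t_ref, p_ref = ss.ttest_ind(np.stack(A), np.stack(B), axis=0)
        assert np.allclose(stat.t, t_ref, rtol=1e-10)
        assert np.allclose(stat.p, p_ref, rtol=1e-10)

    def test_paired_matches_scipy(self, rng):
        from scipy import stats as ss
        A = [rng.random((3, 3, 3)) for _ in range(5)]
        B = [rng.random((3, 3, 3)) for _ in range(5)]
        stat = voxelwise_ttest(A, B, self._mask(), paired=True)
        t_ref, p_ref = ss.ttest_rel(np.stack(A), np.stack(B), axis=0)
        assert np.allclose(stat.t, t_ref, rtol=1e-10)
        assert np.allclose(stat.p, p_ref, rtol=1e-10)

    def test_group_too_small_rejected(self):
        m = np.zeros((2, 2, 2))
        with pytest.raises(ValueError, match="at least 2"):
            voxelwise_ttest([m], [m, m], self._mask((2, 2, 2)))


# -- per-day change (longitudinal rate) --------------------------------------

class TestDeltaMap:
    d1 = datetime.date(2020, 1, 1)
    d2 = datetime.date(2020, 5, 30)      # 150 days later

    def test_identical_maps_give_zero(self):
        m = np.random.default_rng(0).random((4, 4, 4))
        assert np.allclose(delta_map(m, m, self.d1, self.d2), 0.0)

    def test_direct_substitution(self):
        """DM falls 0.50 -> 0.40 over 150 days: rate = -6.67e-4 / day."""
        b = np.full((2, 2, 2), 0.50)
        f = np.full((2, 2, 2), 0.40)
        out = delta_map(b, f, self.d1, self.d2)
        assert out[0, 0, 0] == pytest.approx(0.10 / -150, rel=1e-12)

    def test_interval_scaling(self):
        b = np.full((2, 2, 2), 0.5)
        f = np.full((2, 2, 2), 0.4)
        one = delta_map(b, f, self.d1, self.d2)
        double = delta_map(b, f, self.d1,
                           self.d1 + datetime.timedelta(days=300))
        assert np.allclose(double, one / 2, rtol=1e-12)

    def test_date_offset_invariance(self):
        b = np.full((2, 2, 2), 0.5)
        f = np.full((2, 2, 2), 0.4)
        shift = datetime.timedelta(days=365)
        a = delta_map(b, f, self.d1, self.d2)
        c = delta_map(b, f, self.d1 + shift, self.d2 + shift)
        assert np.allclose(a, c)

    def test_equal_dates_rejected(self):
        m = np.zeros((2, 2, 2))
        with pytest.raises(ValueError):
            delta_map(m, m, self.d1, self.d1)


# -- FDR ---------------------------------------------------------------------

class TestFDR:
    def test_textbook_case_all_rejected(self):
        mask = np.ones((2, 2, 1), dtype=bool)
        p = np.array([0.01, 0.02, 0.03, 0.04]).reshape(2, 2, 1)
        rej = fdr_correct(p, 0.05, mask)
        assert rej.all()

    def test_all_ones_none_rejected(self):
        mask = np.ones((3, 3, 3), dtype=bool)
        rej = fdr_correct(np.ones((3, 3, 3)), 0.05, mask)
        assert not rej.any()

    def test_single_test_reduces_to_threshold(self):
        mask = np.zeros((2, 2, 2), dtype=bool)
        mask[0, 0, 0] = True
        p = np.ones((2, 2, 2))
        p[0, 0, 0] = 0.04
        assert fdr_correct(p, 0.05, mask)[0, 0, 0]
        p[0, 0, 0] = 0.06
        assert not fdr_correct(p, 0.05, mask).any()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        shape = (10, 10, 10)
        p = rng.random(shape) ** 2
        mask = rng.random(shape) > 0.3
        rej = fdr_correct(p, 0.05, mask)
        assert np.array_equal(rej[mask], bh_bruteforce(p[mask], 0.05))

    def test_monotone_in_q_property(self):
        """BH rejections grow monotonically with q for arbitrary
        p-fields (property test)."""
        from hypothesis import given, settings
        from hypothesis import strategies as st

        @given(st.lists(st.floats(min_value=0.0, max_value=1.0),
                        min_size=1, max_size=64),
               st.floats(min_value=0.01, max_value=0.2))
        @settings(max_examples=50, derandomize=True, deadline=None)
        def check(ps, q_lo):
            p = np.asarray(ps).reshape(-1, 1, 1)
            mask = np.ones(p.shape, dtype=bool)
            lo = fdr_correct(p, q_lo, mask)
            hi = fdr_correct(p, min(q_lo * 2, 0.5), mask)
            assert np.all(hi[lo])

        check()

    def test_monotone_in_q(self, rng):
        p = rng.random((8, 8, 8)) ** 3
        mask = np.ones(p.shape, dtype=bool)
        r1 = fdr_correct(p, 0.01, mask)
        r5 = fdr_correct(p, 0.05, mask)
        assert np.all(r5[r1])            # q=0.01 rejections subset of q=0.05

    def test_empty_mask(self):
        assert not fdr_correct(np.ones((2, 2, 2)), 0.05,
                               np.zeros((2, 2, 2), bool)).any()


# -- cluster filtering -------------------------------------------------------

class TestClusterFilter:
    def test_size_threshold(self):
        field = np.zeros((20, 20, 20), dtype=bool)
        field[0:10, 0:10, 0:3] = True            # 300 voxels
        field[15:20, 15:20, 15:19] = True        # 100 voxels
        table = cluster_filter(field, min_size=256)
        assert len(table) == 1
        assert table.df.iloc[0].size_voxels == 300

    def test_empty_field_empty_table(self):
        table = cluster_filter(np.zeros((5, 5, 5), bool), 256)
        assert len(table) == 0

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_random_field_matches_flood_fill(self, connectivity, rng):
        field = rng.random((12, 12, 12)) > 0.7
        table = cluster_filter(field, min_size=1, connectivity=connectivity)
        ref_labels, ref_n = flood_fill_labels(field, connectivity)
        ref_sizes = sorted(np.bincount(ref_labels.ravel())[1:].tolist())
        assert sorted(table.df.size_voxels.tolist()) == ref_sizes
        # identical partitions: label images agree up to renumbering
        for lab in range(1, ref_n + 1):
            ours = table.labels[ref_labels == lab]
            assert len(set(ours.tolist())) == 1

    def test_survivors_subset_of_rejections(self, rng):
        field = rng.random((15, 15, 15)) > 0.5
        table = cluster_filter(field, min_size=20)
        assert not np.any((table.labels > 0) & ~field)

    def test_peak_is_minimum_p_and_reported_in_mm(self):
        space = TemplateSpace((9, 9, 9), 0.05)
        field = np.zeros((9, 9, 9), dtype=bool)
        field[2:7, 2:7, 2:7] = True
        p = np.ones((9, 9, 9))
        p[3, 4, 5] = 1e-8
        t = np.full((9, 9, 9), -3.0)
        table = cluster_filter(field, 10, space=space, p=p, t=t)
        row = table.df.iloc[0]
        assert row.p == pytest.approx(1e-8)
        assert (row.bregma_cor, row.bregma_hor, row.bregma_sag) == \
            pytest.approx(((3 - 4) * 0.05, 0.0, 0.05))
        assert row.mean_t == pytest.approx(-3.0)


# -- the four dispatched analyses --------------------------------------------

class TestRunWbss:
    def test_lesion_cohort_contrast_pattern(self, lesion_cohort):
        """Mutant-only follow-up lesion, desk scale: the baseline
        contrast stays clean and the follow-up group effect concentrates
        in the true lesion (cluster emergence itself is exercised at the
        study-condition scale below)."""
        res = lesion_cohort["result"]
        cfg = lesion_cohort["config"]
        stat_a, tab_a = run_wbss(res.manifest, res.metric_maps["FA"],
                                 res.space, "FA", "a", cfg)
        assert len(tab_a) == 0
        stat_b, _ = run_wbss(res.manifest, res.metric_maps["FA"],
                             res.space, "FA", "b", cfg)
        lesion = lesion_cohort["spec"].lesion_mask_template(res.space)
        inmask = lesion & stat_b.mask
        # negative t concentrated in the true lesion, null elsewhere
        assert np.median(stat_b.t[inmask]) < -1
        assert np.abs(np.median(stat_b.t[stat_b.mask & ~lesion])) < 1
        peak = np.unravel_index(
            np.argmin(np.where(stat_b.mask, stat_b.p, 1.0)), stat_b.p.shape)
        assert lesion[peak]

    def test_study_scale_cluster_emergence(self, study_cohort):
        """Study-condition cohort: no clusters at baseline, a cluster
        overlapping the lesion (Dice >= 0.3) at follow-up and in the
        per-day-change contrast."""
        res = study_cohort["result"]
        cfg = study_cohort["config"]
        lesion = study_cohort["spec"].lesion_mask_template(res.space)
        _, tab_a = run_wbss(res.manifest, res.metric_maps["FA"],
                            res.space, "FA", "a", cfg)
        assert len(tab_a) == 0
        for contrast in ("b", "d"):
            _, tab = run_wbss(res.manifest, res.metric_maps["FA"],
                              res.space, "FA", contrast, cfg)
            assert len(tab) >= 1
            det = tab.labels > 0
            dice = 2 * np.sum(det & lesion) / (det.sum() + lesion.sum())
            assert dice >= 0.3

    def test_unknown_contrast_rejected(self, lesion_cohort):
        res = lesion_cohort["result"]
        with pytest.raises(ValueError, match="contrast"):
            run_wbss(res.manifest, res.metric_maps["FA"], res.space,
                     "FA", "x", lesion_cohort["config"])

    def test_cluster_voxels_all_rejected(self, lesion_cohort):
        res = lesion_cohort["result"]
        cfg = lesion_cohort["config"]
        stat, table = run_wbss(res.manifest, res.metric_maps["FA"],
                               res.space, "FA", "b", cfg)
        rej = fdr_correct(stat.p, cfg.fdr_q, stat.mask)
        if table.labels is not None:
            assert not np.any((table.labels > 0) & ~rej)
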