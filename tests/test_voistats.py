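import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from dceperf._errors import EstimationError, InputError
from dceperf.datasets import cohort_summaries, group_comparison_table, paired_meningioma_table
from dceperf.io import DynamicSeries, MaskVOI, VolumeMap
from dceperf.voistats import (
    enhancement_curve,
    group_comparison_report,
    mann_whitney_exact,
    mirror_control_voi,
    pearson_correlation,
    render_value,
    voi_mean,
    wilcoxon_signed_rank_exact,
)

AFF = np.eye(4)


class TestVOIMean:
    def test_uniform_map(self):
        vmap = VolumeMap(np.full((4, 4, 2), 3.0), AFF)
        mask = MaskVOI(np.ones((4, 4, 2), np.uint8), AFF)
        mean, n, _ = voi_mean(vmap, mask)
        assert mean == 3.0 and n == 32

    def test_exclusion_arithmetic(self):
        vmap = VolumeMap(np.array([[[0.0, 4.0]]]), AFF)
        mask = MaskVOI(np.array([[[1, 1]]], dtype=np.uint8), AFF)
        excl = MaskVOI(np.array([[[1, 0]]], dtype=np.uint8), AFF)
        mean, n_used, n_excl = voi_mean(vmap, mask, excl)
        assert mean == 4.0 and n_used == 1 and n_excl == 1

    def test_all_excluded_warns_nan(self):
        vmap = VolumeMap(np.full((1, 1, 2), np.nan), AFF)
        mask = MaskVOI(np.ones((1, 1, 2), np.uint8), AFF)
        with pytest.warns(UserWarning, match="no usable"):
            mean, n_used, n_excl = voi_mean(vmap, mask)
        assert np.isnan(mean) and n_used == 0 and n_excl == 2


class TestMirrorControl:
    def test_symmetric_phantom_count_matches(self, small_tofts_phantom):
        _, _, _, masks = small_tofts_phantom
        ctl = mirror_control_voi(masks["tumour"], masks["brain"])
        assert ctl.n_voxels == masks["tumour"].n_voxels
        assert not (ctl.data & masks["tumour"].data).any()

    def test_control_truth_quieter_than_tumour(self, small_tofts_phantom):
        _, _, truth, masks = small_tofts_phantom
        ctl = mirror_control_voi(masks["tumour"], masks["brain"])
        kt = truth["ktrans"].data
        assert np.nanmean(kt[ctl.data.astype(bool)]) < np.nanmean(kt[masks["tumour"].data.astype(bool)])

    def test_midline_crossing_warns_and_excludes_overlap(self):
        brain = MaskVOI(np.ones((10, 6, 4), np.uint8), AFF, "brain")
        tum = np.zeros((10, 6, 4), np.uint8)
        tum[4:8, 2:4, 1:3] = 1  # straddles x midline 4.5 asymmetrically
        with pytest.warns(UserWarning, match="midline"):
            ctl = mirror_control_voi(MaskVOI(tum, AFF), brain)
        assert not (ctl.data & tum).any()

    def test_reflection_outside_brain_errors(self):
        brain = np.zeros((10, 6, 4), np.uint8)
        brain[6:10] = 1  # brain only on one side
        tum = np.zeros((10, 6, 4), np.uint8)
        tum[8:10, 2:4, 1:3] = 1  # reflects to x 0..1, outside brain
        with pytest.raises(InputError, match="manual"):
            mirror_control_voi(MaskVOI(tum, AFF), MaskVOI(brain, AFF, "brain"))

    def test_top_up_dilation_matches_count(self):
        brain = np.zeros((12, 8, 4), np.uint8)
        brain[:, :, :] = 1
        brain[0:3] = 0  # reflected target partially clipped
        tum = np.zeros((12, 8, 4), np.uint8)
        tum[8:12, 2:6, 1:3] = 1
        ctl = mirror_control_voi(MaskVOI(tum, AFF), MaskVOI(brain, AFF, "brain"))
        assert ctl.n_voxels == int(tum.sum())


class TestWilcoxonExact:
    def test_three_positive_differences_one_sided(self):
        r = wilcoxon_signed_rank_exact([2.0, 3.0, 4.0], [1.0, 1.0, 1.0], alternative="greater")
        assert r.p_value == pytest.approx(1.0 / 8.0)
        assert r.p_count == 1 and r.p_total == 8

    def test_all_zero_differences_error(self):
        with pytest.raises(EstimationError):
            wilcoxon_signed_rank_exact([1.0, 2.0], [1.0, 2.0])

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=8), rng.normal(size=8)
        p1 = wilcoxon_signed_rank_exact(x, y).p_value
        d = x - y
        d2 = np.sign(d) * (np.abs(d) ** 3 + np.abs(d))  # strictly monotone in |d|
        p2 = wilcoxon_signed_rank_exact(d2, np.zeros_like(d2)).p_value
        assert p1 == p2

    @given(st.integers(0, 500))
    def test_matches_scipy_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 11))
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        mine = wilcoxon_signed_rank_exact(x, y)
        ref = stats.wilcoxon(x, y, mode="exact")
        assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-12)
        one = wilcoxon_signed_rank_exact(x, y, alternative="greater")
        refg = stats.wilcoxon(x, y, mode="exact", alternative="greater")
        assert one.p_value == pytest.approx(refg.pvalue, abs=1e-12)
        less = wilcoxon_signed_rank_exact(x, y, alternative="less")
        # the directional test matching the observed effect never exceeds two-sided
        assert min(one.p_value, less.p_value) <= mine.p_value + 1e-12


class TestMannWhitneyExact:
    def test_single_observations_two_sided(self):
        r = mann_whitney_exact([1.0], [2.0])
        assert r.p_value == 1.0
        assert r.statistic == 0.0

    def test_tied_values_against_brute_force(self):
        a, b = [1.0, 2.0, 2.0], [2.0, 3.0]
        mine = mann_whitney_exact(a, b)
        pooled = a + b
        n = len(a)

        def u_stat(ax, bx):
            return sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in ax for y in bx)

        u_obs = u_stat(a, b)
        us = [u_stat([pooled[i] for i in c], [pooled[i] for i in range(5) if i not in c])
              for c in itertools.combinations(range(5), n)]
        n_le = sum(u <= u_obs for u in us)
        n_ge = sum(u >= u_obs for u in us)
        expect = min(len(us), 2 * min(n_le, n_ge)) / len(us)
        assert mine.p_value == pytest.approx(expect)
        assert mine.statistic == pytest.approx(u_obs)

    @given(st.integers(0, 500))
    def test_matches_scipy_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        na, nb = int(rng.integers(1, 11)), int(rng.integers(1, 11))
        a = rng.normal(size=na)
        b = rng.normal(size=nb)
        mine = mann_whitney_exact(a, b)
        ref = stats.mannwhitneyu(a, b, method="exact")
        assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-12)
        g = mann_whitney_exact(a, b, alternative="greater")
        refg = stats.mannwhitneyu(a, b, method="exact", alternative="greater")
        assert g.p_value == pytest.approx(refg.pvalue, abs=1e-12)


class TestPearson:
    def test_perfect_linear(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_correlation(x, 2 * x + 1).statistic == pytest.approx(1.0)
        assert pearson_correlation(x, -x).statistic == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(EstimationError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_t_based_p_close_to_permutation(self):
        x = np.array([0.3, 1.1, 2.0, 2.2, 3.7])
        y = np.array([0.9, 1.4, 1.2, 3.1, 3.3])
        r_obs = pearson_correlation(x, y)
        perms = [abs(np.corrcoef(x, np.array(p))[0, 1]) for p in itertools.permutations(y)]
        p_perm = np.mean([p >= abs(r_obs.statistic) - 1e-12 for p in perms])
        assert r_obs.p_value == pytest.approx(p_perm, abs=0.05)


class TestEnhancementCurve:
    @staticmethod
    def _series(data):
        return DynamicSeries(data=data, frame_times=np.arange(data.shape[3]) * 5.0,
                             tr=4.83, te=1.87, flip_angle=12.0,
                             voxel_size=(1, 1, 1), affine=AFF)

    def test_flat_series_zero_enhancement(self):
        s = self._series(np.full((2, 2, 1, 10), 50.0))
        mask = MaskVOI(np.ones((2, 2, 1), np.uint8), AFF)
        np.testing.assert_allclose(enhancement_curve(s, mask, 3), 0.0)

    def test_doubling_is_hundred_percent(self):
        data = np.full((2, 2, 1, 10), 50.0)
        data[..., 5:] = 100.0
        s = self._series(data)
        mask = MaskVOI(np.ones((2, 2, 1), np.uint8), AFF)
        curve = enhancement_curve(s, mask, 3)
        assert curve[-1] == pytest.approx(100.0)

    def test_phantom_tumour_later_and_lower_than_artery(self, small_tofts_phantom):
        series, _, _, masks = small_tofts_phantom
        tum = enhancement_curve(series, masks["tumour"], 3)
        art = enhancement_curve(series, masks["artery"], 3)
        assert tum.max() < art.max()
        # leakage persists while blood washes out: the tumour curve's
        # temporal centroid falls later than the artery's
        t = series.frame_times
        assert (t * tum).sum() / tum.sum() > (t * art).sum() / art.sum()


class TestGroupReport:
    def test_reproduces_published_cohort_statistics(self):
        res, text = group_comparison_report(cohort_summaries())
        by = {(r.test, r.label): r for r in res}
        wk = by[("wilcoxon_signed_rank_exact", "ktrans")]
        assert render_value(wk.median_of_differences, 3) == "-0.045"
        assert render_value(wk.p_value, 4) == "0.0313"
        wr = by[("wilcoxon_signed_rank_exact", "rbf")]
        assert render_value(wr.median_of_differences, 3) == "-3.824"
        assert render_value(wr.p_value, 4) == "0.0313"
        assert render_value(by[("mann_whitney_exact", "rbf")].p_value, 4) == "0.0238"
        assert by[("mann_whitney_exact", "ktrans")].p_value > 0.05

    def test_row_order_invariance(self):
        rows = cohort_summaries()
        rev = list(reversed(rows))
        _, t1 = group_comparison_report(rows)
        _, t2 = group_comparison_report(rev)
        assert t1 == t2

    def test_single_other_subject_still_runs_mann_whitney(self):
        rows = [r for r in cohort_summaries() if not r.subject.startswith("oth")]
        rows += [r for r in cohort_summaries() if r.subject == "oth1"]
        with pytest.warns(UserWarning):  # Pearson skipped (no volumes)
            res, _ = group_comparison_report(rows)
        mw = [r for r in res if r.test == "mann_whitney_exact"]
        assert len(mw) == 2 and all(r.n == (6, 1) for r in mw)

    def test_one_sided_halves_clean_two_sided_p(self):
        res2, _ = group_comparison_report(cohort_summaries(), sidedness="two")
        res1, _ = group_comparison_report(cohort_summaries(), sidedness="one")
        p2 = {r.label: r for r in res2 if r.test == "wilcoxon_signed_rank_exact"}
        p1 = {r.label: r for r in res1 if r.test == "wilcoxon_signed_rank_exact"}
        for lbl in ("ktrans", "rbf"):
            assert p1[lbl].p_value == pytest.approx(p2[lbl].p_value / 2.0)


def test_wilcoxon_reproduces_paired_table_from_raw_columns():
    t = paired_meningioma_table()
    r = wilcoxon_signed_rank_exact(t["ktrans_control"], t["ktrans_tumour"])
    assert r.p_count == 2 and r.p_total == 64
    g = group_comparison_table()
    m = mann_whitney_exact(g["rbf_meningioma"], g["rbf_other"])
    assert m.p_count == 2 and m.p_total == 84
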