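import numpy as np
import pytest

from dceperf.aif import AIFCurve
from dceperf.kinetics import FitConfig, compute_parameter_maps, fit_2cu, fit_extended_tofts, semiquant_flow
from dceperf.relaxometry import RelaxationState, concentration_to_signal
from dceperf.synthetic import TissueKineticParams, UptakeKineticParams, forward_2cu, forward_tofts


class TestExtendedToftsFit:
    def test_null_curve_flagged_degenerate(self, parker_aif):
        res = fit_extended_tofts(np.zeros_like(parker_aif.cp), parker_aif)
        assert res.degenerate
        assert res.params.ktrans == 0.0 and res.params.vp == 0.0

    def test_pure_plasma_construction(self, parker_aif):
        res = fit_extended_tofts(0.1 * parker_aif.cp, parker_aif)
        assert res.params.vp == pytest.approx(0.1, abs=1e-3)
        assert res.params.ktrans == pytest.approx(0.0, abs=1e-3)

    def test_noiseless_recovery_within_two_percent(self, parker_aif, tumour_truth):
        ct = forward_tofts(tumour_truth, parker_aif.cp, parker_aif.t)
        res = fit_extended_tofts(ct, parker_aif)
        assert res.params.ktrans == pytest.approx(tumour_truth.ktrans, rel=0.02)
        assert res.params.ve == pytest.approx(tumour_truth.ve, rel=0.02)
        assert res.params.vp == pytest.approx(tumour_truth.vp, rel=0.02)
        assert res.rsq > 0.999

    def test_kep_is_ktrans_over_ve(self, parker_aif, tumour_truth):
        ct = forward_tofts(tumour_truth, parker_aif.cp, parker_aif.t)
        res = fit_extended_tofts(ct, parker_aif)
        assert res.params.kep * res.params.ve == pytest.approx(res.params.ktrans, rel=1e-9)

    def test_fit_never_worse_than_truth_curve(self, parker_aif, tumour_truth):
        """Optimizer sanity: on noisy data the best-of-starts SSE cannot
        exceed the SSE of the generating parameters."""
        rng = np.random.default_rng(11)
        ct_clean = forward_tofts(tumour_truth, parker_aif.cp, parker_aif.t)
        ct = ct_clean + rng.normal(0, 0.02, size=ct_clean.shape)
        res = fit_extended_tofts(ct, parker_aif, seed=5)
        sse_fit = float(np.sum((res.fitted - ct) ** 2))
        sse_truth = float(np.sum((ct_clean - ct) ** 2))
        assert sse_fit <= sse_truth + 1e-12


class TestUptakeFit:
    truth = UptakeKineticParams(fp=0.6, vp=0.05, ps=0.05)

    def test_noiseless_fp_recovery_within_five_percent(self, parker_aif):
        ct = forward_2cu(self.truth, parker_aif.cp, parker_aif.t)
        res = fit_2cu(ct, parker_aif)
        assert res.params.fp == pytest.approx(self.truth.fp, rel=0.05)

    def test_zero_permeability_recovers_zero_extraction(self, parker_aif):
        ct = forward_2cu(UptakeKineticParams(fp=0.6, vp=0.05, ps=0.0), parker_aif.cp, parker_aif.t)
        res = fit_2cu(ct, parker_aif)
        assert res.params.e == pytest.approx(0.0, abs=1e-3)

    def test_null_curve_flagged(self, parker_aif):
        assert fit_2cu(np.zeros_like(parker_aif.cp), parker_aif).degenerate

    def test_noise_bias_median_under_ten_percent(self, parker_aif, tumour_truth):
        """50 replicate tumour voxels at 5% baseline-signal Gaussian noise:
        median relative bias of fitted ktrans stays below 10%."""
        state = RelaxationState(t10=1400.0, m0=1000.0)
        tr, flip = 4.83, 12.0
        ct = forward_tofts(tumour_truth, parker_aif.cp, parker_aif.t)
        sig = concentration_to_signal(ct, state, tr, flip)
        rng = np.random.default_rng(2024)
        from dceperf.relaxometry import signal_to_concentration

        fits = []
        for i in range(50):
            noisy = sig + rng.normal(0, 0.05 * sig[0], size=sig.shape)
            conc, _ = signal_to_concentration(noisy, 3, state, tr, flip)
            res = fit_extended_tofts(conc, parker_aif, seed=i)
            fits.append(res.params.ktrans)
        bias = np.median(np.abs(np.array(fits) / tumour_truth.ktrans - 1.0))
        assert bias < 0.10


class TestSemiQuantFlow:
    def test_identical_curves_floor_and_flag(self, parker_aif):
        out = semiquant_flow(parker_aif.cp.copy(), parker_aif)
        assert out.cbv == pytest.approx(1.0, rel=1e-9)
        assert out.flagged and out.mtt == pytest.approx(1.0 / 60.0)

    def test_shift_scale_construction(self):
        # ct = 0.5 aif(t - 0.5 min): CBV 0.5, MTT 0.5 min, rBF 1.0 /min
        t = np.linspace(0, 10, 2001)
        bump = np.exp(-0.5 * (t - 2.0) ** 2 / 0.3**2)
        aif = AIFCurve(t=t, cp=bump, source="analytic", n_voxels_used=0)
        ct = 0.5 * np.interp(t - 0.5, t, bump, left=0.0)
        out = semiquant_flow(ct, aif)
        assert out.cbv == pytest.approx(0.5, rel=1e-3)
        assert out.mtt == pytest.approx(0.5, rel=1e-3)
        assert out.rbf_auc == pytest.approx(1.0, rel=2e-3)

    def test_zero_tissue_curve(self, parker_aif):
        out = semiquant_flow(np.zeros_like(parker_aif.cp), parker_aif)
        assert out.cbv == 0.0 and out.rbf_auc == 0.0 and out.flagged


@pytest.fixture(scope="module")
def maps_and_phantom(small_tofts_phantom):
    series, t10, truth, masks = small_tofts_phantom
    t_min = series.frame_times / 60.0
    from dceperf.synthetic import analytic_aif

    aif = AIFCurve(t=t_min, cp=analytic_aif(t_min, "parker", t0=t_min[3]),
                   source="analytic", n_voxels_used=0)
    cfg = FitConfig(models=("tofts",), seed=7)
    maps = compute_parameter_maps(series, t10, aif, masks, cfg)
    return maps, series, truth, masks, aif, cfg


class TestParameterMaps:
    def test_region_median_recovery(self, maps_and_phantom, tumour_truth):
        maps, _, truth, masks, _, _ = maps_and_phantom
        sel = masks["tumour"].data.astype(bool)
        assert np.nanmedian(maps.ktrans.data[sel]) == pytest.approx(tumour_truth.ktrans, rel=0.02)
        assert np.nanmedian(maps.ve.data[sel]) == pytest.approx(tumour_truth.ve, rel=0.02)
        assert np.nanmedian(maps.vp.data[sel]) == pytest.approx(tumour_truth.vp, rel=0.02)

    def test_zero_signal_voxels_excluded_and_nan(self, maps_and_phantom):
        maps, series, _, masks, _, _ = maps_and_phantom
        brain = masks["brain"].data.astype(bool)
        zero_sig = brain & (series.data.max(axis=-1) <= 0)
        if zero_sig.any():
            assert maps.excluded.data[zero_sig].all()
            assert np.isnan(maps.ktrans.data[zero_sig]).all()

    def test_excluded_is_exactly_failures_union(self, maps_and_phantom):
        """Within brain, a voxel is excluded iff it has no fitted ktrans."""
        maps, _, _, masks, _, _ = maps_and_phantom
        brain = masks["brain"].data.astype(bool)
        excluded = maps.excluded.data.astype(bool)
        fitted = np.isfinite(maps.ktrans.data)
        assert not (excluded & fitted).any()
        np.testing.assert_array_equal(excluded[brain], ~fitted[brain])
        assert not excluded[~brain].any() and not fitted[~brain].any()

    def test_rerun_bit_identical(self, maps_and_phantom, small_tofts_phantom):
        maps, series, _, masks, aif, cfg = maps_and_phantom
        _, t10, _, _ = small_tofts_phantom
        again = compute_parameter_maps(series, t10, aif, masks, cfg)
        np.testing.assert_array_equal(maps.ktrans.data, again.ktrans.data)
        np.testing.assert_array_equal(maps.excluded.data, again.excluded.data)
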