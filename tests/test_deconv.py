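"""Block-circulant SVD deconvolution and the interpolated-mCTP baseline."""

import numpy as np
import pytest

from mctperf.containers import KAPPA, AIFModel, CTPSeries, MCTPTriplet
from mctperf.deconv import (
    DeconvConfig,
    baseline_bsvd_mctp,
    bsvd_deconvolve,
    extract_global_curve,
    maps_from_residue,
    reference_maps,
)
from mctperf.phantom import gamma_variate, tissue_curve

DT = 0.5


@pytest.fixture(scope="module")
def noiseless_cfg():
    return DeconvConfig(dt=DT, lambda_svd=DeconvConfig.NOISELESS_LAMBDA)


def _maps(k, aif, ct, mask=None):
    mask = np.ones((1, 1, 1), bool) if mask is None else mask
    return maps_from_residue(
        k.reshape(-1, 1, 1, 1), aif, ct.reshape(-1, 1, 1, 1), DT, mask
    )


class TestExtractGlobalCurve:
    def test_single_voxel_roi_is_that_curve_baseline_subtracted(self, noiseless_series):
        roi = np.array([[0, 32, 32]])
        curve = extract_global_curve(noiseless_series, roi)
        raw = noiseless_series.data[:, 0, 32, 32]
        assert np.allclose(curve, raw - raw[0])
        assert curve[0] == 0.0

    def test_two_voxel_roi_is_mean_of_curves(self, noiseless_series):
        a = extract_global_curve(noiseless_series, np.array([[0, 30, 30]]))
        b = extract_global_curve(noiseless_series, np.array([[0, 34, 34]]))
        ab = extract_global_curve(noiseless_series, np.array([[0, 30, 30], [0, 34, 34]]))
        assert np.allclose(ab, (a + b) / 2)

    def test_empty_roi_rejected(self, noiseless_series):
        with pytest.raises(ValueError):
            extract_global_curve(noiseless_series, np.empty((0, 3), dtype=int))

    def test_out_of_volume_roi_rejected(self, noiseless_series):
        with pytest.raises(ValueError):
            extract_global_curve(noiseless_series, np.array([[5, 0, 0]]))


class TestBsvdDeconvolve:
    def test_self_deconvolution_gives_discrete_delta(self, aif_curve, noiseless_cfg):
        k = bsvd_deconvolve(aif_curve[:, None], aif_curve, noiseless_cfg)[:, 0]
        assert k[0] * DT == pytest.approx(1.0, abs=1e-6)
        assert np.abs(k[1:]).max() * DT < 1e-6

    @pytest.mark.parametrize("m", [3, 8, 16])
    def test_delayed_copy_recovers_shift(self, aif_curve, noiseless_cfg, m):
        ct = np.zeros_like(aif_curve)
        ct[m:] = aif_curve[: len(aif_curve) - m]
        k = bsvd_deconvolve(ct[:, None], aif_curve, noiseless_cfg)[:, 0]
        assert np.argmax(k) * DT == m * DT

    def test_box_voxel_recovers_cbf_and_delay(self, aif_curve, noiseless_cfg):
        ct = tissue_curve(aif_curve, 60.0, 4.0, 2.0, DT)
        k = bsvd_deconvolve(ct[:, None], aif_curve, noiseless_cfg)[:, 0]
        assert k.max() == pytest.approx(60.0 / KAPPA, rel=0.10)
        m = _maps(k, aif_curve, ct)
        assert m.cbf.ravel()[0] == pytest.approx(60.0, rel=0.10)
        assert m.tmax.ravel()[0] == 2.0

    def test_all_zero_aif_rejected(self, noiseless_cfg):
        with pytest.raises(ValueError):
            bsvd_deconvolve(np.ones((10, 1)), np.zeros(10), noiseless_cfg)

    def test_scale_equivariance(self, aif_curve):
        cfg = DeconvConfig(dt=DT)
        ct = tissue_curve(aif_curve, 60.0, 4.0, 2.0, DT)
        k1 = bsvd_deconvolve(ct[:, None], aif_curve, cfg)[:, 0]
        k3 = bsvd_deconvolve(3 * ct[:, None], aif_curve, cfg)[:, 0]
        assert k3.max() / k1.max() == pytest.approx(3.0, rel=1e-9)
        assert np.argmax(k3) == np.argmax(k1)

    def test_delay_equivariance_of_maps(self, aif_curve):
        # shifting tissue by m samples adds m*dt to Tmax, CBF within 5%
        cfg = DeconvConfig(dt=DT)
        ct = tissue_curve(aif_curve, 60.0, 4.0, 2.0, DT)
        m = 4
        ct_shift = np.zeros_like(ct)
        ct_shift[m:] = ct[:-m]
        k1 = bsvd_deconvolve(ct[:, None], aif_curve, cfg)[:, 0]
        k2 = bsvd_deconvolve(ct_shift[:, None], aif_curve, cfg)[:, 0]
        t1 = _maps(k1, aif_curve, ct).tmax.ravel()[0]
        t2 = _maps(k2, aif_curve, ct_shift).tmax.ravel()[0]
        assert t2 - t1 == pytest.approx(m * DT, abs=1e-9)
        assert k2.max() == pytest.approx(k1.max(), rel=0.05)


class TestMapsFromResidue:
    def test_zero_residue_gives_zero_maps(self, aif_curve):
        k = np.zeros(len(aif_curve))
        m = _maps(k, aif_curve, np.zeros_like(aif_curve))
        assert m.cbf.ravel()[0] == 0.0
        assert m.tmax.ravel()[0] == 0.0

    def test_delta_residue_tmax_reads_sample_position(self, aif_curve):
        k = np.zeros(len(aif_curve))
        k[4] = 2.0
        m = _maps(k, aif_curve, np.zeros_like(aif_curve))
        assert m.tmax.ravel()[0] == 2.0

    def test_central_volume_consistency(self, aif_curve, noiseless_cfg):
        # CBV / CBF (converted to per-second flow) ~ MTT on a noiseless voxel
        cbf, mtt = 50.0, 5.0
        ct = tissue_curve(aif_curve, cbf, mtt, 1.0, DT)
        k = bsvd_deconvolve(ct[:, None], aif_curve, noiseless_cfg)[:, 0]
        m = _maps(k, aif_curve, ct)
        mtt_est = m.mtt.ravel()[0]
        assert mtt_est == pytest.approx(mtt, rel=0.10)


def _piecewise_linear_series(times):
    """A tiny series whose voxel curves are linear between the given knots."""
    rng = np.random.default_rng(4)
    knots = rng.uniform(0, 40, size=(len(times), 1, 4, 4))
    knots[0] = 0.0
    aif_v = np.interp(times, [0, 10, 14, 40], [0, 0, 120, 5])
    data = knots + 30.0
    data[:, 0, 1, 1] = 30.0 + aif_v  # AIF voxel
    return CTPSeries(
        data=data,
        frame_times=times,
        aif_roi=np.array([[0, 1, 1]]),
        brain_mask=np.ones((1, 4, 4), bool),
    )


class TestBaselineBsvdMctp:
    def test_piecewise_linear_series_reconstructed_exactly(self, noiseless_cfg):
        # when curves really are linear between the 4 chosen times, the
        # 4-point baseline equals the full-series reference
        times = np.arange(0.0, 28.5, DT)
        s = _piecewise_linear_series(times)
        pick = [14.0, 20.0, 28.0]
        idx = [np.searchsorted(times, p) for p in pick]
        tri = MCTPTriplet(
            phase_images=s.data[idx], phase_times=np.array(pick), shift_label="Peak"
        )
        # rebuild the series with linear segments between the knots only
        knot_t = np.array([0.0] + pick)
        knot_v = s.data[[0] + idx]
        lin = np.empty_like(s.data)
        for i, t in enumerate(times):
            j = np.clip(np.searchsorted(knot_t, t, side="right") - 1, 0, 2)
            w = (t - knot_t[j]) / (knot_t[j + 1] - knot_t[j])
            lin[i] = (1 - w) * knot_v[j] + w * knot_v[j + 1]
        s_lin = CTPSeries(
            data=lin, frame_times=times, aif_roi=s.aif_roi, brain_mask=s.brain_mask
        )
        ref = reference_maps(s_lin, noiseless_cfg, mask=s.brain_mask)
        base = baseline_bsvd_mctp(
            tri, s_lin.data[0], times, noiseless_cfg, s.aif_roi, s.brain_mask
        )
        assert np.allclose(base.cbf, ref.cbf, atol=1e-6)
        assert np.allclose(base.tmax, ref.tmax)

    def test_non_monotone_phase_times_rejected(self, noiseless_cfg):
        with pytest.raises(ValueError):
            MCTPTriplet(
                phase_images=np.zeros((3, 1, 4, 4)),
                phase_times=np.array([14.0, 12.0, 20.0]),
            )

    def test_triplet_outside_grid_rejected(self, noiseless_cfg):
        tri = MCTPTriplet(
            phase_images=np.zeros((3, 1, 4, 4)),
            phase_times=np.array([14.0, 20.0, 28.0]),
        )
        with pytest.raises(ValueError):
            baseline_bsvd_mctp(
                tri,
                np.zeros((1, 4, 4)),
                np.arange(0, 20, DT),
                noiseless_cfg,
                np.array([[0, 1, 1]]),
                np.ones((1, 4, 4), bool),
            )


class TestReferenceMaps:
    def test_nonuniform_grid_rejected(self, noiseless_series):
        with pytest.raises(ValueError):
            reference_maps(noiseless_series, mask=noiseless_series.brain_mask)

    def test_recovers_phantom_contrasts(self, phantom, noiseless_series):
        from mctperf.preprocess import interpolate_time

        s = interpolate_time(noiseless_series, DT)
        maps = reference_maps(s, DeconvConfig(dt=DT), mask=phantom.brain_mask)
        healthy = phantom.brain_mask & ~phantom.hypo_mask
        for roi in (s.aif_roi, s.vof_roi):
            healthy[roi[:, 0], roi[:, 1], roi[:, 2]] = False
        # lesion Tmax above threshold, healthy below
        assert np.median(maps.tmax[phantom.hypo_mask]) > 6.0
        assert np.median(maps.tmax[healthy]) < 6.0
        # core flow well below healthy flow
        assert np.median(maps.cbf[phantom.core_mask]) < 0.5 * np.median(
            maps.cbf[healthy]
        )
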