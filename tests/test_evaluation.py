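"""Similarity metrics, lesion volumetrics, and agreement statistics."""

import numpy as np
import pytest

from mctperf.containers import PerfusionMaps
from mctperf.evaluation import (
    RandomFilterBank,
    acquisition_dose_fraction,
    band_icc,
    band_scc,
    bland_altman,
    dice,
    icc,
    lesion_volume,
    mismatch_ratio,
    nrmse,
    perceptual_distance,
    reference_cbf,
    round_half_up,
    scc,
    segment_lesions,
    ssim,
)

RNG = np.random.default_rng(0)


class TestNrmse:
    def test_identity_is_zero(self):
        ref = RNG.normal(50, 10, (16, 16))
        assert nrmse(ref, ref) == 0.0

    def test_constant_offset_of_c_times_range_gives_c(self):
        ref = RNG.uniform(0, 100, (16, 16))
        c = 0.1
        pred = ref + c * (ref.max() - ref.min())
        assert nrmse(pred, ref) == pytest.approx(c, rel=1e-9)

    def test_not_symmetric_when_ranges_differ(self):
        ref = np.array([[0.0, 1.0]])
        pred = np.array([[0.0, 10.0]])
        assert nrmse(pred, ref) != nrmse(ref, pred)

    def test_constant_reference_rejected(self):
        with pytest.raises(ValueError):
            nrmse(RNG.normal(size=(4, 4)), np.ones((4, 4)))


class TestSsim:
    def test_identity_is_one(self):
        ref = RNG.normal(50, 10, (32, 32))
        assert ssim(ref, ref, data_range=ref.max() - ref.min()) == pytest.approx(1.0)

    def test_anticorrelated_patch_has_negative_structure(self):
        # zero LOCAL mean (checkerboard), so the negative covariance term
        # is not cancelled by a sign flip of the luminance term
        yy, xx = np.mgrid[0:16, 0:16]
        ref = ((yy + xx) % 2 * 2 - 1).astype(float)
        assert ssim(-ref, ref, data_range=4.0) < 0

    def test_symmetric_with_shared_data_range(self):
        a = RNG.normal(50, 5, (16, 16))
        b = a + RNG.normal(0, 2, (16, 16))
        assert ssim(a, b, data_range=30.0) == pytest.approx(
            ssim(b, a, data_range=30.0)
        )

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            ssim(np.zeros((4, 4)), np.ones((4, 4)), data_range=1.0, win_size=7)


class TestPerceptualDistance:
    def test_identity_is_zero_and_positive_otherwise(self):
        a = RNG.normal(0, 1, (32, 32))
        assert perceptual_distance(a, a) == 0.0
        assert perceptual_distance(a, a + 0.5) > 0

    def test_symmetric(self):
        a = RNG.normal(0, 1, (32, 32))
        b = RNG.normal(0, 1, (32, 32))
        assert perceptual_distance(a, b) == pytest.approx(perceptual_distance(b, a))

    def test_monotone_under_increasing_noise(self):
        base = RNG.normal(0, 1, (32, 32))
        noise = np.random.default_rng(7).normal(0, 1, (32, 32))
        d = [perceptual_distance(base + s * noise, base) for s in (0.2, 0.6, 1.5)]
        assert d[0] < d[1] < d[2]

    def test_pluggable_extractor(self):
        a = RNG.normal(0, 1, (16, 16))
        bank = RandomFilterBank(n_filters=4, scales=(1, 2), seed=3)
        assert perceptual_distance(a, a + 1.0, extractor=bank) > 0


class TestLesionSegmentation:
    def _maps(self, cbf, tmax, mask):
        return PerfusionMaps(
            cbf=cbf, tmax=tmax, brain_mask=mask, provenance="reference-bsvd"
        )

    def test_healthy_phantom_gives_empty_masks(self):
        mask = np.ones((1, 8, 8), bool)
        maps = self._maps(np.full((1, 8, 8), 60.0), np.full((1, 8, 8), 2.0), mask)
        lm = segment_lesions(maps, reference_cbf_value=60.0)
        assert lm.core.sum() == 0 and lm.hypoperfusion.sum() == 0

    def test_rcbf_threshold_is_strict(self):
        mask = np.ones((1, 1, 2), bool)
        cbf = np.array([[[0.29 * 60, 0.31 * 60]]])
        maps = self._maps(cbf, np.zeros((1, 1, 2)), mask)
        lm = segment_lesions(maps, 60.0)
        assert lm.core[0, 0, 0] and not lm.core[0, 0, 1]

    def test_thresholds_applied_independently(self):
        # a voxel can be core without being hypoperfused (Tmax <= 6 s)
        mask = np.ones((1, 1, 1), bool)
        maps = self._maps(np.array([[[5.0]]]), np.array([[[3.0]]]), mask)
        lm = segment_lesions(maps, 60.0)
        assert lm.core[0, 0, 0] and not lm.hypoperfusion[0, 0, 0]

    def test_nonpositive_reference_rejected(self):
        mask = np.ones((1, 1, 1), bool)
        maps = self._maps(np.zeros((1, 1, 1)), np.zeros((1, 1, 1)), mask)
        with pytest.raises(ValueError):
            segment_lesions(maps, 0.0)


class TestReferenceCbf:
    def test_uniform_map_returns_value(self):
        mask = np.ones((1, 8, 8), bool)
        assert reference_cbf(np.full((1, 8, 8), 55.0), mask) == 55.0

    def test_median_robust_to_minority_contamination(self):
        region = np.ones((1, 4, 4), bool)
        cbf = np.full((1, 4, 4), 60.0)
        cbf[0, 0, :3] = 1000.0  # 3 of 16 outliers
        assert reference_cbf(cbf, region, region=region) == 60.0

    def test_mirrored_hemisphere_excludes_lesioned_side(self):
        mask = np.ones((1, 8, 8), bool)
        cbf = np.full((1, 8, 8), 60.0)
        cbf[:, :, 4:] = 15.0  # lesion fills the right hemisphere
        assert reference_cbf(cbf, mask) == 60.0

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            reference_cbf(np.zeros((1, 2, 2)), np.zeros((1, 2, 2), bool))


class TestVolumesAndRatio:
    def test_empty_mask_is_zero_ml(self):
        assert lesion_volume(np.zeros((2, 4, 4), bool), (5.0, 1.0, 1.0)) == 0.0

    def test_thousand_voxels_at_5mm3_is_5ml(self):
        mask = np.zeros((1, 40, 40), bool)
        mask.ravel()[:1000] = True
        assert lesion_volume(mask, (5.0, 1.0, 1.0)) == 5.0

    def test_additive_over_disjoint_masks(self):
        a = np.zeros((1, 4, 4), bool)
        b = np.zeros((1, 4, 4), bool)
        a[0, 0], b[0, 2] = True, True
        sp = (5.0, 1.0, 1.0)
        assert lesion_volume(a | b, sp) == lesion_volume(a, sp) + lesion_volume(b, sp)

    def test_equal_volumes_give_unit_ratio(self):
        assert mismatch_ratio(12.5, 12.5) == 1.0

    def test_zero_core_rejected(self):
        with pytest.raises(ValueError):
            mismatch_ratio(10.0, 0.0)

    def test_rounding_is_half_up(self):
        assert round_half_up(0.25, 1) == 0.3
        assert round_half_up(0.24999, 1) == 0.2


class TestDice:
    def test_identical_nonempty_is_one(self):
        m = np.zeros((4, 4), bool)
        m[1:3] = True
        assert dice(m, m) == 1.0

    def test_disjoint_nonempty_is_zero(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0], b[2] = True, True
        assert dice(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros(200, bool)
        b = np.zeros(200, bool)
        a[:100] = True
        b[50:150] = True
        assert dice(a.reshape(10, 20), b.reshape(10, 20)) == 0.5

    def test_symmetric_and_empty_convention(self):
        a = RNG.random((6, 6)) > 0.5
        b = RNG.random((6, 6)) > 0.5
        assert dice(a, b) == dice(b, a)
        assert dice(np.zeros((2, 2), bool), np.zeros((2, 2), bool)) == 1.0


class TestBlandAltman:
    def test_identical_vectors_give_zero_band(self):
        v = np.array([1.0, 2.0, 3.0])
        assert bland_altman(v, v) == (0.0, 0.0, 0.0)

    def test_hand_computed_two_pair_case(self):
        # d = {-1, +1}: mean 0, sd (n-1) = sqrt(2), LoA = +-1.96*sqrt(2)
        m, lo, hi = bland_altman(np.array([0.0, 2.0]), np.array([1.0, 1.0]))
        assert m == 0.0
        assert hi == pytest.approx(1.96 * np.sqrt(2))
        assert lo == pytest.approx(-1.96 * np.sqrt(2))

    def test_translation_equivariance(self):
        pred = np.array([3.0, 5.0, 9.0, 12.0])
        ref = np.array([2.0, 6.0, 8.0, 13.0])
        m0, lo0, hi0 = bland_altman(pred, ref)
        m1, lo1, hi1 = bland_altman(pred + 4.0, ref)
        assert (m1 - m0, lo1 - lo0, hi1 - hi0) == pytest.approx((4.0, 4.0, 4.0))

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [2.0])

    def test_plot_draws_limit_lines(self):
        import matplotlib

        matplotlib.use("Agg")
        from mctperf.evaluation import plot_bland_altman

        ax = plot_bland_altman([3.0, 5.0, 9.0], [2.0, 6.0, 8.0])
        assert len(ax.lines) == 3  # mean difference + two limits


class TestIcc:
    PRED = np.array([10.0, 12.0, 18.0, 25.0, 31.0, 40.0])
    REF = np.array([11.0, 14.0, 17.0, 27.0, 30.0, 42.0])

    def test_perfect_agreement_is_one(self):
        v = np.array([1.0, 5.0, 9.0, 13.0])
        assert icc(v, v)[0] == pytest.approx(1.0)

    def test_six_pair_table_matches_mean_squares_arithmetic(self):
        # independent oracle: explicit two-way ANOVA decomposition
        data = np.column_stack([self.PRED, self.REF])
        n, k = data.shape
        grand = data.mean()
        msr = k * ((data.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((data.mean(axis=0) - grand) ** 2).sum() / (k - 1)
        mse = (
            (data - data.mean(axis=1, keepdims=True) - data.mean(axis=0) + grand) ** 2
        ).sum() / ((n - 1) * (k - 1))
        expect = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        value, lo, hi = icc(self.PRED, self.REF)
        assert value == pytest.approx(expect)
        # frozen from the same arithmetic (and pingouin's ICC(A,1))
        assert value == pytest.approx(0.990799, abs=1e-6)
        assert lo < value < hi

    def test_matches_pingouin_two_way_random_absolute(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        df = pd.DataFrame(
            {
                "t": list(range(6)) * 2,
                "r": ["p"] * 6 + ["r"] * 6,
                "s": np.concatenate([self.PRED, self.REF]),
            }
        )
        res = pg.intraclass_corr(df, targets="t", raters="r", ratings="s")
        mask = res["Type"].isin(["ICC2", "ICC(A,1)"])  # label differs by version
        expect = res.loc[mask, "ICC"].iloc[0]
        assert icc(self.PRED, self.REF)[0] == pytest.approx(expect, abs=1e-9)

    def test_constant_bias_penalized_below_pearson(self):
        biased = self.REF + 20.0
        value = icc(biased, self.REF)[0]
        pearson = np.corrcoef(biased, self.REF)[0, 1]
        assert value < pearson
        assert pearson == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            icc(np.ones(4), np.ones(4))


class TestScc:
    def test_monotone_transform_has_unit_rank_correlation(self):
        ref = np.array([3.0, 7.0, 1.0, 9.0, 4.0])
        pred = np.exp(ref / 3.0)  # strictly monotone transform
        rho, p = scc(pred, ref)
        assert rho == pytest.approx(1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            scc(np.ones(4), np.arange(4.0))


class TestInterpretationBands:
    @pytest.mark.parametrize(
        "value,band",
        [
            (0.883, "good"),
            (0.499, "poor"),
            (0.731, "moderate"),
            (0.50, "moderate"),
            (0.75, "good"),
            (0.90, "good"),
            (0.91, "excellent"),
        ],
    )
    def test_icc_bands(self, value, band):
        assert band_icc(value) == band

    @pytest.mark.parametrize(
        "rho,band",
        [
            (0.808, "excellent"),
            (0.720, "strong"),
            (0.80, "excellent"),
            (0.60, "strong"),
            (0.40, "moderate"),
            (0.39, "weak"),
        ],
    )
    def test_scc_bands(self, rho, band):
        assert band_scc(rho) == band


class TestDoseFraction:
    def test_three_of_nineteen_phases(self):
        assert acquisition_dose_fraction(3, 19) == 15.8

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            acquisition_dose_fraction(3, 0)
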