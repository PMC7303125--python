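"""Segmentation, adiposity, SUV, gamma-count normalization and morphometry."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bmatquant import synthetic as syn
from bmatquant.errors import ConfigurationError, EmptyRegionError
from bmatquant.quantify import (
    F18_HALF_LIFE_MIN,
    GammaSample,
    MarrowClass,
    SUVParams,
    adiposity_fraction,
    classify_hu,
    classify_hu_codes,
    compartment_suv,
    decay_correct,
    morphometry,
    percent_id_per_g,
    segment_bm,
    suv_map,
)
from bmatquant.thresholds import ThresholdScheme
from bmatquant.volumes import VOIMask, VoxelVolume


def make_voi(hu_values, spacing=(1.0, 1.0, 1.0)):
    """A volume whose single region contains exactly ``hu_values``."""
    hu = np.asarray(hu_values, dtype=np.int32)
    n = hu.size
    ct = VoxelVolume(hu.reshape(n, 1, 1), spacing)
    labels = np.ones((n, 1, 1), dtype=np.int32)
    return ct, VOIMask(labels, {1: "bm"}, spacing)


class TestClassifyHu:
    @pytest.mark.parametrize(
        "hu,expected",
        [
            (114, MarrowClass.BMAT),
            (115, MarrowClass.RM),
            (300, MarrowClass.RM),
            (301, MarrowClass.BONE),
            (-200, MarrowClass.BMAT),
            (-201, MarrowClass.OUT_OF_RANGE),
        ],
    )
    def test_boundary_inclusivity(self, hu, expected):
        assert classify_hu(hu) is expected

    @given(
        hu=st.integers(-2000, 3000),
        lo=st.integers(-300, -100),
        mid=st.integers(0, 200),
        hi=st.integers(250, 500),
    )
    def test_agrees_with_interval_lookup(self, hu, lo, mid, hi):
        scheme = ThresholdScheme(lo, mid, hi)
        if hu < lo:
            expected = MarrowClass.OUT_OF_RANGE
        elif hu < mid:
            expected = MarrowClass.BMAT
        elif hu <= hi:
            expected = MarrowClass.RM
        else:
            expected = MarrowClass.BONE
        assert classify_hu(hu, scheme) is expected


class TestSegmentation:
    def test_eight_voxel_hand_classification(self):
        ct, mask = make_voi([-250, -100, 0, 114, 115, 250, 300, 301])
        seg = segment_bm(ct, mask, region="bm")
        counts = seg.counts
        assert counts[MarrowClass.BMAT] == 3
        assert counts[MarrowClass.RM] == 3
        assert counts[MarrowClass.BONE] == 1
        assert counts[MarrowClass.OUT_OF_RANGE] == 1

    def test_uniform_voi_is_all_bmat(self):
        ct, mask = make_voi([50] * 20)
        seg = segment_bm(ct, mask, region="bm")
        assert seg.counts[MarrowClass.BMAT] == 20

    def test_permutation_invariance_of_counts(self):
        rng = np.random.default_rng(0)
        hu = rng.integers(-300, 400, 500)
        a = segment_bm(*make_voi(hu), region="bm").counts
        b = segment_bm(*make_voi(rng.permutation(hu)), region="bm").counts
        assert a == b

    @given(hu=st.lists(st.integers(-1500, 2000), min_size=1, max_size=300))
    def test_class_counts_conserve_voi_size(self, hu):
        seg = segment_bm(*make_voi(hu), region="bm")
        assert sum(seg.counts.values()) == len(hu)

    def test_empty_voi_rejected(self):
        ct, _ = make_voi([50])
        empty = VOIMask(np.zeros((1, 1, 1), np.int32) , {1: "bm"}, ct.spacing)
        with pytest.raises(EmptyRegionError):
            segment_bm(ct, empty, region="bm")


class TestAdiposity:
    def test_hand_classified_fraction(self):
        ct, mask = make_voi([-250, -100, 0, 114, 115, 250, 300, 301])
        result = adiposity_fraction(segment_bm(ct, mask, region="bm"))
        assert result.ad_v_over_ma_v_pct == pytest.approx(37.5)

    def test_all_bmat_is_100pct(self):
        ct, mask = make_voi([0] * 10)
        assert adiposity_fraction(segment_bm(ct, mask, region="bm")).ad_v_over_ma_v_pct == 100.0

    def test_out_of_range_stays_in_denominator_by_default(self):
        ct, mask = make_voi([-500, 0])
        seg = segment_bm(ct, mask, region="bm")
        assert adiposity_fraction(seg).ad_v_over_ma_v_pct == pytest.approx(50.0)
        restricted = adiposity_fraction(seg, include_out_of_range_in_denominator=False)
        assert restricted.ad_v_over_ma_v_pct == pytest.approx(100.0)

    def test_phantom_70pct_recovers_to_integer_70(self, default_phantom):
        ct, _, masks, _ = default_phantom
        result = adiposity_fraction(segment_bm(ct, masks, region="bm"))
        # expected classified fraction ~ 0.7*Phi(2.42) + 0.3*(1-Phi(2.45)) ~ 69.7%
        assert round(result.ad_v_over_ma_v_pct) == 70

    @pytest.mark.parametrize("scale", [0.2, 1.0, 3.7])
    def test_scale_invariance_of_fraction_and_volume_scaling(self, scale):
        hu = np.random.default_rng(1).integers(-300, 400, 200)
        base = adiposity_fraction(segment_bm(*make_voi(hu), region="bm"))
        scaled = adiposity_fraction(
            segment_bm(*make_voi(hu, spacing=(scale, scale, scale)), region="bm")
        )
        assert scaled.ad_v_over_ma_v_pct == pytest.approx(base.ad_v_over_ma_v_pct)
        for cls in MarrowClass:
            assert scaled.class_volumes_ml[cls] == pytest.approx(
                base.class_volumes_ml[cls] * scale**3
            )


class TestDecayAndGamma:
    def test_one_half_life_doubles_activity(self):
        assert decay_correct(0.5, F18_HALF_LIFE_MIN) == pytest.approx(1.0)

    def test_zero_elapsed_is_identity(self):
        assert decay_correct(0.75, 0.0) == 0.75

    def test_two_half_lives_quadruple(self):
        assert decay_correct(1.0, 219.54, 109.77) == pytest.approx(4.0)

    def test_negative_elapsed_rejected(self):
        with pytest.raises(ConfigurationError):
            decay_correct(1.0, -10.0)

    def test_percent_id_per_g_arithmetic(self):
        # 0.02 MBq (no decay needed), dose 10 MBq, mass 0.1 g -> 2 %ID/g
        sample = GammaSample(2000.0, 1e-5, 0.1, 0.0)
        assert percent_id_per_g(sample, 10.0) == pytest.approx(2.0)

    def test_whole_dose_in_one_gram(self):
        sample = GammaSample(1.0, 5.0, 1.0, 0.0)
        assert percent_id_per_g(sample, 5.0) == pytest.approx(100.0)

    def test_mass_proportionality(self):
        a = percent_id_per_g(GammaSample(100.0, 1e-4, 0.1, 30.0), 8.0)
        b = percent_id_per_g(GammaSample(100.0, 1e-4, 0.2, 30.0), 8.0)
        assert a == pytest.approx(2 * b)

    def test_decay_correction_applied_to_counts(self):
        no_decay = percent_id_per_g(GammaSample(100.0, 1e-4, 1.0, 0.0), 10.0)
        one_tau = percent_id_per_g(GammaSample(100.0, 1e-4, 1.0, F18_HALF_LIFE_MIN), 10.0)
        assert one_tau == pytest.approx(2 * no_decay)


class TestSUV:
    def test_uniform_concentration_fixed_point(self):
        # concentration = dose/body-mass everywhere -> SUV 1.0
        params = SUVParams(injected_dose_mbq=185.0, body_mass_g=60_000.0)
        conc = 185.0 * 1000 / 60_000.0  # kBq/mL
        pet = VoxelVolume(np.full((4, 4, 4), conc), (1, 1, 1), modality="PET")
        np.testing.assert_allclose(suv_map(pet, params), 1.0)

    def test_known_concentration(self):
        params = SUVParams(injected_dose_mbq=185.0, body_mass_g=60_000.0)
        pet = VoxelVolume(np.full((2, 2, 2), 5.0), (1, 1, 1), modality="PET")
        assert suv_map(pet, params)[0, 0, 0] == pytest.approx(5.0 / (185_000 / 60_000))

    def test_empty_class_absent_from_report(self):
        ct, mask = make_voi([50, 120])  # BMAT + RM, no bone
        seg = segment_bm(ct, mask, region="bm")
        pet = VoxelVolume(np.ones((2, 1, 1), np.float32), (1, 1, 1), modality="PET")
        suvs = compartment_suv(pet, seg, SUVParams(10.0, 1000.0))
        assert MarrowClass.BONE not in suvs
        assert set(suvs) == {MarrowClass.BMAT, MarrowClass.RM}

    def test_invalid_params_rejected(self):
        with pytest.raises(ConfigurationError):
            SUVParams(injected_dose_mbq=0.0, body_mass_g=100.0)
        with pytest.raises(ConfigurationError):
            SUVParams(injected_dose_mbq=1.0, body_mass_g=100.0, measurement_time_min=-5.0)


class TestMorphometry:
    def test_density_and_area_fraction(self):
        ann = syn.AdipocyteAnnotationSet(
            marrow_area_mm2=2.0,
            adipocytes=[syn.Adipocyte(0.05, 0) for _ in range(10)],
        )
        result = morphometry(ann)
        assert result.n_ad_per_marrow_area == pytest.approx(5.0)
        assert result.ad_area_fraction_pct == pytest.approx(25.0)

    @pytest.mark.parametrize("droplets,is_multi", [(2, False), (3, True), (7, True), (0, False)])
    def test_multilocular_rule_three_or_more(self, droplets, is_multi):
        ann = syn.AdipocyteAnnotationSet(1.0, [syn.Adipocyte(0.01, droplets)])
        assert (morphometry(ann).multilocular_count == 1) is is_multi

    def test_zero_marrow_area_rejected(self):
        with pytest.raises(ConfigurationError):
            morphometry(syn.AdipocyteAnnotationSet(0.0, []))

    def test_generated_annotations_multilocular_fraction(self):
        ann = syn.generate_adipocyte_annotations(6, 4, marrow_area_mm2=5.0, seed=1)
        result = morphometry(ann)
        assert result.multilocular_count == 4
        assert result.multilocular_fraction == pytest.approx(0.4)
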