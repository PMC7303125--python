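"""HU histograms, ROC analysis and cutpoint derivation.

The ROC implementation is checked against two independent oracles: an
exhaustive per-threshold enumeration, and the Mann-Whitney pair-counting
estimate of the AUC.
"""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bmatquant import synthetic as syn
from bmatquant.errors import ConfigurationError, EmptyRegionError, RegionLookupError
from bmatquant.thresholds import (
    ThresholdScheme,
    build_histogram,
    compute_roc,
    extract_voi_hu,
    optimal_threshold,
    summarize_cohort,
)


def brute_force_roc(pos, neg, grid):
    """Oracle: evaluate sens/spec at each threshold by direct counting."""
    rows = []
    for t in grid:
        sens = sum(1 for x in pos if x < t) / len(pos)
        spec = sum(1 for x in neg if x >= t) / len(neg)
        rows.append((t, sens, spec, sens + spec - 1))
    return rows


def brute_force_best(pos, neg, grid):
    rows = brute_force_roc(pos, neg, grid)
    best_j = max(r[3] for r in rows)
    return next(t for t, _, _, j in rows if j == best_j)


def mann_whitney_auc(pos, neg):
    """Oracle: AUC = P(pos < neg) + 0.5 P(pos == neg) by pair counting."""
    wins = sum(1 for p in pos for n in neg if p < n)
    ties = sum(1 for p in pos for n in neg if p == n)
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestExtractVoiHu:
    def test_sample_length_equals_region_size(self, default_phantom):
        ct, _, masks, _ = default_phantom
        assert extract_voi_hu(ct, masks, "bm").size == 100_000

    def test_unknown_region_named_in_error(self, default_phantom):
        ct, _, masks, _ = default_phantom
        with pytest.raises(RegionLookupError, match="femur"):
            extract_voi_hu(ct, masks, "femur")

    def test_constant_region(self):
        from bmatquant.volumes import VOIMask, VoxelVolume

        ct = VoxelVolume(np.full((3, 3, 3), 42, np.int32), (1, 1, 1))
        labels = np.zeros((3, 3, 3), np.int32)
        labels[0] = 1
        sample = extract_voi_hu(ct, VOIMask(labels, {1: "r"}, (1, 1, 1)), "r")
        assert set(sample) == {42} and sample.size == 9


class TestHistogram:
    def test_counts_per_bin(self):
        h = build_histogram(np.array([-10, -10, 20]), hu_range=(-50, 50))
        assert h.counts[h.values == -10][0] == 2
        assert h.counts[h.values == 20][0] == 1
        assert h.total_voxels == 3 and h.out_of_range_count == 0

    def test_out_of_range_counted_not_binned(self):
        h = build_histogram(np.array([0, 2000]), hu_range=(-500, 1500))
        assert h.counts.sum() == 1 and h.out_of_range_count == 1
        assert h.counts.sum() + h.out_of_range_count == h.total_voxels

    def test_modal_bin_near_distribution_mean(self):
        # raw 1-HU bin counts are multinomial-noisy, so smooth before taking
        # the mode; the smoothed mode of Normal(42, 30) sits at 42 +/- 2
        s = syn.sample_voxel_classes(100_000, 1, (42, 30), (0, 1), seed=5)
        h = build_histogram(s.pos)
        smoothed = np.convolve(h.counts, np.ones(21) / 21, mode="same")
        mode = h.values[np.argmax(smoothed)]
        assert abs(mode - 42) <= 2

    def test_empty_sample_rejected(self):
        with pytest.raises(EmptyRegionError):
            build_histogram(np.array([]))


class TestCohortSummary:
    def test_identical_subjects_have_zero_sem(self):
        h = build_histogram(np.array([1, 2, 2, 3]), hu_range=(0, 10))
        summary = summarize_cohort([h, h])
        assert np.all(summary.sem == 0)

    def test_mean_and_sem_two_subjects(self):
        # proportions 0.2 and 0.4 in the HU=5 bin: mean 0.3, SEM 0.1
        a = build_histogram(np.array([5, 0, 0, 0, 0]), hu_range=(0, 10))
        b = build_histogram(np.array([5, 5, 0, 0, 0]), hu_range=(0, 10))
        summary = summarize_cohort([a, b])
        i = np.flatnonzero(summary.values == 5)[0]
        assert summary.mean_proportion[i] == pytest.approx(0.3)
        assert summary.sem[i] == pytest.approx(0.1)

    def test_single_subject_rejected(self):
        h = build_histogram(np.array([1]), hu_range=(0, 10))
        with pytest.raises(ConfigurationError):
            summarize_cohort([h])

    def test_mismatched_grids_rejected(self):
        a = build_histogram(np.array([1]), hu_range=(0, 10))
        b = build_histogram(np.array([1]), hu_range=(0, 11))
        with pytest.raises(ConfigurationError):
            summarize_cohort([a, b])


class TestROC:
    def test_perfect_separation_toy_sets(self):
        pos, neg = [10, 50, 120], [130, 200, 250]
        roc = compute_roc(pos, neg)
        i = np.flatnonzero(roc.thresholds == 121)[0]
        assert roc.sensitivity[i] == 1.0 and roc.specificity[i] == 1.0
        assert roc.auc == 1.0
        assert optimal_threshold(roc) == 121  # lowest maximizer of J

    def test_identical_classes_auc_half(self):
        sample = [10, 20, 30, 40]
        assert compute_roc(sample, sample).auc == pytest.approx(0.5)

    def test_empty_class_rejected(self):
        with pytest.raises(EmptyRegionError):
            compute_roc([], [1, 2])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_enumeration_exactly(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.integers(-50, 150, size=rng.integers(3, 50))
        neg = rng.integers(50, 250, size=rng.integers(3, 50))
        roc = compute_roc(pos, neg)
        oracle = brute_force_roc(list(pos), list(neg), list(roc.thresholds))
        np.testing.assert_allclose(roc.sensitivity, [r[1] for r in oracle], atol=0)
        np.testing.assert_allclose(roc.specificity, [r[2] for r in oracle], atol=0)
        assert optimal_threshold(roc) == brute_force_best(list(pos), list(neg), list(roc.thresholds))

    @pytest.mark.parametrize("seed", range(3))
    def test_auc_equals_mann_whitney(self, seed):
        rng = np.random.default_rng(100 + seed)
        pos = rng.integers(0, 40, size=30)  # overlap and ties with neg
        neg = rng.integers(20, 60, size=25)
        roc = compute_roc(pos, neg)
        assert roc.auc == pytest.approx(mann_whitney_auc(list(pos), list(neg)), abs=1e-9)

    def test_monotonicity_of_sens_and_spec(self):
        s = syn.sample_voxel_classes(2000, 2000, (42, 30), (188, 30), seed=1)
        roc = compute_roc(s.pos, s.neg)
        assert np.all(np.diff(roc.sensitivity) >= 0)
        assert np.all(np.diff(roc.specificity) <= 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_gaussian_midpoint_recovery_bmat_rm(self, seed):
        # equal-variance Gaussians: Youden optimum = midpoint of means = 115
        s = syn.sample_voxel_classes(100_000, 100_000, (42, 30), (188, 30), seed=seed)
        assert abs(optimal_threshold(compute_roc(s.pos, s.neg)) - 115) <= 2

    def test_gaussian_midpoint_recovery_rm_bone(self):
        s = syn.sample_voxel_classes(100_000, 100_000, (188, 55), (412, 55), seed=0)
        assert abs(optimal_threshold(compute_roc(s.pos, s.neg)) - 300) <= 3

    def test_closest_topleft_criterion_also_near_midpoint(self):
        s = syn.sample_voxel_classes(50_000, 50_000, (42, 30), (188, 30), seed=2)
        roc = compute_roc(s.pos, s.neg)
        assert abs(optimal_threshold(roc, criterion="closest_topleft") - 115) <= 3


class TestThresholdScheme:
    def test_defaults_are_clinical_scheme(self):
        scheme = ThresholdScheme()
        assert (scheme.yellow_low, scheme.bmat_rm, scheme.rm_bone) == (-200, 115, 300)

    @given(
        a=st.integers(-400, 400), b=st.integers(-400, 400), c=st.integers(-400, 400)
    )
    def test_ordering_invariant_enforced(self, a, b, c):
        if a < b < c:
            ThresholdScheme(a, b, c)
        else:
            with pytest.raises(ConfigurationError):
                ThresholdScheme(a, b, c)
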