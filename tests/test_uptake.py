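"""ROI statistics, uptake ratios, quadrant construction and group statistics."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pulmoquant.datasets import load_animal_table, load_lesion_table
from pulmoquant.errors import RoiError, StatisticsError
from pulmoquant.registration import resample
from pulmoquant.uptake import (
    QUADRANT_NAMES,
    RoiDefinition,
    quadrant_rois,
    roi_stats,
    spearman_correlation,
    summarize_animal,
    tumour_to_nontumour_ratio,
    two_sample_tests,
)
from pulmoquant.volume import SegmentationMask, Volume3D


def _vol(data, spacing=(1.0, 1.0, 1.0)):
    return Volume3D(np.asarray(data, float), spacing, modality="PET")


class TestRoiStats:
    def test_constant_volume(self):
        vol = _vol(np.full((10, 10, 10), 3.5))
        s = roi_stats(vol, RoiDefinition("r", (5.0, 5.0, 5.0), 30.0))
        assert s.minimum == s.maximum == s.mean == pytest.approx(3.5)
        assert s.sd == 0.0

    def test_two_valued_region(self):
        data = np.ones((10, 10, 10))
        data[:5] = 3.0
        mask = SegmentationMask(np.ones((10, 10, 10), bool), (1, 1, 1))
        s = roi_stats(_vol(data), RoiDefinition("half", mask=mask))
        assert s.mean == pytest.approx(2.0)
        assert s.maximum == pytest.approx(3.0)
        assert s.minimum == pytest.approx(1.0)

    def test_lesion_sphere_discretization_on_pet_grid(self):
        """11.6 mm3 lesion ROI on the scanner's 0.39x0.39x0.76 mm grid.

        Voxel-centre counting realizes 95 voxels = 10.98 mm3 for a
        voxel-centred sphere (value frozen from a brute-force centre
        count); the realized volume stays within 10% of the target.
        """
        vol = Volume3D(np.ones((40, 40, 24)), (0.39, 0.39, 0.76), modality="PET")
        centre = vol.index_to_world((20, 20, 12))
        s = roi_stats(vol, RoiDefinition("lesion", tuple(centre), 11.6))

        # independent brute-force centre count
        r = (3 * 11.6 / (4 * math.pi)) ** (1 / 3)
        count = 0
        for i, j, k in itertools.product(range(40), range(40), range(24)):
            p = vol.index_to_world((i, j, k))
            if np.sum((p - centre) ** 2) <= r**2:
                count += 1
        assert s.voxel_count == count == 95
        assert s.volume_mm3 == pytest.approx(count * 0.39 * 0.39 * 0.76)
        assert s.volume_mm3 == pytest.approx(11.6, rel=0.10)

    def test_empty_roi_names_the_roi(self):
        vol = _vol(np.ones((10, 10, 10)))
        with pytest.raises(RoiError, match="tiny"):
            roi_stats(vol, RoiDefinition("tiny", (50.0, 50.0, 50.0), 0.001))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_min_mean_max_bracket(self, seed):
        rng = np.random.default_rng(seed)
        vol = _vol(rng.uniform(0, 10, size=(12, 12, 12)))
        s = roi_stats(vol, RoiDefinition("fuzz", (6.0, 6.0, 6.0), 50.0))
        assert s.minimum <= s.mean <= s.maximum
        assert s.sd >= 0


class TestRatios:
    def test_arithmetic(self):
        num = roi_stats(_vol(np.full((4, 4, 4), 5.0)),
                        RoiDefinition("lung", (2, 2, 2), 8.0))
        liv = roi_stats(_vol(np.full((4, 4, 4), 2.0)),
                        RoiDefinition("liver", (2, 2, 2), 8.0))
        assert tumour_to_nontumour_ratio(num, liv) == pytest.approx(2.5)

    def test_identical_rois_on_constant_volume_give_one(self):
        vol = _vol(np.full((6, 6, 6), 4.2))
        roi = RoiDefinition("r", (3, 3, 3), 20.0)
        s = roi_stats(vol, roi)
        assert tumour_to_nontumour_ratio(s, s) == pytest.approx(1.0)

    def test_zero_liver_mean_rejected(self):
        s = roi_stats(_vol(np.zeros((4, 4, 4))), RoiDefinition("liver", (2, 2, 2), 8.0))
        num = roi_stats(_vol(np.ones((4, 4, 4))), RoiDefinition("lung", (2, 2, 2), 8.0))
        with pytest.raises(RoiError, match="liver"):
            tumour_to_nontumour_ratio(num, s)

    def test_programmed_tumour_contrast_recovered(self, phantom_circumscribed_clean):
        """Phantom with 3.0 tumour:liver uptake, blur on, noise off."""
        truth = phantom_circumscribed_clean
        pet_on_ct = resample(truth.pet, truth.transform, truth.ct)
        liver = roi_stats(
            pet_on_ct,
            RoiDefinition("liver", tuple(truth.masks["liver"].centroid_world()), 11.9),
        )
        tum = roi_stats(
            pet_on_ct,
            RoiDefinition("tumour", tuple(truth.masks["tumour"].centroid_world()), 11.6),
        )
        ratio = tumour_to_nontumour_ratio(tum, liver)
        assert ratio == pytest.approx(truth.tumour_to_liver_ratio, rel=0.10)

    def test_ratio_invariant_under_global_rescaling(self, phantom_circumscribed_clean):
        truth = phantom_circumscribed_clean
        pet = resample(truth.pet, truth.transform, truth.ct)
        scaled = pet.with_data(pet.data * 37.5)
        liver_roi = RoiDefinition("liver", tuple(truth.masks["liver"].centroid_world()), 11.9)
        tum_roi = RoiDefinition("t", tuple(truth.masks["tumour"].centroid_world()), 11.6)
        r1 = tumour_to_nontumour_ratio(roi_stats(pet, tum_roi), roi_stats(pet, liver_roi))
        r2 = tumour_to_nontumour_ratio(roi_stats(scaled, tum_roi), roi_stats(scaled, liver_roi))
        assert r2 == pytest.approx(r1, rel=1e-12)


class TestQuadrants:
    def test_symmetric_lungs_give_mirror_symmetric_centres(self):
        """A perfectly mirror-symmetric two-lung mask yields mirror-
        symmetric quadrant centres (the phantom's own lungs are left-right
        asymmetric because of the cardiac carve-out, so a synthetic
        symmetric mask is used)."""
        n = 41  # odd: exact mirror axis on a voxel column
        ii, jj, kk = np.indices((n, 25, 31))
        right = ((ii - 12) / 7.0) ** 2 + ((jj - 12) / 8.0) ** 2 + ((kk - 15) / 11.0) ** 2 <= 1
        left = right[::-1]
        mask = SegmentationMask(right | left, (0.3, 0.3, 0.3))
        rois = quadrant_rois(mask)
        assert set(rois) == set(QUADRANT_NAMES)
        mid_x = mask.centroid_world()[0]
        for level in ("upper", "lower"):
            right = np.asarray(rois[f"right-{level}"].centre_mm)
            left = np.asarray(rois[f"left-{level}"].centre_mm)
            mirrored = left.copy()
            mirrored[0] = 2 * mid_x - left[0]
            assert np.all(np.abs(right - mirrored) < mask.spacing_mm[0] + 1e-9)

    def test_single_voxel_quadrants_degenerate_shrink(self):
        data = np.zeros((8, 8, 8), bool)
        for i, k in itertools.product((2, 5), (2, 5)):
            data[i, 4, k] = True
        rois = quadrant_rois(SegmentationMask(data, (1, 1, 1)), target_volume_mm3=3.5)
        vol = Volume3D(np.ones((8, 8, 8)), (1, 1, 1), modality="PET")
        for roi in rois.values():
            assert roi_stats(vol, roi).voxel_count == 1

    def test_one_sided_lung_rejected(self):
        data = np.zeros((8, 8, 8), bool)
        data[2, 3:5, 1:7] = True  # single sagittal slab
        with pytest.raises(RoiError, match="midsagittal"):
            quadrant_rois(SegmentationMask(data, (1, 1, 1)))

    def test_empty_quadrant_error_names_quadrant(self):
        data = np.zeros((8, 8, 8), bool)
        data[1:3, 3:5, 5:7] = True  # right side, upper only
        data[5:7, 3:5, 1:3] = True  # left side, lower only
        with pytest.raises(RoiError, match="right-lower"):
            quadrant_rois(SegmentationMask(data, (1, 1, 1)))


class TestAnimalSummary:
    def test_equal_quadrants_mean(self):
        rec = summarize_animal(
            "a1", "SPC-raf",
            {q: 1.3 for q in QUADRANT_NAMES},
            {q: 2.0 for q in QUADRANT_NAMES},
        )
        assert rec.lung_ratio_mean == pytest.approx(1.3)
        assert rec.histology_mean == pytest.approx(2.0)
        assert rec.tumour_ratio_mean is None

    def test_missing_quadrant_rejected(self):
        with pytest.raises(StatisticsError, match="right-upper"):
            summarize_animal(
                "a", "SPC-myc",
                {q: 1.0 for q in QUADRANT_NAMES[1:]},
                {q: 1.0 for q in QUADRANT_NAMES},
            )

    def test_study_group_means_match_published_summary(self):
        """Mean lung ratio over the six disseminated-tumour animals is 1.47;
        the mean over the five circumscribed lesions is 2.47-2.48."""
        animals = load_animal_table()
        raf = animals[animals.genotype == "SPC-raf"]
        assert raf.lung_ratio_mean.mean() == pytest.approx(1.47, abs=0.005)
        lesions = load_lesion_table()
        assert lesions.tumour_ratio.mean() == pytest.approx(2.478, abs=0.001)


class TestSpearman:
    def test_perfect_monotone(self):
        rho, _ = spearman_correlation([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)
        rho, _ = spearman_correlation([1, 2, 3, 4], [40, 30, 20, 10])
        assert rho == pytest.approx(-1.0)

    def test_constant_vector_undefined(self):
        with pytest.raises(StatisticsError, match="constant"):
            spearman_correlation([1.0, 1.0, 1.0], [1, 2, 3])

    def test_exact_p_matches_brute_force_average_ranks(self):
        """Tie-corrected rho and exact permutation p on the disseminated-
        tumour group's histology means vs lung uptake ratios."""
        x = [3, 3.25, 2, 2, 1, 1]
        y = [1.03, 2.16, 1.32, 1.21, 1.63, 1.48]
        rho, p = spearman_correlation(x, y)

        # independent oracle: average-rank Pearson, full enumeration
        def avg_rank(v):
            v = np.asarray(v, float)
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            i = 0
            sorted_v = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sorted_v[j] == sorted_v[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2.0
                i = j
            return ranks

        rx, ry = avg_rank(x), avg_rank(y)

        def pearson(a, b):
            a = a - a.mean()
            b = b - b.mean()
            return (a @ b) / math.sqrt((a @ a) * (b @ b))

        rho_ref = pearson(rx, ry)
        assert rho == pytest.approx(rho_ref, abs=1e-12)
        assert rho == pytest.approx(-0.0883, abs=0.001)

        hits = sum(
            abs(pearson(rx, ry[list(perm)])) >= abs(rho_ref) - 1e-12
            for perm in itertools.permutations(range(6))
        )
        assert p == pytest.approx(hits / math.factorial(6), abs=1e-12)
        assert p > 0.05  # no significant correlation in this group

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=7)
        y = rng.normal(size=7)
        rho, p = spearman_correlation(x, y)
        rho2, p2 = spearman_correlation(np.exp(x), y**3)
        assert rho2 == pytest.approx(rho, abs=1e-12)
        assert p2 == pytest.approx(p, abs=1e-12)

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=20)
        y = x + rng.normal(size=20)
        rho, p = spearman_correlation(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)


class TestTwoSampleTests:
    def test_identical_groups_p_one(self):
        p_s, p_w = two_sample_tests([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p_s == pytest.approx(1.0)
        assert p_w == pytest.approx(1.0)

    def test_separated_groups_p_tiny(self):
        rng = np.random.default_rng(13)
        a = 0.0 + rng.normal(0, 1e-6, size=4)
        b = 1.0 + rng.normal(0, 1e-6, size=4)
        p_s, p_w = two_sample_tests(a, b)
        assert p_s < 1e-10 and p_w < 1e-10

    def test_group_too_small_rejected(self):
        with pytest.raises(StatisticsError):
            two_sample_tests([1.0], [1.0, 2.0])

    def test_welch_equals_student_for_equal_variance_and_size(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = a + 0.7  # identical sample variance, equal n
        p_s, p_w = two_sample_tests(a, b)
        assert p_w == pytest.approx(p_s, abs=1e-12)

    def test_welch_type_I_error_calibrated(self):
        """Monte-Carlo: equal-mean normal groups rejected at ~5% (3 SE band)."""
        rng = np.random.default_rng(2024)
        alpha, reps = 0.05, 1000
        rejections = 0
        for _ in range(reps):
            a = rng.normal(0, 1, size=8)
            b = rng.normal(0, 2, size=6)
            _, p_w = two_sample_tests(a, b)
            rejections += p_w < alpha
        se = math.sqrt(alpha * (1 - alpha) / reps)
        assert abs(rejections / reps - alpha) < 3 * se
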