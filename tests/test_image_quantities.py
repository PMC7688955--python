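import numpy as np
import pytest

from her2forecast.grid import ImageVolume, LABEL_ADIPOSE, LABEL_FIBROGLANDULAR, LABEL_TUMOR
from her2forecast.quantities import (
    carrying_capacity,
    cellularity_from_adc,
    compute_auc_drug_map,
    fit_adc,
    normalize_pet_map,
    segment_tissues_kmeans,
    segment_tumor_fcm,
    tumor_volume,
)

B_VALUES = [0.0, 600.0, 800.0, 1000.0, 1500.0]


def make_stack(signal_fn, shape=(3, 3, 3), b_values=B_VALUES):
    return [ImageVolume(np.full(shape, 0.0) + signal_fn(b)) for b in b_values]


class TestFitADC:
    def test_exact_mono_exponential(self):
        adc_true = 1.0e-3
        stack = [ImageVolume(np.full((3, 3, 3), 1000.0 * np.exp(-b * adc_true)))
                 for b in B_VALUES]
        adc = fit_adc(stack, B_VALUES)
        np.testing.assert_allclose(adc.values, adc_true, rtol=1e-12)

    def test_random_s0_field_recovery(self):
        rng = np.random.default_rng(5)
        s0 = rng.uniform(100.0, 5000.0, (6, 6, 6))
        adc_true = rng.uniform(0.5e-3, 2.5e-3, (6, 6, 6))
        stack = [ImageVolume(s0 * np.exp(-b * adc_true)) for b in B_VALUES]
        adc = fit_adc(stack, B_VALUES)
        np.testing.assert_allclose(adc.values, adc_true, rtol=1e-10)

    def test_constant_signal_gives_zero(self):
        stack = [ImageVolume(np.full((2, 2, 2), 500.0)) for _ in B_VALUES]
        adc = fit_adc(stack, B_VALUES)
        np.testing.assert_array_equal(adc.values, 0.0)

    def test_two_point_slope_identity(self):
        s0, s1 = 800.0, 200.0
        stack = [ImageVolume(np.full((2, 2, 2), s0)), ImageVolume(np.full((2, 2, 2), s1))]
        adc = fit_adc(stack, [0.0, 1000.0])
        np.testing.assert_allclose(adc.values, np.log(s0 / s1) / 1000.0, rtol=1e-12)

    def test_nonpositive_signal_marked_as_fluid(self):
        stack = [ImageVolume(np.full((2, 2, 2), 100.0)) for _ in B_VALUES]
        stack[2] = ImageVolume(np.zeros((2, 2, 2)))
        adc = fit_adc(stack, B_VALUES, adc_w=3e-3)
        np.testing.assert_array_equal(adc.values, 3e-3)

    def test_identical_b_values_rejected(self):
        stack = [ImageVolume(np.ones((2, 2, 2)))] * 3
        with pytest.raises(ValueError, match="distinct"):
            fit_adc(stack, [500.0, 500.0, 500.0])


class TestFCM:
    def _stack_from_enhancement(self, enhancement):
        baseline = ImageVolume(np.full(enhancement.shape, 100.0))
        late = ImageVolume(100.0 + enhancement)
        return [baseline, late]

    def test_separable_levels_match_brute_force(self):
        rng = np.random.default_rng(0)
        enh = rng.normal(100.0, 1.0, (6, 6, 6))
        bright = np.zeros((6, 6, 6), bool)
        bright[2:4, 2:4, 2:4] = True
        enh[bright] = rng.normal(1000.0, 1.0, bright.sum())
        roi = np.ones((6, 6, 6), bool)
        mask = segment_tumor_fcm(self._stack_from_enhancement(enh), roi, 2, 0.5)
        # brute-force oracle: nearest-of-two-cluster assignment on 1D values
        feat = enh[roi]
        boundary = (feat[feat < 500].mean() + feat[feat > 500].mean()) / 2.0
        expected = enh > boundary
        np.testing.assert_array_equal(mask, expected)

    def test_single_bright_voxel(self):
        enh = np.full((4, 4, 4), 50.0)
        enh[1, 1, 1] = 900.0
        roi = np.ones((4, 4, 4), bool)
        mask = segment_tumor_fcm(self._stack_from_enhancement(enh), roi, 2, 0.5)
        assert mask[1, 1, 1]

    def test_zero_threshold_returns_all(self):
        rng = np.random.default_rng(1)
        enh = rng.uniform(0, 100, (4, 4, 4))
        roi = np.zeros((4, 4, 4), bool)
        roi[1:3, 1:3, 1:3] = True
        mask = segment_tumor_fcm(self._stack_from_enhancement(enh), roi, 2, 0.0)
        np.testing.assert_array_equal(mask, roi)

    def test_degenerate_feature_rejected(self):
        enh = np.full((4, 4, 4), 5.0)
        roi = np.ones((4, 4, 4), bool)
        with pytest.raises(ValueError, match="degenerate"):
            segment_tumor_fcm(self._stack_from_enhancement(enh), roi, 2, 0.5)


class TestTissueKMeans:
    def test_bimodal_exact_partition(self):
        vals = np.full((6, 6, 6), 10.0)
        high = np.zeros((6, 6, 6), bool)
        high[:, :, 3:] = True
        vals[high] = 100.0
        mask = np.ones((6, 6, 6), bool)
        tumor = np.zeros((6, 6, 6), bool)
        tumor[0, 0, 0] = True
        domain = segment_tissues_kmeans(ImageVolume(vals), mask, tumor)
        labels = domain.labels_array
        # 1D 2-means boundary sits at the centroid midpoint: modes separate
        assert np.all(labels[high & ~tumor] == LABEL_FIBROGLANDULAR)
        assert np.all(labels[~high & ~tumor] == LABEL_ADIPOSE)

    def test_near_uniform_phantom_one_dominant_cluster(self):
        vals = np.full((6, 6, 6), 10.0)
        vals[0, 0, 0] = 10.001  # a lone slightly-off voxel
        mask = np.ones((6, 6, 6), bool)
        domain = segment_tissues_kmeans(
            ImageVolume(vals), mask, np.zeros((6, 6, 6), bool)
        )
        labels = domain.labels_array
        counts = np.bincount(labels.ravel(), minlength=4)
        assert counts.max() >= 0.99 * mask.sum()

    def test_tumor_never_relabeled(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(0, 100, (6, 6, 6))
        mask = np.ones((6, 6, 6), bool)
        tumor = np.zeros((6, 6, 6), bool)
        tumor[2:4, 2:4, 2:4] = True
        domain = segment_tissues_kmeans(ImageVolume(vals), mask, tumor)
        assert np.all(domain.labels_array[tumor] == LABEL_TUMOR)

    def test_constant_intensity_rejected(self):
        vals = np.full((4, 4, 4), 1.0)
        with pytest.raises(ValueError, match="distinct"):
            segment_tissues_kmeans(
                ImageVolume(vals), np.ones((4, 4, 4), bool), np.zeros((4, 4, 4), bool)
            )


class TestAUCMap:
    def _stack(self, enh_slopes, n_post=3):
        # enhancement grows linearly: voxel value = baseline + slope * frame
        base = np.full(enh_slopes.shape, 50.0)
        stack = [ImageVolume(base.copy())]
        for j in range(1, n_post + 1):
            stack.append(ImageVolume(base + enh_slopes * j))
        return stack

    def test_single_hot_voxel(self):
        slopes = np.zeros((3, 3, 3))
        slopes[1, 1, 1] = 2.0
        out = compute_auc_drug_map(self._stack(slopes), 0, np.ones((3, 3, 3), bool))
        assert out.values[1, 1, 1] == 1.0
        assert np.all(out.values[slopes == 0] == 0.0)

    def test_uniform_enhancement(self):
        slopes = np.full((3, 3, 3), 1.5)
        out = compute_auc_drug_map(self._stack(slopes), 0, np.ones((3, 3, 3), bool))
        np.testing.assert_allclose(out.values, 1.0)

    def test_trapezoid_ratio_of_ramp_slopes(self):
        slopes = np.zeros((2, 1, 1))
        slopes[0, 0, 0] = 1.0
        slopes[1, 0, 0] = 2.0
        out = compute_auc_drug_map(self._stack(slopes), 0, np.ones((2, 1, 1), bool))
        np.testing.assert_allclose(out.values[:, 0, 0], [0.5, 1.0], rtol=1e-12)

    def test_positive_rescaling_invariance(self):
        rng = np.random.default_rng(7)
        slopes = rng.uniform(0.1, 5.0, (4, 4, 4))
        roi = np.ones((4, 4, 4), bool)
        a = compute_auc_drug_map(self._stack(slopes), 0, roi)
        scaled = [v.with_values(v.values * 13.7) for v in self._stack(slopes)]
        # scaling both baseline and post frames scales enhancement linearly
        b = compute_auc_drug_map(scaled, 0, roi)
        np.testing.assert_allclose(a.values, b.values, rtol=1e-12)

    def test_zero_auc_rejected(self):
        slopes = np.zeros((3, 3, 3))
        with pytest.raises(ValueError, match="zero"):
            compute_auc_drug_map(self._stack(slopes), 0, np.ones((3, 3, 3), bool))


class TestPetMap:
    def test_uniform_uptake(self):
        pet = ImageVolume(np.full((3, 3, 3), 4.2))
        out = normalize_pet_map(pet, np.ones((3, 3, 3), bool))
        np.testing.assert_allclose(out.values, 1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(9)
        up = rng.uniform(0.1, 9.0, (4, 4, 4))
        roi = np.ones((4, 4, 4), bool)
        a = normalize_pet_map(ImageVolume(up), roi)
        b = normalize_pet_map(ImageVolume(up * 2.0), roi)
        np.testing.assert_allclose(a.values, b.values, rtol=1e-12)

    def test_max_location_preserved(self):
        rng = np.random.default_rng(10)
        up = rng.uniform(0.1, 1.0, (4, 4, 4))
        up[2, 3, 1] = 5.0
        out = normalize_pet_map(ImageVolume(up), np.ones((4, 4, 4), bool))
        assert np.unravel_index(np.argmax(out.values), (4, 4, 4)) == (2, 3, 1)

    def test_nonpositive_max_rejected(self):
        with pytest.raises(ValueError):
            normalize_pet_map(ImageVolume(np.zeros((2, 2, 2))), np.ones((2, 2, 2), bool))


class TestCarryingCapacity:
    def test_unit_construction(self):
        cell_volume = 4.0 / 3.0 * np.pi * (10e-3) ** 3  # mm^3 for r = 10 um
        assert carrying_capacity(cell_volume, 1.0, 10.0) == pytest.approx(1.0)

    def test_linearity_in_voxel_volume(self):
        assert carrying_capacity(4.36) == pytest.approx(2 * carrying_capacity(2.18))

    def test_reference_voxel_arithmetic(self):
        # 0.74 * 2.18 / ((4/3) pi (0.01)^3) -- hand computation
        assert carrying_capacity(2.18, 0.74, 10.0) == pytest.approx(3.851e5, rel=1e-3)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            carrying_capacity(0.0)
        with pytest.raises(ValueError):
            carrying_capacity(1.0, -0.5)


class TestCellularity:
    def test_formula_endpoints_and_midpoint(self):
        adc_w, adc_min, theta = 3e-3, 0.8e-3, 1e6
        adc = np.full((3, 1, 1), adc_w)
        adc[0] = adc_min
        adc[1] = 1.9e-3  # midpoint of [adc_min, adc_w]
        roi = np.ones((3, 1, 1), bool)
        cells = cellularity_from_adc(ImageVolume(adc), roi, theta, adc_w)
        np.testing.assert_allclose(
            cells.counts.values[:, 0, 0], [theta, 0.5 * theta, 0.0], rtol=1e-12
        )

    def test_monotone_decreasing_in_adc(self):
        rng = np.random.default_rng(3)
        adc = np.sort(rng.uniform(0.5e-3, 2.9e-3, 64)).reshape(4, 4, 4)
        cells = cellularity_from_adc(ImageVolume(adc), np.ones((4, 4, 4), bool), 1e6)
        flat = cells.counts.values.ravel()
        assert np.all(np.diff(flat) <= 1e-9)
        assert flat.min() >= 0 and flat.max() <= 1e6

    def test_zero_outside_roi(self):
        adc = np.full((4, 4, 4), 1.5e-3)
        roi = np.zeros((4, 4, 4), bool)
        roi[1, 1, 1] = True
        cells = cellularity_from_adc(ImageVolume(adc), roi, 1e6)
        assert cells.counts.values[0, 0, 0] == 0.0

    def test_degenerate_tumor_rejected(self):
        adc = np.full((2, 2, 2), 5e-3)  # above free water
        with pytest.raises(ValueError, match="degenerate"):
            cellularity_from_adc(ImageVolume(adc), np.ones((2, 2, 2), bool), 1e6)


class TestTumorVolume:
    def test_roi_count_times_voxel_volume(self):
        roi = np.zeros((10, 10, 10), bool)
        roi.ravel()[:100] = True
        assert tumor_volume(roi, 2.18) == pytest.approx(218.0)

    def test_empty_roi(self):
        assert tumor_volume(np.zeros((3, 3, 3), bool), 2.18) == 0.0

    def test_map_below_threshold(self):
        from her2forecast.quantities import CellularityMap

        counts = ImageVolume(np.full((3, 3, 3), 100.0))
        m = CellularityMap(counts, 1e6, np.ones((3, 3, 3), bool))
        assert tumor_volume(m, 2.18, threshold_fraction=0.25) == 0.0
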