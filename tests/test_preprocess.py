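"""Masking, EQD2 conversion, normalisation, crop/resample and augmentation."""

import numpy as np
import pytest

from dosemap_ntcp import preprocess as pp


def grid(values):
    return pp.DoseGrid(values=np.asarray(values, dtype=float))


class TestMaskDose:
    def test_all_ones_mask_is_identity(self, rng):
        dose = grid(rng.uniform(0, 70, (4, 4, 4)))
        out = pp.mask_dose(dose, np.ones((4, 4, 4)))
        np.testing.assert_array_equal(out.values, dose.values)

    def test_empty_mask_rejected(self):
        with pytest.raises(pp.EmptyStructureError):
            pp.mask_dose(grid(np.ones((4, 4, 4))), np.zeros((4, 4, 4)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(pp.GridIncompatibilityError):
            pp.mask_dose(grid(np.ones((4, 4, 4))), np.ones((4, 4, 5)))

    def test_voxelwise_definition(self):
        dose = grid(np.array([40.0, 80.0]).reshape(2, 1, 1))
        mask = np.array([1, 0]).reshape(2, 1, 1)
        out = pp.mask_dose(dose, mask)
        np.testing.assert_array_equal(out.values.ravel(), [40.0, 0.0])

    def test_in_mask_values_bitwise_identical(self, rng):
        dose = grid(rng.uniform(0, 70, (6, 6, 6)))
        mask = rng.random((6, 6, 6)) > 0.5
        out = pp.mask_dose(dose, mask)
        assert np.array_equal(out.values[mask], dose.values[mask])


class TestEqd2:
    def test_identity_at_2gy_per_fraction(self):
        out = pp.eqd2_correct(
            grid(np.full((2, 2, 2), 70.0)), pp.EQD2Params(alpha_beta=3.0, n_fractions=35)
        )
        np.testing.assert_allclose(out.values, 70.0)

    def test_hypofractionated_closed_form(self):
        # 55 Gy in 20 fractions, alpha/beta 3: 55 * (2.75 + 3) / 5 = 63.25 Gy
        out = pp.eqd2_correct(
            grid(np.full((2, 2, 2), 55.0)), pp.EQD2Params(alpha_beta=3.0, n_fractions=20)
        )
        np.testing.assert_allclose(out.values, 63.25)

    def test_zero_stays_zero_and_invalid_params_rejected(self):
        out = pp.eqd2_correct(grid(np.zeros((2, 2, 2))), pp.EQD2Params(3.0, 30))
        assert np.all(out.values == 0.0)
        with pytest.raises(ValueError):
            pp.EQD2Params(alpha_beta=3.0, n_fractions=0)
        with pytest.raises(ValueError):
            pp.EQD2Params(alpha_beta=0.0, n_fractions=30)

    def test_amplifies_above_shrinks_below_2gy_fractions(self, rng):
        params = pp.EQD2Params(alpha_beta=3.0, n_fractions=30)
        hot = grid(np.full((2, 2, 2), 66.0))  # 2.2 Gy/fx
        cold = grid(np.full((2, 2, 2), 54.0))  # 1.8 Gy/fx
        assert np.all(pp.eqd2_correct(hot, params).values > hot.values)
        assert np.all(pp.eqd2_correct(cold, params).values < cold.values)

    def test_monotone_in_dose(self, rng):
        params = pp.EQD2Params(alpha_beta=3.0, n_fractions=25)
        d = np.sort(rng.uniform(0, 75, 50)).reshape(50, 1, 1)
        out = pp.eqd2_correct(pp.DoseGrid(values=d), params).values.ravel()
        assert np.all(np.diff(out) >= 0)


class TestNormalisation:
    def test_three_point_example(self):
        stats = pp.fit_normalisation([np.array([[[0.0, 35.0, 70.0]]])])
        np.testing.assert_allclose(
            pp.apply_normalisation(np.array([0.0, 35.0, 70.0]), stats),
            [0.0, 0.5, 1.0],
        )

    def test_external_value_clipped(self):
        stats = pp.NormalisationStats(0.0, 70.0)
        assert pp.apply_normalisation(np.array([80.0]), stats)[0] == 1.0
        assert pp.apply_normalisation(np.array([-5.0]), stats)[0] == 0.0

    def test_constant_cohort_rejected(self):
        with pytest.raises(pp.DegenerateRangeError):
            pp.fit_normalisation([np.full((2, 2, 2), 42.0)])

    def test_round_trip_inside_fit_range(self, rng):
        maps = [rng.uniform(0, 70, (4, 4, 4)) for _ in range(3)]
        stats = pp.fit_normalisation(maps)
        recovered = pp.denormalise(pp.apply_normalisation(maps[0], stats), stats)
        np.testing.assert_allclose(recovered, maps[0], rtol=1e-12, atol=1e-10)


class TestCropResample:
    def test_bounding_box_equal_to_target_is_identity(self, rng):
        dose = rng.uniform(1, 70, (8, 8, 8))
        mask = np.ones((8, 8, 8))
        out = pp.crop_resample(dose, mask, (12, 12, 12), margin=0)
        np.testing.assert_array_equal(out.values[2:10, 2:10, 2:10], dose)
        assert out.values.shape == (12, 12, 12)

    def test_single_voxel_mask_preserved_at_centre(self):
        dose = np.zeros((9, 9, 9))
        dose[4, 4, 4] = 66.0
        mask = np.zeros((9, 9, 9))
        mask[4, 4, 4] = 1
        out = pp.crop_resample(dose, mask, (8, 8, 8), margin=0)
        assert out.values.sum() == 66.0
        assert out.values[tuple(np.argwhere(out.mask)[0])] == 66.0

    def test_downsampled_constant_region_stays_constant(self):
        dose = np.full((16, 16, 16), 60.0)
        mask = np.ones((16, 16, 16))
        out = pp.crop_resample(dose, mask, (8, 8, 8), margin=0)
        np.testing.assert_allclose(out.values[out.mask == 1], 60.0)

    def test_resample_disabled_rejects_oversized_crop(self):
        dose = np.ones((16, 16, 16))
        mask = np.ones((16, 16, 16))
        with pytest.raises(ValueError):
            pp.crop_resample(dose, mask, (8, 8, 8), margin=0, allow_resample=False)


class TestAugment:
    def test_disabled_is_identity(self, rng):
        v = rng.random((8, 8, 8))
        cfg = pp.AugmentConfig(enabled=False)
        np.testing.assert_array_equal(pp.augment(v, cfg), v)

    def test_fixed_seed_reproducible(self, rng):
        v = rng.random((8, 8, 8))
        cfg = pp.AugmentConfig(seed=3)
        np.testing.assert_array_equal(pp.augment(v, cfg), pp.augment(v, cfg))

    def test_output_stays_in_unit_interval(self, rng):
        v = rng.random((8, 8, 8))
        out = pp.augment(v, pp.AugmentConfig(seed=1))
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_sampled_parameters_stay_in_ranges(self):
        cfg = pp.AugmentConfig()
        r = np.random.default_rng(0)
        for _ in range(1000):
            angles, zoom = pp.sample_augmentation(cfg, r)
            assert np.all(angles >= -0.1) and np.all(angles <= 0.1)
            assert 0.8 <= zoom <= 1.2

    def test_ranges_must_contain_identity(self):
        with pytest.raises(ValueError):
            pp.AugmentConfig(rotation_range=(0.05, 0.1))
        with pytest.raises(ValueError):
            pp.AugmentConfig(zoom_range=(1.1, 1.2))


class TestPipelineOrder:
    def test_eqd2_before_normalisation_matters(self, rng):
        """EQD2 is nonlinear in dose, so swapping it with min-max scaling
        changes the result; the pipeline fixes mask -> EQD2 -> normalise."""
        dose = rng.uniform(10, 70, (6, 6, 6))
        params = pp.EQD2Params(alpha_beta=3.0, n_fractions=20)
        stats = pp.NormalisationStats(0.0, 80.0)

        correct = pp.apply_normalisation(
            pp.eqd2_correct(pp.DoseGrid(values=dose), params).values, stats
        )
        swapped_gy = pp.eqd2_correct(
            pp.DoseGrid(values=pp.apply_normalisation(dose, stats) * 80.0), params
        ).values / 80.0
        assert not np.allclose(correct, swapped_gy)

    def test_full_subject_pipeline_output_contract(self, rng):
        dose = pp.DoseGrid(values=rng.uniform(0, 70, (12, 12, 12)))
        mask = np.zeros((12, 12, 12))
        mask[3:9, 3:9, 3:9] = 1
        stats = pp.NormalisationStats(0.0, 75.0)
        out = pp.preprocess_subject(
            dose, mask, pp.EQD2Params(3.0, 30), stats, (8, 8, 8), margin=0, subject_id="S1"
        )
        assert out.values.shape == (8, 8, 8)
        assert out.values.min() >= 0.0 and out.values.max() <= 1.0
        assert np.all(out.values[out.mask == 0] == 0.0)
        assert out.meta["subject_id"] == "S1" and out.meta["eqd2_applied"]
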