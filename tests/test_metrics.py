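"""Discrimination, calibration and effect-size statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dosemap_ntcp import metrics as em


def preds(p, y, ids=None, **kw):
    p = np.asarray(p, dtype=float)
    return em.PredictionSet(
        subject_ids=ids if ids is not None else list(range(p.size)),
        probabilities=p,
        labels=np.asarray(y, dtype=int),
        **kw,
    )


class TestAuroc:
    def test_perfect_separation(self):
        a, lo, hi = em.auroc_with_ci(preds([0.9, 0.8, 0.3, 0.1], [1, 1, 0, 0]))
        assert a == 1.0 and lo <= a <= hi

    def test_one_discordant_pair(self):
        # positives score 0.9 and 0.3, negatives 0.8 and 0.1: the (0.3, 0.8)
        # pair is the single discordant one of four -> 3/4
        assert em.auroc([1, 1, 0, 0], [0.9, 0.3, 0.8, 0.1]) == 0.75

    def test_matches_sklearn_on_random_scores(self, rng):
        from sklearn.metrics import roc_auc_score

        y = rng.integers(0, 2, 200)
        y[:5] = 1
        y[5:10] = 0
        s = np.round(rng.random(200), 2)  # ties included
        assert em.auroc(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_null_permutation_near_half(self, rng):
        y = rng.permutation(np.repeat([0, 1], 500))
        s = rng.random(1000)
        assert abs(em.auroc(y, s) - 0.5) < 0.05

    def test_invariant_under_monotone_transform(self, rng):
        y = rng.integers(0, 2, 100)
        y[0], y[1] = 0, 1
        s = rng.random(100)
        assert em.auroc(y, s) == em.auroc(y, sps.norm.ppf(s * 0.999))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            em.auroc_with_ci(preds([0.3, 0.4], [1, 1]))


class TestDelong:
    def test_identical_models_p_one(self, rng):
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        s = rng.random(50)
        assert em.delong_test(preds(s, y), preds(s, y)) == 1.0

    def test_unpaired_inputs_rejected(self, rng):
        a = preds(rng.random(10), np.tile([0, 1], 5))
        b = preds(rng.random(10), np.tile([1, 0], 5))
        with pytest.raises(ValueError):
            em.delong_test(a, b)

    def test_power_against_random_model(self, rng):
        y = np.repeat([0, 1], 92)
        good = y + rng.normal(0, 0.1, 184)
        good = (good - good.min()) / np.ptp(good)
        rand = rng.random(184)
        assert em.delong_test(preds(good, y), preds(rand, y)) < 0.05

    def test_null_p_values_roughly_uniform(self, rng):
        """Two equally noisy models on the same subjects: the DeLong p-value
        should be uniform under the null (KS test, alpha=0.01)."""
        pvals = []
        y = np.repeat([0, 1], 92)
        for _ in range(500):
            signal = rng.normal(0, 1, 184) + 0.8 * y
            a = sps.norm.cdf(signal + rng.normal(0, 0.8, 184))
            b = sps.norm.cdf(signal + rng.normal(0, 0.8, 184))
            pvals.append(em.delong_test(preds(a, y), preds(b, y)))
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestCalibrationScores:
    def test_perfect_predictions_zero_losses(self):
        p = preds([1.0, 1.0, 0.0], [1, 1, 0])
        assert em.brier(p) == 0.0 and em.log_loss(p) < 1e-12

    def test_constant_half_forecasts(self):
        p = preds(np.full(10, 0.5), np.tile([0, 1], 5))
        assert em.brier(p) == 0.25
        assert em.log_loss(p) == pytest.approx(np.log(2), abs=1e-12)

    def test_brier_of_calibrated_forecaster_is_one_sixth(self, rng):
        p = rng.random(100_000)
        y = (rng.random(100_000) < p).astype(int)
        assert em.brier(preds(p, y)) == pytest.approx(1 / 6, abs=0.01)

    def test_brier_decomposition_for_constant_forecast(self, rng):
        prob = 0.3
        y = rng.integers(0, 2, 500)
        prevalence = y.mean()
        expected = prob**2 + prevalence * (1 - 2 * prob)
        assert em.brier(preds(np.full(500, prob), y)) == pytest.approx(expected)

    def test_log_loss_finite_on_confident_errors(self):
        assert np.isfinite(em.log_loss(preds([1.0], [0])))


class TestClassificationMetrics:
    def test_all_positive_on_balanced_cohort(self):
        m = em.classification_metrics(preds(np.ones(10), np.tile([0, 1], 5)))
        assert m["recall"] == 1.0 and m["specificity"] == 0.0 and m["accuracy"] == 0.5

    def test_perfect_predictions(self):
        m = em.classification_metrics(preds([0.9, 0.1, 0.8, 0.2], [1, 0, 1, 0]))
        assert all(v == 1.0 for v in m.values())

    def test_confusion_matrix_closed_form(self):
        # TP=30 FN=11 TN=12 FP=29
        y = np.array([1] * 41 + [0] * 41)
        p = np.array([0.9] * 30 + [0.1] * 11 + [0.1] * 12 + [0.9] * 29)
        m = em.classification_metrics(preds(p, y))
        assert m["recall"] == pytest.approx(30 / 41)
        assert m["specificity"] == pytest.approx(12 / 41)
        assert m["precision"] == pytest.approx(30 / 59)

    def test_threshold_tie_classified_positive(self):
        m = em.classification_metrics(preds([0.5, 0.4], [1, 0]))
        assert m["recall"] == 1.0 and m["specificity"] == 1.0


class TestCalibrationCurve:
    def test_calibrated_forecasts_lie_on_diagonal(self, rng):
        p = rng.random(100_000)
        y = (rng.random(100_000) < p).astype(int)
        curve = em.calibration_curve(preds(p, y), n_bins=10)
        assert (curve["mean_predicted"] - curve["observed_fraction"]).abs().max() < 0.02

    def test_single_occupied_bin(self):
        curve = em.calibration_curve(preds([0.42, 0.44, 0.41], [0, 1, 0]), n_bins=10)
        assert len(curve) == 1

    def test_deterministic_correct_forecasts(self):
        curve = em.calibration_curve(preds([0.0, 0.0, 1.0, 1.0], [0, 0, 1, 1]), n_bins=10)
        assert curve.iloc[0].tolist() == [0.0, 0.0, 2]
        assert curve.iloc[1].tolist() == [1.0, 1.0, 2]


class TestEffectSizes:
    @pytest.mark.parametrize(
        "k1, n1, k2, n2, expected",
        [
            (47, 92, 21, 92, 0.6),   # smoking, development cohort
            (7, 41, 15, 41, -0.5),   # chemotherapy, external cohort
            (34, 41, 30, 41, 0.2),   # pre-RT extractions, external cohort
            (16, 41, 13, 41, 0.2),   # PORT, external cohort
            (35, 92, 35, 92, 0.0),   # PORT, development cohort
        ],
    )
    def test_binary_d_reproduces_published_cells(self, k1, n1, k2, n2, expected):
        assert round(em.cohens_d_binary(k1, n1, k2, n2), 1) == expected

    def test_equal_proportions_give_exact_zero(self):
        assert em.cohens_d_binary(10, 40, 5, 20) == 0.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            em.cohens_d_binary(5, 0, 1, 10)

    def test_continuous_d_recovers_one_sd_shift(self, rng):
        x1 = rng.normal(1.0, 1.0, 200)
        x2 = rng.normal(0.0, 1.0, 200)
        assert em.cohens_d_continuous(x1, x2) == pytest.approx(1.0, abs=0.15)

    def test_identical_samples_d_zero_p_one(self, rng):
        x = rng.normal(0, 1, 30)
        assert em.cohens_d_continuous(x, x) == 0.0
        assert em.mann_whitney(np.ones(10), np.ones(10)) == 1.0

    def test_smoking_contingency_table_significant(self):
        assert em.chi_squared(np.array([[47, 45], [21, 71]])) < 0.001

    def test_chi_squared_matches_permutation_oracle(self, rng):
        """Yates-corrected chi-squared p-value vs a 1e4-draw permutation test."""
        table = np.array([[12, 8], [5, 15]])
        p_chi = em.chi_squared(table)
        group = np.repeat([0, 1], 20)
        outcome = np.array([1] * 12 + [0] * 8 + [1] * 5 + [0] * 15)
        observed = abs(outcome[group == 0].mean() - outcome[group == 1].mean())
        null = []
        for _ in range(10_000):
            perm = rng.permutation(outcome)
            null.append(abs(perm[:20].mean() - perm[20:].mean()))
        null = np.asarray(null)
        p_perm = (null >= observed - 1e-12).mean()
        assert abs(p_chi - p_perm) < 0.05

    def test_mann_whitney_matches_permutation_oracle(self, rng):
        x1 = rng.normal(0.9, 1, 12)
        x2 = rng.normal(0.0, 1, 12)
        p_mw = em.mann_whitney(x1, x2)
        pooled = np.concatenate([x1, x2])
        obs = sps.rankdata(pooled)[: x1.size].sum()
        null = []
        for _ in range(10_000):
            perm = rng.permutation(pooled)
            null.append(sps.rankdata(perm)[: x1.size].sum())
        null = np.asarray(null)
        centre = null.mean()
        p_perm = (np.abs(null - centre) >= abs(obs - centre) - 1e-12).mean()
        assert abs(p_mw - p_perm) < 0.05


class TestCohortSummary:
    def make_table(self, rng, n=2000):
        from dosemap_ntcp import synthetic_cohort as sc

        cfg = sc.PhantomConfig(grid_shape=(12, 12, 12), voxel_spacing=(4.0, 4.0, 4.0), seed=int(rng.integers(1e6)))
        return sc.generate_population(cfg, sc.PlantedTruth(), n).clinical_table()

    def test_prevalences_within_binomial_error(self, rng):
        from dosemap_ntcp import synthetic_cohort as sc

        table = self.make_table(rng)
        summary = em.cohort_summary(table)
        for var, target in sc.INTERNAL_PREVALENCES.items():
            k1 = int(table[table.orn_label == 1][var].sum())
            k0 = int(table[table.orn_label == 0][var].sum())
            prev = (k1 + k0) / len(table)
            se = np.sqrt(target * (1 - target) / len(table))
            assert abs(prev - target) < 3.5 * se
        assert set(summary.index) >= set(em.BINARY_VARIABLES) | {"age"}

    def test_identical_groups_null_results(self):
        rows = []
        for label in (0, 1):
            for i in range(20):
                rows.append(
                    dict(
                        subject_id=f"S{label}{i}", age=50 + i, gender=i % 2,
                        smoking=i % 2, pre_rt_extractions=(i // 2) % 2, port=i % 2,
                        chemotherapy=(i // 3) % 2, primary_site="oropharynx",
                        treatment_year=2015, n_fractions=30, orn_label=label,
                    )
                )
        summary = em.cohort_summary(pd.DataFrame(rows).set_index("subject_id"))
        binaries = summary.loc[list(em.BINARY_VARIABLES)]
        assert (binaries["cohens_d"] == 0.0).all()
        assert (binaries["p_value"] == 1.0).all()

    def test_covariate_shift_flags_chemotherapy(self, rng):
        from dosemap_ntcp import synthetic_cohort as sc

        internal = self.make_table(rng, 600)
        cfg = sc.external_config(seed=4, grid_shape=(12, 12, 12), voxel_spacing=(4.0, 4.0, 4.0))
        external = sc.generate_population(cfg, sc.PlantedTruth(), 600).clinical_table()
        report = em.covariate_shift_report(internal, external)
        assert report.loc["chemotherapy", "shifted"]
        assert not report.loc["gender", "shifted"]
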