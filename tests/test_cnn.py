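"""Architecture arithmetic, forward/backward contracts and training behaviour
of the 3D DenseNet classifiers."""

import numpy as np
import pytest

from dosemap_ntcp.nn import (
    ArchitectureConfig,
    DenseNet3D,
    HYPERPARAMETER_GRID,
    Hyperparameters,
    TrainedModel,
    build_dose_only,
    build_joint_fusion,
    enumerate_grid,
    feature_dimension,
    fused_dimension,
    parameter_count,
    train,
)
from dosemap_ntcp.nn.densenet import IncompatibleInputShapeError
from dosemap_ntcp.nn.layers import cross_entropy_loss, softmax
from dosemap_ntcp.nn.train import grid_search, validation_auroc

TINY = ArchitectureConfig(initial_channels=4, growth_rate=3, layers_per_block=(2, 2, 2))


class TestFeatureDimension:
    def test_default_config_yields_688_and_694(self):
        cfg = ArchitectureConfig()
        # 64 +384 =448 -> 224; +384 =608 -> 304; +384 = 688
        assert feature_dimension(cfg) == 688
        assert fused_dimension(cfg) == 694

    def test_hand_arithmetic_without_compression(self):
        cfg = ArchitectureConfig(
            initial_channels=16, growth_rate=12, layers_per_block=(12, 12, 12), compression=1.0
        )
        # 16 +144 =160; +144 =304; +144 =448
        assert feature_dimension(cfg) == 448

    def test_matches_instantiated_network(self):
        model = build_dose_only(TINY, seed=0)
        x = np.zeros((2, 1, 8, 8, 8))
        feats_len = model.feature_length
        assert feats_len == feature_dimension(TINY)
        assert model.forward(x).shape == (2, 2)

    def test_parameter_count_matches_instantiation(self):
        model = build_dose_only(TINY, seed=0)
        assert model.n_parameters() == parameter_count(TINY, "dose")
        fusion = build_joint_fusion(
            ArchitectureConfig(initial_channels=4, growth_rate=3, layers_per_block=(2, 2, 2)),
            seed=0,
        )
        assert fusion.n_parameters() == parameter_count(fusion.config, "fusion")

    def test_shallower_than_121_layer_variant(self):
        """The 40-layer variant (3x12 dense layers) has strictly fewer
        parameters than the deeper standard variant at the same growth rate."""
        dn40 = ArchitectureConfig()
        dn121ish = ArchitectureConfig(layers_per_block=(6, 12, 24, 16))
        assert parameter_count(dn40) < parameter_count(dn121ish)


class TestForwardContracts:
    def test_softmax_probabilities_sum_to_one(self, rng):
        model = build_dose_only(TINY, seed=1)
        x = rng.random((4, 1, 8, 8, 8))
        p = model.predict_proba(x)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(p >= 0)

    def test_zero_volume_forward_valid(self):
        model = build_dose_only(TINY, seed=1)
        p = model.predict_proba(np.zeros((1, 1, 8, 8, 8)))
        np.testing.assert_allclose(p.sum(), 1.0, atol=1e-6)

    def test_incompatible_shape_reports_minimal_valid(self):
        model = build_dose_only(TINY, seed=0)
        with pytest.raises(IncompatibleInputShapeError, match=r"\(4, 4, 4\)"):
            model.forward(np.zeros((1, 1, 6, 6, 6)))

    def test_fusion_requires_six_clinical_inputs(self, rng):
        model = build_joint_fusion(TINY, seed=0)
        x = rng.random((2, 1, 8, 8, 8))
        with pytest.raises(ValueError):
            model.forward(x, clinical=np.zeros((2, 4)))
        assert model.forward(x, clinical=np.zeros((2, 6))).shape == (2, 2)

    def test_fusion_sensitive_to_clinical_flags(self, rng):
        """Identical dose maps with different smoking flags must produce
        different logits when clinical weights are nonzero."""
        model = build_joint_fusion(TINY, seed=3)
        x = np.repeat(rng.random((1, 1, 8, 8, 8)), 2, axis=0)
        clinical = np.zeros((2, 6))
        clinical[1, 2] = 1.0  # smoking flag
        logits = model.forward(x, clinical)
        assert not np.allclose(logits[0], logits[1])

    def test_zeroed_clinical_weights_reduce_to_image_dependence(self, rng):
        model = build_joint_fusion(TINY, seed=3)
        f = model.feature_length
        model.fc_hidden._params["w"][:, f:] = 0.0
        x = np.repeat(rng.random((1, 1, 8, 8, 8)), 2, axis=0)
        clinical = np.zeros((2, 6))
        clinical[1] = rng.random(6)
        logits = model.forward(x, clinical)
        np.testing.assert_allclose(logits[0], logits[1])

    def test_invalid_modality_and_clinical_width_rejected(self):
        with pytest.raises(ValueError):
            DenseNet3D(TINY, modality="late")
        with pytest.raises(ValueError):
            build_joint_fusion(ArchitectureConfig(n_clinical=4))


class TestTraining:
    def small_task(self, rng, n=10):
        y = np.tile([0, 1], n // 2)
        x = np.zeros((n, 1, 8, 8, 8))
        for i in range(n):
            x[i, 0] = rng.random((8, 8, 8)) * 0.2 + 0.6 * y[i]
        return x, y

    def test_overfits_small_separable_set(self, rng):
        x, y = self.small_task(rng)
        model = build_dose_only(TINY, seed=0)
        hp = Hyperparameters(dropout=0.0, learning_rate=0.01, batch_size=5,
                             weight_decay=0.0, epochs=30, seed=0)
        trained = train(model, x, y, hp)
        pred = (model.predict_proba(x)[:, 1] >= 0.5).astype(int)
        assert np.array_equal(pred, y)
        assert trained.history[-1] < trained.history[0]

    def test_zero_learning_rate_freezes_parameters(self, rng):
        x, y = self.small_task(rng, 4)
        model = build_dose_only(TINY, seed=0)
        before = {k: v.copy() for k, v in model.state_arrays().items()}
        hp = Hyperparameters(dropout=0.0, learning_rate=0.0, batch_size=4,
                             weight_decay=0.0, epochs=2, seed=0)
        train(model, x, y, hp)
        after = model.state_arrays()
        for k in before:
            if "running" in k:
                continue  # BN statistics update regardless of the optimiser
            np.testing.assert_array_equal(before[k], after[k])

    def test_same_seed_reproduces_loss_history(self, rng):
        x, y = self.small_task(rng, 6)
        hp = Hyperparameters(dropout=0.3, learning_rate=0.003, batch_size=3,
                             weight_decay=1e-3, epochs=3, seed=5)
        h1 = train(build_dose_only(TINY, seed=2), x, y, hp).history
        h2 = train(build_dose_only(TINY, seed=2), x, y, hp).history
        assert h1 == h2

    def test_checkpoint_round_trip(self, rng, tmp_path):
        x, y = self.small_task(rng, 4)
        model = build_dose_only(TINY, seed=0)
        hp = Hyperparameters(dropout=0.0, learning_rate=0.01, batch_size=4,
                             weight_decay=0.0, epochs=1, seed=0)
        trained = train(model, x, y, hp)
        trained.save(tmp_path / "ckpt")
        loaded = TrainedModel.load(tmp_path / "ckpt")
        np.testing.assert_allclose(
            loaded.predict_proba(x), trained.predict_proba(x), atol=1e-12
        )


class TestGrid:
    def test_published_grid_enumerates_108_combinations(self):
        assert len(enumerate_grid()) == 108
        sizes = [len(v) for v in HYPERPARAMETER_GRID.values()]
        assert int(np.prod(sizes)) == 108

    def test_singleton_grid_returned_unchanged(self, rng):
        x, y = TestTraining().small_task(rng, 8)
        hp = Hyperparameters(dropout=0.0, learning_rate=0.01, batch_size=4,
                             weight_decay=0.0, epochs=2, seed=0)
        folds = [(np.arange(4), np.arange(4, 8))]
        best, results = grid_search([hp], x, y, folds, TINY)
        assert best == hp and len(results) == 1

    def test_dominant_configuration_selected(self, rng):
        """On separable data a training configuration that learns (lr 0.01,
        30 epochs) must beat one that cannot move (lr 0)."""
        x, y = TestTraining().small_task(rng, 12)
        good = Hyperparameters(dropout=0.0, learning_rate=0.01, batch_size=4,
                               weight_decay=0.0, epochs=30, seed=0)
        frozen = Hyperparameters(dropout=0.0, learning_rate=0.0, batch_size=4,
                                 weight_decay=0.0, epochs=1, seed=0)
        folds = [(np.arange(8), np.arange(8, 12))]
        best, _ = grid_search([frozen, good], x, y, folds, TINY)
        assert best == good

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            grid_search([], np.zeros((2, 1, 8, 8, 8)), np.array([0, 1]), [], TINY)


class TestLossFunction:
    def test_cross_entropy_gradient_matches_finite_difference(self, rng):
        logits = rng.normal(size=(5, 2))
        y = rng.integers(0, 2, 5)
        loss, grad = cross_entropy_loss(logits, y)
        eps = 1e-6
        for i in (0, 3):
            for j in (0, 1):
                lp = logits.copy(); lp[i, j] += eps
                lm = logits.copy(); lm[i, j] -= eps
                num = (cross_entropy_loss(lp, y)[0] - cross_entropy_loss(lm, y)[0]) / (2 * eps)
                assert grad[i, j] == pytest.approx(num, abs=1e-6)

    def test_softmax_rows_normalised(self, rng):
        z = rng.normal(size=(10, 2)) * 50
        np.testing.assert_allclose(softmax(z).sum(axis=1), 1.0, atol=1e-12)
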