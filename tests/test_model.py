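"""Patch extraction, class weighting and the hybrid 3D-1D CNN."""

import numpy as np
import pytest

from esohsi.hsi_io import AnnotationMask, HyperCube
from esohsi.model import (
    CANCER_CLASS,
    ModelConfig,
    PatchDataset,
    build_model,
    class_weights,
    extract_patches,
    predict_map,
    subsample_patches,
    train,
)
from esohsi.preprocess import PreprocessConfig, preprocess_cube


def _labeled_cube(h=6, w=6, b=20, label=1, seed=0):
    rng = np.random.default_rng(seed)
    wl = np.linspace(500, 1000, b)
    cube = HyperCube(rng.random((h, w, b)), wl, "p")
    mask = AnnotationMask(np.full((h, w), label, dtype=np.uint8))
    return cube, mask


@pytest.fixture(scope="module")
def fold_data(small_cohort):
    """Preprocessed patches from the shared cohort: 3 train, 2 val patients."""
    cfg = PreprocessConfig()
    sets = []
    for p in small_cohort.patients[:5]:
        pre = preprocess_cube(p.cube, cfg)
        sets.append(extract_patches(pre, p.mask, 3))
    train_set = subsample_patches(PatchDataset.concatenate(sets[:3]), 600, seed=0)
    val_set = subsample_patches(PatchDataset.concatenate(sets[3:]), 300, seed=1)
    return train_set, val_set


class TestExtractPatches:
    def test_border_exclusion_on_fully_labeled_image(self):
        cube, mask = _labeled_cube(5, 5)
        ds = extract_patches(cube, mask, 3)
        assert len(ds) == 9  # the 3x3 interior

    def test_patch_size_one_returns_pixel_spectra(self):
        cube, mask = _labeled_cube(4, 4, b=10)
        ds = extract_patches(cube, mask, 1)
        assert len(ds) == 16
        np.testing.assert_array_equal(ds.patches[0, 0, 0], cube.reflectance[0, 0])

    def test_corner_only_labels_yield_no_patches(self):
        cube, _ = _labeled_cube(6, 6)
        labels = np.zeros((6, 6), dtype=np.uint8)
        labels[[0, 0, 5, 5], [0, 5, 0, 5]] = 1
        with pytest.raises(ValueError, match="no labeled"):
            extract_patches(cube, AnnotationMask(labels), 3)

    def test_center_pixel_labeling_and_scan_order(self):
        cube, _ = _labeled_cube(5, 5)
        labels = np.zeros((5, 5), dtype=np.uint8)
        labels[1, 1], labels[2, 3], labels[3, 2] = 1, 3, 2
        ds = extract_patches(cube, AnnotationMask(labels), 3)
        np.testing.assert_array_equal(ds.labels, [0, 2, 1])  # row-major centers
        np.testing.assert_array_equal(
            ds.patches[1], cube.reflectance[1:4, 2:5].transpose(0, 1, 2))


class TestClassWeights:
    def test_balanced_formula(self):
        w = class_weights(np.repeat([0, 1, 2], [10, 10, 20]))
        np.testing.assert_allclose(w, [4 / 3, 4 / 3, 2 / 3])

    def test_equal_counts_give_unit_weights(self):
        np.testing.assert_allclose(class_weights(np.repeat([0, 1, 2], 7)), 1.0)

    def test_weighted_mean_over_label_distribution_is_one(self):
        labels = np.repeat([0, 1, 2], [123, 45, 6])
        w = class_weights(labels)
        assert w[labels].mean() == pytest.approx(1.0)

    def test_clinical_spectrum_counts(self):
        """The published training-set imbalance (2,182,695 gastric /
        1,467,937 esophageal / 295,025 cancer spectra) yields weights
        (0.603, 0.896, 4.458)."""
        labels = np.repeat([0, 1, 2], [2_182_695, 1_467_937, 295_025])
        w = class_weights(labels)
        np.testing.assert_allclose(np.round(w, 3), [0.603, 0.896, 4.458])

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            class_weights(np.array([0, 0, 1]))


class TestBuildModel:
    def test_softmax_contract_on_single_patch(self):
        cfg = ModelConfig(seed=0)
        net = build_model(cfg, 96)
        probs = net.predict_proba(np.random.default_rng(0).random((1, 3, 3, 96)))
        assert probs.shape == (1, 3)
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)

    def test_seeded_builds_are_identical(self):
        a = build_model(ModelConfig(seed=4), 96)
        b = build_model(ModelConfig(seed=4), 96)
        for pa, pb in zip(a._all_params(), b._all_params()):
            np.testing.assert_array_equal(pa, pb)

    def test_doubling_conv1d_filters_increases_parameter_count(self):
        small = build_model(ModelConfig(conv1d_filters=(32, 64)), 96)
        big = build_model(ModelConfig(conv1d_filters=(64, 128)), 96)
        assert big.n_parameters > small.n_parameters

    def test_parameter_count_matches_hand_formula(self):
        """Layer-by-layer arithmetic for p=3, B'=96, filters (8,16)/(32,64)."""
        net = build_model(ModelConfig(), 96)
        expected = (3 * 3 * 7 * 1 * 8 + 8          # Conv3D-1
                    + 1 * 1 * 7 * 8 * 16 + 16      # Conv3D-2 (spatial collapsed)
                    + 5 * 16 * 32 + 32             # Conv1D-1
                    + 5 * 32 * 64 + 64             # Conv1D-2
                    + 76 * 64 * 3 + 3)             # dense over 76 positions
        assert net.n_parameters == expected

    def test_oversized_spectral_kernel_rejected(self):
        with pytest.raises(ValueError, match="kernel"):
            build_model(ModelConfig(conv3d_spectral_kernel=7), 10)

    def test_patch5_architecture_builds_and_predicts(self):
        net = build_model(ModelConfig(patch_size=5), 96)
        probs = net.predict_proba(np.random.default_rng(1).random((2, 5, 5, 96)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_checkpoint_roundtrip(self, tmp_path):
        net = build_model(ModelConfig(seed=2), 40)
        x = np.random.default_rng(0).random((3, 3, 3, 40))
        path = net.save(tmp_path / "model.npz")
        back = net.load(path)
        np.testing.assert_array_equal(net.predict_proba(x), back.predict_proba(x))


class TestTraining:
    def test_zero_learning_rate_leaves_parameters_unchanged(self, fold_data):
        train_set, val_set = fold_data
        cfg = ModelConfig(learning_rate=0.0, max_epochs=2, early_stop_patience=0, seed=0)
        net = build_model(cfg, train_set.patches.shape[-1])
        before = net.snapshot()
        net = train(net, train_set, val_set, cfg)
        for b, a in zip(before, net._all_params()):
            np.testing.assert_array_equal(b, a)

    def test_patience_zero_stops_at_first_non_improving_epoch(self, fold_data):
        train_set, val_set = fold_data
        cfg = ModelConfig(learning_rate=0.0, max_epochs=10, early_stop_patience=0, seed=0)
        net = build_model(cfg, train_set.patches.shape[-1])
        net = train(net, train_set, val_set, cfg)
        # epoch 0 sets the best; epoch 1 cannot improve at lr 0 -> stop
        assert len(net.history) == 2

    def test_separable_phantom_reaches_high_cancer_f1(self, fold_data):
        train_set, val_set = fold_data
        cfg = ModelConfig(optimizer_name="adam", learning_rate=1e-3,
                          max_epochs=8, early_stop_patience=2, seed=0)
        net = build_model(cfg, train_set.patches.shape[-1])
        net = train(net, train_set, val_set, cfg)
        assert max(h["val_cancer_f1"] for h in net.history) >= 0.9

    def test_adadelta_optimizer_takes_steps(self, fold_data):
        train_set, val_set = fold_data
        cfg = ModelConfig(optimizer_name="adadelta", learning_rate=1.0,
                          max_epochs=1, early_stop_patience=0, seed=0)
        net = build_model(cfg, train_set.patches.shape[-1])
        before = [p.copy() for p in net._all_params()]
        net = train(net, train_set, val_set, cfg)
        assert any(not np.array_equal(b, a)
                   for b, a in zip(before, net._all_params()))

    def test_overlapping_train_val_patients_rejected(self, fold_data):
        train_set, _ = fold_data
        cfg = ModelConfig(max_epochs=1)
        net = build_model(cfg, train_set.patches.shape[-1])
        with pytest.raises(ValueError, match="overlap"):
            train(net, train_set, train_set, cfg)

    def test_validation_without_cancer_rejected(self, fold_data):
        train_set, val_set = fold_data
        keep = val_set.labels != CANCER_CLASS
        no_cancer = PatchDataset(val_set.patches[keep], val_set.labels[keep],
                                 val_set.patient_ids[keep])
        cfg = ModelConfig(max_epochs=1)
        net = build_model(cfg, train_set.patches.shape[-1])
        with pytest.raises(ValueError, match="cancer"):
            train(net, train_set, no_cancer, cfg)

    def test_weighted_loss_equals_unweighted_on_balanced_batch(self):
        """With equal class counts all weights are 1, so the weighted
        cross-entropy reduces to the plain mean."""
        labels = np.repeat([0, 1, 2], 4)
        w = class_weights(labels)
        rng = np.random.default_rng(0)
        probs = rng.dirichlet(np.ones(3), size=12)
        picked = probs[np.arange(12), labels]
        weighted = -(w[labels] * np.log(picked)).mean()
        plain = -np.log(picked).mean()
        assert weighted == pytest.approx(plain, rel=1e-12)


@pytest.fixture(scope="module")
def trained(fold_data):
    train_set, val_set = fold_data
    cfg = ModelConfig(optimizer_name="adam", learning_rate=1e-3,
                      max_epochs=5, early_stop_patience=2, seed=0)
    net = build_model(cfg, train_set.patches.shape[-1])
    return train(net, train_set, val_set, cfg)


class TestPredictMap:
    def test_probabilities_sum_to_one_and_border_unpredicted(self, trained,
                                                            small_cohort):
        p = small_cohort.patients[5]
        pre = preprocess_cube(p.cube, PreprocessConfig())
        label_map, prob_maps = predict_map(trained, pre)
        h, w = label_map.shape
        assert (label_map[0, :] == 0).all() and (label_map[:, 0] == 0).all()
        inner = prob_maps[1:h - 1, 1:w - 1]
        np.testing.assert_allclose(inner.sum(axis=2), 1.0, atol=1e-6)
        assert set(np.unique(label_map[1:h - 1, 1:w - 1])) <= {1, 2, 3}

    def test_trained_model_recovers_mask_interior(self, trained, small_cohort):
        p = small_cohort.patients[5]
        pre = preprocess_cube(p.cube, PreprocessConfig())
        label_map, _ = predict_map(trained, pre)
        interior = np.zeros_like(label_map, dtype=bool)
        interior[1:-1, 1:-1] = True
        usable = interior & (p.mask.labels > 0)
        agreement = (label_map[usable] == p.mask.labels[usable]).mean()
        assert agreement > 0.9

    def test_band_count_mismatch_rejected(self, trained, small_cohort):
        p = small_cohort.patients[5]
        with pytest.raises(ValueError, match="bands"):
            predict_map(trained, p.cube)  # raw cube: 100 bands, model wants 96
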