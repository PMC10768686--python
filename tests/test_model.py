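"""Losses, triplet sampling, training behavior, inference, serialization."""

import numpy as np
import pytest

from deepcsd import model as M, sh, simulate
from deepcsd.errors import InvalidArgumentError


def _loss_oracle(a, b):
    """Independent double-loop implementation of the summed-square loss."""
    total = 0.0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            total += (a[i, j] - b[i, j]) ** 2
    return total / a.shape[0]


class TestLosses:
    def test_fit_loss_zero_and_unit_cases(self):
        p = np.zeros((1, 45))
        assert M.loss_fit(p, p) == 0.0
        q = p.copy()
        q[0, 7] = 1.0
        assert M.loss_fit(q, p) == 1.0

    def test_pair_loss_sign_flip(self):
        u = np.zeros((1, 45))
        v = np.zeros((1, 45))
        u[0, 0], v[0, 0] = 1.0, -1.0
        assert M.loss_pair(u, v) == 4.0

    def test_random_batches_match_double_loop_oracle(self, rng):
        a = rng.standard_normal((17, 45))
        b = rng.standard_normal((17, 45))
        assert M.loss_fit(a, b) == pytest.approx(_loss_oracle(a, b), rel=1e-12)
        assert M.loss_pair(a, b) == pytest.approx(_loss_oracle(a, b), rel=1e-12)

    def test_total_combinations(self):
        assert M.loss_total(2.0, 3.0, M.LossWeights(1.0, 1.0)) == 5.0
        assert M.loss_total(2.0, 3.0, M.LossWeights(1.0, 0.0)) == 2.0
        assert M.loss_total(2.0, 3.0, M.LossWeights(0.0, 0.0)) == 0.0
        with pytest.raises(InvalidArgumentError):
            M.LossWeights(-1.0, 0.0)


@pytest.fixture(scope="module")
def training_world():
    """Small labeled + paired phantom set with GT-based labels (fast)."""
    scheme = simulate.make_gradient_scheme(96, 2000.0, 1, seed=7)
    phantom = simulate.make_phantom((10, 10, 10), seed=4)
    scan, rescan = simulate.make_scan_rescan(phantom, scheme, seed=44)
    from deepcsd import augment
    sig = augment.refit_signal_sh(scan, mask=phantom.wm_mask)
    sig_v = augment.refit_signal_sh(rescan, mask=phantom.wm_mask)
    label = sh.SHField(np.asarray(phantom.gt_fodf.data), sh.SHBasisSpec(8), kind="fodf")
    return phantom, sig, sig_v, label


class TestSampleTriplets:
    def test_shapes_and_pair_alignment(self, training_world):
        phantom, sig, sig_v, label = training_world
        batches = M.sample_triplets([(sig, label, phantom.wm_mask)],
                                    [(sig, sig_v, phantom.wm_mask)],
                                    batch_size=8, seed=0, n_batches=3)
        for tb in batches:
            assert tb.labeled_x.shape == (8, 3, 3, 3, 45)
            assert tb.labels.shape == (8, 45)
            assert tb.paired_u.shape == tb.paired_v.shape == (8, 3, 3, 3, 45)

    def test_paired_patches_from_same_coordinates(self, training_world):
        phantom, sig, sig_v, label = training_world
        # identical paired fields -> identical patches at shared coordinates
        batches = M.sample_triplets([(sig, label, phantom.wm_mask)],
                                    [(sig, sig, phantom.wm_mask)],
                                    batch_size=8, seed=1, n_batches=2)
        for tb in batches:
            np.testing.assert_array_equal(tb.paired_u, tb.paired_v)

    def test_deterministic_stream(self, training_world):
        phantom, sig, sig_v, label = training_world
        args = ([(sig, label, phantom.wm_mask)], [(sig, sig_v, phantom.wm_mask)], 8, 5, 3)
        a = M.sample_triplets(*args)
        b = M.sample_triplets(*args)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.labeled_x, tb.labeled_x)
            np.testing.assert_array_equal(ta.paired_u, tb.paired_u)

    def test_labels_are_center_voxel_coefficients(self, training_world):
        phantom, sig, sig_v, label = training_world
        batches = M.sample_triplets([(sig, label, phantom.wm_mask)], [],
                                    batch_size=16, seed=2, n_batches=1)
        tb = batches[0]
        # each label must occur in the label field at the patch's center
        flat = label.data.reshape(-1, 45)
        for row in tb.labels:
            assert np.any(np.all(np.isclose(flat, row[None, :]), axis=1))


class TestTraining:
    def test_beta0_training_reduces_fit_loss(self, training_world):
        phantom, sig, sig_v, label = training_world
        net = M.build_patch_cnn(M.NetworkConfig(seed=1))
        batches = M.sample_triplets([(sig, label, phantom.wm_mask)], [],
                                    batch_size=64, seed=3, n_batches=4)
        hist = M.train(net, batches, M.LossWeights(1.0, 0.0),
                       M.OptimConfig(lr=3e-3, epochs=12, patience=12))
        assert hist["loss1"][-1] < hist["loss1"][0]
        assert all(l2 == 0.0 for l2 in hist["loss2"])

    def test_beta1_training_reduces_pairing_loss(self, training_world):
        phantom, sig, sig_v, label = training_world
        net = M.build_patch_cnn(M.NetworkConfig(seed=2))
        batches = M.sample_triplets([(sig, label, phantom.wm_mask)],
                                    [(sig, sig_v, phantom.wm_mask)],
                                    batch_size=64, seed=3, n_batches=4)
        hist = M.train(net, batches, M.LossWeights(1.0, 1.0),
                       M.OptimConfig(lr=3e-3, epochs=12, patience=12))
        first_epoch = np.mean(hist["loss2"][:4])
        last_epoch = np.mean(hist["loss2"][-4:])
        assert last_epoch < first_epoch

    def test_training_bit_reproducible(self, training_world):
        phantom, sig, sig_v, label = training_world
        hists = []
        preds = []
        for _ in range(2):
            net = M.build_patch_cnn(M.NetworkConfig(seed=3))
            batches = M.sample_triplets([(sig, label, phantom.wm_mask)], [],
                                        batch_size=32, seed=3, n_batches=2)
            hists.append(M.train(net, batches, M.LossWeights(1.0, 0.0),
                                 M.OptimConfig(lr=1e-3, epochs=3, patience=3)))
            preds.append(net.forward(batches[0].labeled_x, train=False))
        np.testing.assert_array_equal(hists[0]["loss1"], hists[1]["loss1"])
        np.testing.assert_array_equal(preds[0], preds[1])


class TestPredictVolume:
    def test_constant_input_constant_prediction(self, training_world):
        phantom, sig, sig_v, label = training_world
        net = M.build_patch_cnn(M.NetworkConfig(seed=4))
        const = sh.SHField(np.ones(phantom.shape + (45,)), sh.SHBasisSpec(8), kind="signal")
        mask = np.ones(phantom.shape, dtype=bool)
        out = M.predict_volume(net, const, mask)
        inner = out.data[1:-1, 1:-1, 1:-1].reshape(-1, 45)
        assert np.max(np.abs(inner - inner[0][None, :])) < 1e-10

    def test_empty_mask_gives_zero_field(self, training_world):
        phantom, sig, sig_v, label = training_world
        net = M.build_voxel_mlp(M.NetworkConfig(architecture="voxel_mlp", seed=4))
        out = M.predict_volume(net, sig, np.zeros(phantom.shape, dtype=bool))
        assert np.all(out.data == 0.0)

    def test_order_mismatch_rejected(self, training_world):
        phantom, sig, sig_v, label = training_world
        net = M.build_patch_cnn(M.NetworkConfig(seed=4))
        bad = sh.SHField(np.zeros(phantom.shape + (15,)), sh.SHBasisSpec(4))
        with pytest.raises(InvalidArgumentError):
            M.predict_volume(net, bad, phantom.wm_mask)


class TestSerialization:
    def test_save_load_roundtrip_preserves_predictions(self, tmp_path, training_world, rng):
        phantom, sig, sig_v, label = training_world
        net = M.build_patch_cnn(M.NetworkConfig(seed=6))
        net.set_normalization(*M.compute_normalization([(sig, label, phantom.wm_mask)]))
        x = rng.standard_normal((5, 3, 3, 3, 45))
        M.save_model(net, tmp_path / "model", extra_meta={"beta": 1.0})
        loaded = M.load_model(tmp_path / "model")
        np.testing.assert_array_equal(net.forward(x, train=False),
                                      loaded.forward(x, train=False))

    def test_finetune_freeze_keeps_only_dense_trainable(self):
        net = M.build_patch_cnn(M.NetworkConfig(seed=0))
        net.freeze_all_but_dense()
        layers = net.layers()
        for name in ("conv1", "conv2", "conv3", "bn1", "bn2", "bn3"):
            assert all(not p.trainable for p in layers[name].params())
        for name in ("dense1", "dense2", "bn4"):
            assert all(p.trainable for p in layers[name].params())

    def test_frozen_parameters_unchanged_by_training(self, training_world):
        phantom, sig, sig_v, label = training_world
        net = M.build_patch_cnn(M.NetworkConfig(seed=7))
        net.freeze_all_but_dense()
        before = [p.value.copy() for p in net.conv2.params()]
        batches = M.sample_triplets([(sig, label, phantom.wm_mask)], [],
                                    batch_size=32, seed=1, n_batches=2)
        M.train(net, batches, M.LossWeights(1.0, 0.0),
                M.OptimConfig(lr=1e-3, epochs=2, patience=2))
        for b, p in zip(before, net.conv2.params()):
            np.testing.assert_array_equal(b, p.value)
        assert not np.array_equal(net.dense2.W.value, M.build_patch_cnn(M.NetworkConfig(seed=7)).dense2.W.value)
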