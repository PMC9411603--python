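"""Network structure, forward semantics, gradients, and learnability."""
import numpy as np
import pytest

from dse_ecg import (
    ArchitectureDescription,
    DseResNetClassifier,
    ModelConfig,
    build,
    count_parameters,
    forward,
)
from dse_ecg.nn import softmax_cross_entropy
from dse_ecg.nn.optim import SGD

from conftest import REDUCED_MODEL

TINY = ModelConfig(input_len=64, kernel=8, channels=(2, 4), dropout=0.0,
                   head_width=8, seed=1)


def _batch(rng, n, config):
    x = rng.normal(size=(n, config.input_len, config.n_leads, 1)).astype(np.float32)
    aux = rng.uniform(0, 1, size=(n, 2)).astype(np.float32)
    y = rng.integers(0, config.n_classes, size=n)
    return x, aux, y


@pytest.fixture(scope="module")
def full():
    return build(ModelConfig())


class TestArchitecture:

    def test_twenty_trunk_convolutions_with_32x1_kernels(self, full):
        _, desc = full
        assert desc.total_conv2d == 20
        assert desc.kernel == (32, 1)
        convs = [l for l in desc.layers if l["kind"] == "conv2d"]
        assert all(l["kernel"] == [32, 1] for l in convs)

    def test_one_block1_and_nine_block2(self, full):
        _, desc = full
        assert desc.residual_blocks == 10
        assert desc.block1_count == 1
        assert desc.block2_count == 9

    def test_channel_schedule_doubles_from_12_to_192(self, full):
        _, desc = full
        assert desc.channel_schedule == (12, 24, 48, 96, 192)
        convs = [l for l in desc.layers if l["kind"] == "conv2d"]
        # first and last four convolutions carry 12 and 192 kernels
        assert [c["channels_out"] for c in convs[:4]] == [12] * 4
        assert [c["channels_out"] for c in convs[-4:]] == [192] * 4

    def test_dse_module_has_four_dense_layers(self, full):
        _, desc = full
        assert desc.dse_dense_layers == 4

    def test_nine_temporal_halvings(self, full):
        _, desc = full
        assert desc.downsample_factor == 512  # 8192 -> 16

    def test_age_sex_ablation_switch(self):
        cfg = ModelConfig(input_len=64, kernel=8, channels=(2, 4),
                          use_age_sex=False, seed=0)
        net, desc = build(cfg)
        assert desc.aux_inputs is False
        x = np.zeros((2, 64, 12, 1), dtype=np.float32) + 0.1
        assert forward(net, x).shape == (2, 9)

    def test_indivisible_input_length_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(input_len=100, channels=(2, 4))

    def test_non_doubling_schedule_rejected(self):
        with pytest.raises(ValueError, match="double"):
            ModelConfig(channels=(12, 20))

    def test_description_round_trips_through_json(self, full):
        _, desc = full
        back = ArchitectureDescription.from_json(desc.to_json())
        assert back == desc

    def test_equal_configs_build_equal_parameter_counts(self):
        a, _ = build(TINY)
        b, _ = build(TINY)
        assert count_parameters(a) == count_parameters(b)

    def test_wider_schedule_has_more_parameters(self):
        small, _ = build(TINY)
        big, _ = build(ModelConfig(input_len=64, kernel=8, channels=(4, 8),
                                   dropout=0.0, head_width=8, seed=1))
        assert count_parameters(big) > count_parameters(small)


class TestForward:
    def test_probability_rows_sum_to_one(self):
        net, _ = build(TINY)
        rng = np.random.default_rng(0)
        x, aux, _ = _batch(rng, 5, TINY)
        p = forward(net, x, aux)
        assert p.shape == (5, 9)
        assert np.all(p >= 0)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-5)

    def test_identical_inputs_identical_outputs(self):
        net, _ = build(TINY)
        rng = np.random.default_rng(1)
        x, aux, _ = _batch(rng, 1, TINY)
        x2 = np.concatenate([x, x])
        aux2 = np.concatenate([aux, aux])
        p = forward(net, x2, aux2)
        np.testing.assert_array_equal(p[0], p[1])

    def test_shape_mismatch_rejected(self):
        net, _ = build(TINY)
        with pytest.raises(ValueError, match="expected input"):
            net.forward_logits(np.zeros((2, 32, 12, 1), dtype=np.float32))

    def test_uniform_predictor_loss_is_ln_nine(self):
        logits = np.zeros((7, 9))
        labels = np.arange(7) % 9
        loss, _ = softmax_cross_entropy(logits, labels)
        assert loss == pytest.approx(np.log(9.0), abs=1e-9)

    def test_lead_permutation_changes_output(self):
        """Inter-lead structure is used: the net is not permutation-invariant."""
        net, _ = build(TINY)
        rng = np.random.default_rng(2)
        x, aux, y = _batch(rng, 8, TINY)
        opt = SGD(net.parameters(), lr=0.05, momentum=0.9)
        for _ in range(5):  # a few steps so weights are not at init symmetry
            opt.zero_grad()
            loss, d = softmax_cross_entropy(net.forward_logits(x, aux, True), y)
            net.backward(d)
            opt.step()
        perm = rng.permutation(12)
        p1 = forward(net, x, aux)
        p2 = forward(net, x[:, :, perm, :], aux)
        assert not np.allclose(p1, p2, atol=1e-6)


def _layer_gradcheck(layer, x, eps=1e-3, n_input=12, n_param=8):
    """Finite-difference check of one layer under loss = Σ y·W."""
    rng = np.random.default_rng(0)
    y = layer.forward(x, training=True)
    W = rng.normal(size=y.shape).astype(np.float32)

    def loss():
        return float((layer.forward(x, True).astype(np.float64) * W).sum())

    params = layer.parameters()
    for p in params:
        p.grad[...] = 0
    dx = layer.backward(W)
    rngi = np.random.default_rng(1)
    flat = x.reshape(-1)
    for idx in rngi.choice(flat.size, size=min(n_input, flat.size), replace=False):
        orig = flat[idx]
        flat[idx] = orig + eps
        lp = loss()
        flat[idx] = orig - eps
        lm = loss()
        flat[idx] = orig
        fd = (lp - lm) / (2 * eps)
        assert dx.reshape(-1)[idx] == pytest.approx(fd, rel=0.03, abs=2e-3)
    layer.forward(x, True)
    for p in params:
        pf, g = p.value.reshape(-1), p.grad.reshape(-1)
        for idx in rngi.choice(pf.size, size=min(n_param, pf.size), replace=False):
            orig = pf[idx]
            pf[idx] = orig + eps
            lp = loss()
            pf[idx] = orig - eps
            lm = loss()
            pf[idx] = orig
            fd = (lp - lm) / (2 * eps)
            assert g[idx] == pytest.approx(fd, rel=0.03, abs=2e-3), p.name


class TestGradients:
    def test_layer_gradients_match_finite_differences(self):
        """Backprop of every differentiable layer agrees with central
        differences (the ReLU-free layers are smooth, so agreement is tight)."""
        from dse_ecg.nn import BatchNorm, ChannelPad, Conv2dTime, Dense, MaxPoolTime
        from dse_ecg.model import TimeAvgFlatten

        rng = np.random.default_rng(3)
        x4 = rng.normal(size=(3, 16, 5, 2)).astype(np.float32)
        _layer_gradcheck(Conv2dTime(4, 2, 3, stride=2, rng=rng), x4.copy())
        _layer_gradcheck(Conv2dTime(5, 2, 3, stride=1, rng=rng), x4.copy())
        _layer_gradcheck(BatchNorm(2), x4.copy())
        _layer_gradcheck(MaxPoolTime(2), x4.copy())
        _layer_gradcheck(ChannelPad(2, 5), x4.copy())
        _layer_gradcheck(TimeAvgFlatten(), x4.copy())
        _layer_gradcheck(Dense(6, 4, rng=rng),
                         rng.normal(size=(5, 6)).astype(np.float32))

    def test_full_network_gradient_agreement(self):
        """End-to-end backprop agrees with finite differences on the large
        majority of sampled coordinates (exact agreement is impossible at
        ReLU kinks and float32 forward noise)."""
        cfg = ModelConfig(input_len=16, kernel=4, channels=(2, 4), dropout=0.0,
                          head_width=4, seed=3)
        net, _ = build(cfg)
        rng = np.random.default_rng(4)
        x = rng.normal(size=(3, 16, 12, 1)).astype(np.float32)
        aux = rng.uniform(size=(3, 2)).astype(np.float32)
        y = np.array([0, 3, 7])

        def loss_fn():
            return softmax_cross_entropy(net.forward_logits(x, aux, True), y)[0]

        _, d = softmax_cross_entropy(net.forward_logits(x, aux, True), y)
        for p in net.parameters():
            p.grad[...] = 0
        net.backward(d)
        rng2 = np.random.default_rng(5)
        agree = total = 0
        for p in net.parameters():
            if "bn" in p.name:
                continue
            flat, gflat = p.value.reshape(-1), p.grad.reshape(-1)
            for idx in rng2.choice(flat.size, size=min(3, flat.size), replace=False):
                eps = 2e-3
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = loss_fn()
                flat[idx] = orig - eps
                lm = loss_fn()
                flat[idx] = orig
                fd = (lp - lm) / (2 * eps)
                total += 1
                agree += abs(gflat[idx] - fd) <= max(0.08 * abs(fd), 2e-3)
        assert total > 50
        assert agree / total >= 0.85

    def test_single_sgd_step_decreases_batch_loss(self):
        net, _ = build(TINY)
        rng = np.random.default_rng(6)
        x, aux, y = _batch(rng, 16, TINY)
        opt = SGD(net.parameters(), lr=0.02, momentum=0.0)
        logits = net.forward_logits(x, aux, training=True)
        loss0, d = softmax_cross_entropy(logits, y)
        net.backward(d)
        opt.step()
        loss1, _ = softmax_cross_entropy(net.forward_logits(x, aux, True), y)
        assert loss1 < loss0


class TestClassifier:
    def test_fit_predict_roundtrip_and_sklearn_protocol(self):
        rng = np.random.default_rng(7)
        n = 24
        x = rng.normal(size=(n, 64, 12, 1)).astype(np.float32)
        # separable toy problem: class encoded in the mean of lead 0
        y = np.array(["Normal", "AF"] * (n // 2))
        x[y == "AF", :, 0, 0] += 2.0
        clf = DseResNetClassifier(input_len=64, kernel=8, channels=(2, 4),
                                  dropout=0.0, epochs=12, batch_size=8,
                                  learning_rate=0.05, random_state=0)
        assert clf.get_params()["kernel"] == 8
        clf.fit(x, y)
        assert set(clf.classes_) == {"Normal", "AF"}
        proba = clf.predict_proba(x)
        assert proba.shape == (n, 2)
        assert (clf.predict(x) == y).mean() > 0.9
        assert clf.architecture_.total_conv2d == 8

    def test_same_seed_reproduces_training_exactly(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(12, 64, 12, 1)).astype(np.float32)
        y = np.array(["Normal", "AF", "PVC"] * 4)
        kw = dict(input_len=64, kernel=8, channels=(2, 4), dropout=0.3,
                  epochs=3, batch_size=4, random_state=5)
        a = DseResNetClassifier(**kw).fit(x, y)
        b = DseResNetClassifier(**kw).fit(x, y)
        assert a.loss_curve_ == b.loss_curve_
        np.testing.assert_array_equal(a.predict_proba(x), b.predict_proba(x))


class TestOverfitCapability:
    def test_reduced_net_reaches_95_percent_on_separable_classes(self):
        """64 noise-free slices from three well-separated rhythm classes are
        fit to ≥95% training accuracy within 200 optimizer steps."""
        from dse_ecg import EcgPreprocessor, SynthConfig, synth_dataset
        from dse_ecg.experiment import slices_to_arrays

        cfg = SynthConfig(
            n_records=64, seed=3,
            class_mix={"Normal": 1 / 3, "LBBB": 1 / 3, "STE": 1 / 3},
            duration_range=(2.0, 2.2), duration_lognorm=(np.log(2.1), 0.02),
            heart_rate_range=(65.0, 90.0),
        ).noise_free()
        records, _ = synth_dataset(cfg)
        pre = EcgPreprocessor(slice_len=1024, overlap=512)
        X, y, aux, _ = slices_to_arrays(pre.transform(records))
        assert X.shape[0] == 64
        clf = DseResNetClassifier(
            **REDUCED_MODEL, dropout=0.0, learning_rate=0.05, momentum=0.9,
            epochs=50, batch_size=16, random_state=0,
        )  # 64/16 = 4 steps per epoch -> 200 steps
        clf.fit(X, y, aux=aux)
        _, acc = clf.evaluate(X, y, aux)
        assert acc >= 0.95
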