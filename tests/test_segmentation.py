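"""U-Net construction, gradients, training contracts and the grid."""

import numpy as np
import pytest

from mammoseg import nn
from mammoseg.images import ValidationError
from mammoseg.segmentation import (
    UNetConfig,
    build_unet,
    grid_report,
    load_weights,
    predict,
    run_grid,
    save_weights,
    standard_grid,
    train,
)


def closed_form_param_count(depth, base, in_ch=1, norm=True):
    """Independent parameter count from the architecture definition."""
    def double_conv(cin, c):
        n = (9 * cin * c + c) + (9 * c * c + c)  # two 3x3 convs with bias
        if norm:
            n += 4 * c  # two BN layers: gamma + beta each
        return n

    chs = [base * 2**k for k in range(depth)]
    total, prev = 0, in_ch
    for c in chs:
        total += double_conv(prev, c)
        prev = c
    bott = base * 2**depth
    total += double_conv(prev, bott)
    prev = bott
    for c in reversed(chs):
        total += 4 * prev * c + c  # 2x2 up-conv
        total += double_conv(2 * c, c)
        prev = c
    total += chs[0] * 1 + 1  # 1x1 head
    return total


def tiny_data(rng, n=8, size=16):
    """Bright-blob images with their truth masks."""
    X, Y = [], []
    for _ in range(n):
        img = rng.normal(0.2, 0.02, (size, size))
        mask = np.zeros((size, size), bool)
        r, c = rng.integers(2, size - 6, 2)
        mask[r : r + 5, c : c + 5] = True
        img[mask] += 0.5
        X.append(np.clip(img, 0, 1).astype(np.float32))
        Y.append(mask)
    return X, Y


class TestArchitecture:
    def test_encoder_channel_doubling(self):
        assert UNetConfig(depth=3, base_kernels=64).encoder_channels() == [64, 128, 256]
        assert UNetConfig(depth=5, base_kernels=8).encoder_channels() == [8, 16, 32, 64, 128]

    @pytest.mark.parametrize("depth,base,norm", [(2, 4, "batch"), (3, 2, "none")])
    def test_param_count_matches_closed_form(self, depth, base, norm):
        model = build_unet(UNetConfig(depth=depth, base_kernels=base, norm=norm))
        assert model.num_params == closed_form_param_count(
            depth, base, norm=(norm == "batch")
        )

    def test_build_is_deterministic(self):
        cfg = UNetConfig(depth=2, base_kernels=4, seed=11)
        a, b = build_unet(cfg), build_unet(cfg)
        for pa, pb in zip(a.params(), b.params()):
            assert np.array_equal(pa.value, pb.value)

    def test_output_shape_matches_input(self, rng):
        model = build_unet(UNetConfig(depth=2, base_kernels=2, seed=0))
        z = model.forward(rng.random((2, 32, 32)).astype(np.float32))
        assert z.shape == (2, 32, 32)

    def test_indivisible_input_rejected(self, rng):
        model = build_unet(UNetConfig(depth=3, base_kernels=2, seed=0))
        with pytest.raises(ValidationError):
            model.forward(rng.random((1, 36, 36)).astype(np.float32))

    def test_deep_bottleneck_on_large_input(self, rng):
        """Depth 6 halves a 256-px frame down to a 4-px bottleneck."""
        model = build_unet(UNetConfig(depth=6, base_kernels=1, seed=0))
        z = model.forward(rng.random((1, 256, 256)).astype(np.float32))
        assert z.shape == (1, 256, 256)


class TestGradients:
    def test_backprop_matches_finite_differences(self, rng):
        model = build_unet(UNetConfig(depth=2, base_kernels=3, seed=1))
        # randomise the (normally zero-initialised) head so gradients flow
        # through every layer
        head = model.head
        head.W.value[...] = rng.normal(0, 0.3, head.W.value.shape)
        x = rng.random((2, 8, 8)).astype(np.float32)
        y = rng.random((2, 8, 8)) > 0.5

        def loss():
            return nn.bce_with_logits(model.forward(x), y)

        _, dz = loss()
        params = model.params()
        for p in params:
            p.zero_grad()
        model.backward(dz)

        # directional derivative along the steepest-descent direction:
        # pointwise float32 differences are dominated by ReLU/pool kinks,
        # but the dense projection averages those out and its magnitude
        # (the gradient norm) sits well above the float32 noise floor
        eps = 2e-4
        gnorm = np.sqrt(sum(float((p.grad ** 2).sum()) for p in params))
        dirs = [p.grad / gnorm for p in params]
        analytic = sum(float((p.grad * d).sum()) for p, d in zip(params, dirs))
        saved = [p.value.copy() for p in params]
        for p, d in zip(params, dirs):
            p.value += eps * d
        lp, _ = loss()
        for p, s, d in zip(params, saved, dirs):
            p.value[...] = s - eps * d
        lm, _ = loss()
        for p, s in zip(params, saved):
            p.value[...] = s
        numeric = (lp - lm) / (2 * eps)
        assert analytic == pytest.approx(numeric, rel=0.02)

    def test_batchnorm_gradients_exact(self, rng):
        """BatchNorm backward matches finite differences away from kinks
        (linear surrogate loss, float64 differences)."""
        bn = nn.BatchNorm(3)
        x = rng.normal(1.0, 2.0, (2, 4, 4, 3)).astype(np.float32)
        R = rng.normal(0, 1, (2, 4, 4, 3)).astype(np.float32)

        def loss():
            return float((bn.forward(x) * R).sum())

        loss()
        bn.gamma.zero_grad()
        bn.beta.zero_grad()
        bn.backward(R)
        eps = 1e-2
        for p in (bn.gamma, bn.beta):
            for k in range(p.value.size):
                old = p.value[k]
                p.value[k] = old + eps
                lp = loss()
                p.value[k] = old - eps
                lm = loss()
                p.value[k] = old
                assert float(p.grad[k]) == pytest.approx(
                    (lp - lm) / (2 * eps), rel=1e-2, abs=1e-3
                )


class TestTraining:
    def test_zero_learning_rate_is_null_training(self, rng):
        X, Y = tiny_data(rng)
        cfg = UNetConfig(depth=2, base_kernels=2, learning_rate=0.0, epochs=3,
                         batch_size=4, seed=2)
        model = build_unet(cfg)
        before = [p.value.copy() for p in model.params()]
        rec = train(model, (X[:6], Y[:6]), (X[6:], Y[6:]), cfg)
        for p, b in zip(model.params(), before):
            assert np.array_equal(p.value, b)
        assert len(set(rec.val_dice)) == 1

    def test_seeded_training_reproducible(self, rng):
        X, Y = tiny_data(rng)
        cfg = UNetConfig(depth=2, base_kernels=2, learning_rate=1e-4, epochs=3,
                         batch_size=4, seed=5)
        recs = []
        for _ in range(2):
            model = build_unet(cfg)
            recs.append(train(model, (X[:6], Y[:6]), (X[6:], Y[6:]), cfg))
        assert recs[0].val_dice == recs[1].val_dice
        assert recs[0].epoch_loss == recs[1].epoch_loss

    def test_training_learns_bright_blobs(self, rng):
        """Validation Dice improves over the null model on an easy task."""
        # the loss sums over pixels, so a 16x16 frame needs a larger
        # nominal rate for the same effective step as a full-size image
        X, Y = tiny_data(rng, n=16, size=16)
        cfg = UNetConfig(depth=2, base_kernels=4, learning_rate=1e-2, epochs=10,
                         batch_size=4, seed=3)
        model = build_unet(cfg)
        rec = train(model, (X[:12], Y[:12]), (X[12:], Y[12:]), cfg)
        assert rec.best_val_dice > rec.val_dice[0] or rec.val_dice[0] > 0.8
        assert rec.best_val_dice > 0.5

    def test_empty_training_set_rejected(self, rng):
        cfg = UNetConfig(depth=2, base_kernels=2, epochs=1)
        X, Y = tiny_data(rng, n=2)
        with pytest.raises(ValidationError):
            train(build_unet(cfg), ([], []), (X, Y), cfg)

    def test_replicates_are_distinct_runs(self, rng):
        X, Y = tiny_data(rng)
        cfg = UNetConfig(depth=2, base_kernels=2, learning_rate=1e-3, epochs=2,
                         batch_size=4, seed=1)
        datasets = {"d": {"train": (X[:6], Y[:6]), "val": (X[6:], Y[6:])}}
        records = run_grid([cfg], datasets, replicates=3)
        assert len(records) == 3
        assert {r.replicate for r in records} == {1, 2, 3}
        assert {r.config.seed for r in records} == {2, 3, 4}


class TestPredict:
    def test_mask_area_monotone_in_threshold(self, rng):
        model = build_unet(UNetConfig(depth=2, base_kernels=2, seed=4))
        model.head.W.value[...] = rng.normal(0, 0.5, model.head.W.value.shape)
        img = rng.random((16, 16)).astype(np.float32)
        areas = [predict(model, img, t).sum() for t in (0.3, 0.5, 0.7, 0.9)]
        assert all(a >= b for a, b in zip(areas, areas[1:]))

    def test_all_zero_input_is_total(self):
        model = build_unet(UNetConfig(depth=2, base_kernels=2, seed=0))
        mask = predict(model, np.zeros((16, 16), dtype=np.float32))
        assert mask.shape == (16, 16) and mask.dtype == bool

    def test_weight_roundtrip_preserves_predictions(self, rng, tmp_path):
        X, Y = tiny_data(rng)
        cfg = UNetConfig(depth=2, base_kernels=2, learning_rate=1e-3, epochs=2,
                         batch_size=4, seed=6)
        model = build_unet(cfg)
        train(model, (X[:6], Y[:6]), (X[6:], Y[6:]), cfg)
        save_weights(tmp_path / "w.npz", model)
        loaded = load_weights(tmp_path / "w.npz")
        assert np.array_equal(predict(model, X[0]), predict(loaded, X[0]))


class TestGrid:
    def test_full_grid_enumerates_twenty_cells(self):
        grid = standard_grid()
        assert len(grid) == 20
        assert {c.depth for c in grid} == {3, 4, 5, 6, 7}
        assert {c.learning_rate for c in grid} == {1e-3, 1e-4}
        assert {c.batch_size for c in grid} == {16, 32}

    def test_desk_scale_grid_report(self, rng):
        X, Y = tiny_data(rng)
        datasets = {"d": {"train": (X[:6], Y[:6]), "val": (X[6:], Y[6:])}}
        grid = standard_grid(depths=(2, 3), learning_rates=(1e-3,), batch_sizes=(4,),
                             base_kernels=2, epochs=2)
        records = run_grid(grid, datasets, replicates=3)
        table = grid_report(records)
        assert len(table) == 2
        assert (table["n_replicates"] == 3).all()

    def test_single_replicate_average_is_the_run(self, rng):
        X, Y = tiny_data(rng)
        datasets = {"d": {"train": (X[:6], Y[:6]), "val": (X[6:], Y[6:])}}
        cfg = UNetConfig(depth=2, base_kernels=2, learning_rate=1e-3, epochs=2,
                         batch_size=4, seed=8)
        records = run_grid([cfg], datasets, replicates=1)
        table = grid_report(records)
        assert table["mean_dice"].iloc[0] == pytest.approx(records[0].test_dice)
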