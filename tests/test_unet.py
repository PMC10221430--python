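"""Network building blocks, parameter accounting, loss, and training."""

import numpy as np
import pytest
from scipy import ndimage

from fundoseg import nn
from fundoseg.training import (
    SegmentationModel,
    TrainConfig,
    dice_loss,
    dice_loss_grad,
    predict_mask,
)
from fundoseg.unet import UNet, UNetConfig, parameter_count


class TestLayers:
    def test_conv2d_matches_scipy_correlate(self, rng):
        x = rng.normal(size=(2, 3, 9, 9)).astype(np.float32)
        w = rng.normal(size=(4, 3, 3, 3)).astype(np.float32)
        b = rng.normal(size=4).astype(np.float32)
        out, _ = nn.conv2d(x, w, b)
        for n in range(2):
            for o in range(4):
                expected = sum(
                    ndimage.correlate(x[n, c].astype(float), w[o, c].astype(float),
                                      mode="constant")
                    for c in range(3)
                ) + b[o]
                assert np.allclose(out[n, o], expected, atol=1e-4)

    def test_conv_transpose_upsamples_by_two_exactly(self, rng):
        x = rng.normal(size=(1, 2, 3, 3)).astype(np.float32)
        w = rng.normal(size=(2, 5, 2, 2)).astype(np.float32)
        b = np.zeros(5, dtype=np.float32)
        out, _ = nn.conv_transpose2x2(x, w, b)
        assert out.shape == (1, 5, 6, 6)
        # output patch (2h+i, 2w+j) = sum_c x[c,h,w] * w[c,o,i,j]
        for i in range(2):
            for j in range(2):
                expected = np.einsum("chw,co->ohw", x[0], w[:, :, i, j])
                assert np.allclose(out[0, :, i::2, j::2], expected, atol=1e-5)

    def test_maxpool_matches_block_reduction(self, rng):
        x = rng.normal(size=(2, 3, 8, 8)).astype(np.float32)
        out, _ = nn.maxpool2x2(x)
        expected = x.reshape(2, 3, 4, 2, 4, 2).max(axis=(3, 5))
        assert np.array_equal(out, expected)

    def test_maxpool_backward_routes_gradient_to_argmax(self):
        x = np.array([[[[1.0, 2.0], [3.0, 4.0]]]], dtype=np.float32)
        out, cache = nn.maxpool2x2(x)
        dx = nn.maxpool2x2_backward(np.ones_like(out), cache)
        assert dx.tolist() == [[[[0.0, 0.0], [0.0, 1.0]]]]


class TestArchitecture:
    @pytest.mark.parametrize("depth", [1, 2, 3])
    @pytest.mark.parametrize("size", [32, 64])
    def test_output_spatial_dims_match_input(self, depth, size):
        model = UNet(UNetConfig(depth=depth, base_channels=4), seed=0)
        x = np.zeros((1, 3, size, size), dtype=np.float32)
        probs = model.forward(x)
        assert probs.shape == (1, 1, size, size)
        assert probs.min() > 0 and probs.max() < 1  # sigmoid output

    def test_indivisible_input_side_raises_shape_error(self):
        model = UNet(UNetConfig(depth=3, base_channels=4), seed=0)
        with pytest.raises(ValueError, match="divisible"):
            model.forward(np.zeros((1, 3, 36, 36), dtype=np.float32))

    def test_parameter_count_closed_form_equals_enumeration(self):
        for cfg in (UNetConfig(), UNetConfig(depth=2, base_channels=8),
                    UNetConfig(depth=1, base_channels=4)):
            assert parameter_count(cfg) == UNet(cfg, seed=0).n_parameters()

    def test_single_level_count_by_hand(self):
        # depth 1, base 1, in 3, out 1:
        # enc: 3x3x3x1+1=28, 3x3x1x1+1=10; bottleneck (2ch): 3x3x1x2+2=20,
        # 3x3x2x2+2=38; up: 2x2x2x1+1=9; dec: 3x3x2x1+1=19, 10; final 1x1: 2
        cfg = UNetConfig(depth=1, base_channels=1)
        assert parameter_count(cfg) == 28 + 10 + 20 + 38 + 9 + 19 + 10 + 2

    def test_doubling_width_quadruples_parameters_asymptotically(self):
        small = parameter_count(UNetConfig(depth=3, base_channels=16))
        big = parameter_count(UNetConfig(depth=3, base_channels=32))
        assert 3.5 < big / small < 4.5

    def test_checkpoint_roundtrip(self, tmp_path):
        cfg = UNetConfig(depth=1, base_channels=2)
        model = UNet(cfg, seed=5)
        model.save(tmp_path / "ckpt.npz")
        clone = UNet.load(tmp_path / "ckpt.npz", cfg)
        x = np.random.default_rng(0).normal(size=(1, 3, 16, 16)).astype(np.float32)
        assert np.array_equal(model.forward(x), clone.forward(x))


class TestDiceLoss:
    def test_perfect_overlap_is_near_zero(self):
        t = (np.random.default_rng(0).random((1, 1, 8, 8)) < 0.4).astype(np.float32)
        assert dice_loss(t, t) < 1e-5

    def test_disjoint_masks_lose_everything(self):
        t = np.zeros((1, 1, 4, 4), dtype=np.float32)
        t[0, 0, :2] = 1
        p = 1 - t
        assert dice_loss(p, t) == pytest.approx(1.0, abs=1e-5)

    def test_uniform_half_probability_closed_form(self):
        # p = 0.5 everywhere, t = 1 on half the pixels:
        # loss = 1 - (2*0.5*N/2) / (0.5N + N/2) = 0.5
        t = np.zeros((1, 1, 10, 10), dtype=np.float32)
        t[0, 0, :5] = 1
        p = np.full_like(t, 0.5)
        assert dice_loss(p, t) == pytest.approx(0.5, abs=1e-6)

    def test_gradient_matches_finite_differences(self, rng):
        p = rng.uniform(0.2, 0.8, size=(2, 1, 5, 5))
        t = (rng.random((2, 1, 5, 5)) < 0.4).astype(float)
        grad = dice_loss_grad(p, t)
        eps = 1e-6
        for idx in [(0, 0, 1, 1), (1, 0, 3, 2), (0, 0, 4, 4)]:
            pp = p.copy()
            pp[idx] += eps
            pm = p.copy()
            pm[idx] -= eps
            numeric = (dice_loss(pp, t) - dice_loss(pm, t)) / (2 * eps)
            assert grad[idx] == pytest.approx(numeric, rel=1e-3, abs=1e-8)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros((1, 1, 4, 4)), np.zeros((1, 1, 5, 5)))


def _separable_batch(rng, n, size=16):
    """Tiny bright-square-on-dark scenes, trivially separable."""
    x = np.full((n, 3, size, size), -0.8, dtype=np.float32)
    y = np.zeros((n, 1, size, size), dtype=np.float32)
    for i in range(n):
        r, c = rng.integers(2, size - 7, size=2)
        h, w = rng.integers(4, 7, size=2)
        x[i, :, r : r + h, c : c + w] = 0.8
        y[i, 0, r : r + h, c : c + w] = 1
    return x, y


class TestTraining:
    def test_full_backward_matches_finite_differences(self, rng):
        model = UNet(UNetConfig(depth=1, base_channels=2), seed=3)
        for k in model.params:
            model.params[k] = model.params[k].astype(np.float64)
        x = rng.normal(0, 0.5, (2, 3, 8, 8)).clip(-1, 1)
        y = (rng.random((2, 1, 8, 8)) < 0.3).astype(float)
        probs, cache = model.forward(x, want_cache=True)
        grads = model.backward(dice_loss_grad(probs, y), cache)
        eps = 1e-6
        for name in ("enc0_c1_w", "bott_c2_w", "up0_w", "dec0_c1_w", "final_w",
                     "enc0_c2_b"):
            flat = model.params[name].ravel()
            for i in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                old = flat[i]
                flat[i] = old + eps
                lp = dice_loss(model.forward(x), y)
                flat[i] = old - eps
                lm = dice_loss(model.forward(x), y)
                flat[i] = old
                numeric = (lp - lm) / (2 * eps)
                analytic = grads[name].ravel()[i]
                assert analytic == pytest.approx(numeric, rel=1e-3, abs=1e-7)

    def test_one_adam_step_decreases_loss_across_seeds(self, rng):
        from fundoseg.nn import Adam

        for seed in range(10):
            model = UNet(UNetConfig(depth=1, base_channels=4), seed=seed)
            x, y = _separable_batch(np.random.default_rng(seed), 1)
            probs, cache = model.forward(x, want_cache=True)
            before = dice_loss(probs, y)
            grads = model.backward(dice_loss_grad(probs, y), cache)
            Adam(model.params, lr=1e-4).step(grads)
            after = dice_loss(model.forward(x), y)
            assert after < before

    def test_smoke_fit_reduces_loss_and_fills_history(self, rng):
        x, y = _separable_batch(rng, 20)
        model = SegmentationModel(
            x[:16], y[:16], x[16:], y[16:],
            unet_config=UNetConfig(depth=2, base_channels=4),
            train_config=TrainConfig(epochs=5, batch_size=4, learning_rate=1e-3,
                                     seed=0),
        )
        results = model.fit()
        assert len(results.history) == 5
        assert list(results.history.columns) == [
            "epoch", "train_loss", "val_loss", "train_jaccard", "val_jaccard"]
        assert results.history["train_loss"].iloc[-1] < results.history["train_loss"].iloc[0]
        assert 1 <= results.best_epoch <= 5
        assert "best val Dice loss" in results.summary()

    def test_training_is_deterministic_given_seed(self, rng):
        x, y = _separable_batch(rng, 8)
        traces = []
        for _ in range(2):
            model = SegmentationModel(
                x[:6], y[:6], x[6:], y[6:],
                unet_config=UNetConfig(depth=1, base_channels=2),
                train_config=TrainConfig(epochs=3, batch_size=2, seed=4),
            )
            traces.append(model.fit().history)
        assert traces[0].equals(traces[1])

    def test_zero_learning_rate_freezes_the_loss_trace(self, rng):
        x, y = _separable_batch(rng, 8)
        model = SegmentationModel(
            x[:6], y[:6], x[6:], y[6:],
            unet_config=UNetConfig(depth=1, base_channels=2),
            train_config=TrainConfig(epochs=3, batch_size=6, learning_rate=0.0,
                                     seed=0),
        )
        history = model.fit().history
        assert history["train_loss"].max() - history["train_loss"].min() < 1e-10

    def test_empty_split_rejected(self, rng):
        x, y = _separable_batch(rng, 4)
        with pytest.raises(ValueError):
            SegmentationModel(x[:0], y[:0], x, y)


class TestPredictMask:
    def test_threshold_semantics(self):
        model = UNet(UNetConfig(depth=1, base_channels=2), seed=0)
        x = np.zeros((2, 3, 16, 16), dtype=np.float32)
        probs = model.forward(x)[:, 0]
        mask = predict_mask(model, x, threshold=0.5)
        assert np.array_equal(mask, probs >= 0.5)
        assert not predict_mask(model, x, threshold=1.01).any()

    def test_unnormalized_input_rejected(self):
        model = UNet(UNetConfig(depth=1, base_channels=2), seed=0)
        with pytest.raises(ValueError, match="normalized"):
            predict_mask(model, np.full((1, 3, 16, 16), 200.0, dtype=np.float32))
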