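"""U-Net encoder–decoder for binary structure segmentation.

The encoder compresses the input through ``depth`` double-convolution
blocks (3x3 kernels, ReLU, channel width doubling each level, 2x2 max
pooling); the decoder mirrors it with 2x2 stride-2 transposed
convolutions, concatenating each encoder block's features with the
decoder features at the same spatial resolution (skip connections); a
final 1x1 convolution plus sigmoid maps to one foreground-probability
channel.  One network is trained per structure (disc, cup) so that cup
segmentation never competes with disc segmentation inside one head.

Forward and backward passes are explicit numpy (see :mod:`fundoseg.nn`);
the model is a named dict of parameter arrays, so snapshots and
determinism are straightforward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn

__all__ = ["UNetConfig", "UNet", "parameter_count"]


@dataclass(frozen=True)
class UNetConfig:
    in_channels: int = 3
    out_channels: int = 1
    depth: int = 4
    base_channels: int = 32
    kernel_size: int = 3  # fixed: 3x3 convolutions throughout

    def validate(self) -> None:
        if self.kernel_size != 3:
            raise ValueError("kernel_size is fixed at 3 (3x3 convolutions)")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")

    def level_channels(self, level: int) -> int:
        return self.base_channels * (2**level)


def _conv_params(c_in: int, c_out: int, k: int) -> int:
    return k * k * c_in * c_out + c_out


def parameter_count(config: UNetConfig) -> int:
    """Closed-form trainable parameter total (weights + biases).

    Sums k^2*c_in*c_out + c_out over every convolution and transposed
    convolution; there are no normalization layers.
    """
    config.validate()
    k = config.kernel_size
    total = 0
    c_prev = config.in_channels
    for level in range(config.depth):
        ch = config.level_channels(level)
        total += _conv_params(c_prev, ch, k) + _conv_params(ch, ch, k)
        c_prev = ch
    bottleneck = config.level_channels(config.depth)
    total += _conv_params(c_prev, bottleneck, k) + _conv_params(bottleneck, bottleneck, k)
    c_prev = bottleneck
    for level in reversed(range(config.depth)):
        ch = config.level_channels(level)
        total += 2 * 2 * c_prev * ch + ch  # transposed conv
        total += _conv_params(2 * ch, ch, k) + _conv_params(ch, ch, k)
        c_prev = ch
    total += _conv_params(c_prev, config.out_channels, 1)
    return total


class UNet:
    """Parameter container plus explicit forward/backward passes."""

    def __init__(self, config: UNetConfig, seed: int = 0):
        config.validate()
        self.config = config
        self.params: dict[str, np.ndarray] = {}
        rng = np.random.default_rng(seed)
        k = config.kernel_size

        def add_conv(name: str, c_in: int, c_out: int, ksize: int) -> None:
            # He initialization for ReLU nonlinearities
            std = np.sqrt(2.0 / (ksize * ksize * c_in))
            self.params[f"{name}_w"] = rng.normal(0, std, (c_out, c_in, ksize, ksize)).astype(np.float32)
            self.params[f"{name}_b"] = np.zeros(c_out, dtype=np.float32)

        def add_up(name: str, c_in: int, c_out: int) -> None:
            std = np.sqrt(2.0 / (2 * 2 * c_in))
            self.params[f"{name}_w"] = rng.normal(0, std, (c_in, c_out, 2, 2)).astype(np.float32)
            self.params[f"{name}_b"] = np.zeros(c_out, dtype=np.float32)

        c_prev = config.in_channels
        for lvl in range(config.depth):
            ch = config.level_channels(lvl)
            add_conv(f"enc{lvl}_c1", c_prev, ch, k)
            add_conv(f"enc{lvl}_c2", ch, ch, k)
            c_prev = ch
        bott = config.level_channels(config.depth)
        add_conv("bott_c1", c_prev, bott, k)
        add_conv("bott_c2", bott, bott, k)
        c_prev = bott
        for lvl in reversed(range(config.depth)):
            ch = config.level_channels(lvl)
            add_up(f"up{lvl}", c_prev, ch)
            add_conv(f"dec{lvl}_c1", 2 * ch, ch, k)
            add_conv(f"dec{lvl}_c2", ch, ch, k)
            c_prev = ch
        add_conv("final", c_prev, config.out_channels, 1)

    # -- forward / backward -------------------------------------------------

    def _check_spatial(self, x: np.ndarray) -> None:
        side = 2**self.config.depth
        if x.shape[2] % side or x.shape[3] % side:
            raise ValueError(
                f"input spatial dims {x.shape[2]}x{x.shape[3]} must be divisible "
                f"by 2**depth = {side}"
            )

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """Input (N, C, H, W) in [-1, 1] -> probabilities (N, out, H, W)."""
        self._check_spatial(x)
        p = self.params
        cache: dict = {}
        skips = []
        h = np.ascontiguousarray(x, dtype=np.float32)
        cache["x"] = h
        for lvl in range(self.config.depth):
            h, cache[f"enc{lvl}_c1"] = nn.conv2d(h, p[f"enc{lvl}_c1_w"], p[f"enc{lvl}_c1_b"])
            h, cache[f"enc{lvl}_r1"] = nn.relu(h)
            h, cache[f"enc{lvl}_c2"] = nn.conv2d(h, p[f"enc{lvl}_c2_w"], p[f"enc{lvl}_c2_b"])
            h, cache[f"enc{lvl}_r2"] = nn.relu(h)
            skips.append(h)
            h, cache[f"pool{lvl}"] = nn.maxpool2x2(h)
        h, cache["bott_c1"] = nn.conv2d(h, p["bott_c1_w"], p["bott_c1_b"])
        h, cache["bott_r1"] = nn.relu(h)
        h, cache["bott_c2"] = nn.conv2d(h, p["bott_c2_w"], p["bott_c2_b"])
        h, cache["bott_r2"] = nn.relu(h)
        for lvl in reversed(range(self.config.depth)):
            h, cache[f"up{lvl}"] = nn.conv_transpose2x2(h, p[f"up{lvl}_w"], p[f"up{lvl}_b"])
            h = np.concatenate([skips[lvl], h], axis=1)
            cache[f"cat{lvl}_split"] = skips[lvl].shape[1]
            h, cache[f"dec{lvl}_c1"] = nn.conv2d(h, p[f"dec{lvl}_c1_w"], p[f"dec{lvl}_c1_b"])
            h, cache[f"dec{lvl}_r1"] = nn.relu(h)
            h, cache[f"dec{lvl}_c2"] = nn.conv2d(h, p[f"dec{lvl}_c2_w"], p[f"dec{lvl}_c2_b"])
            h, cache[f"dec{lvl}_r2"] = nn.relu(h)
        logits, cache["final"] = nn.conv2d(h, p["final_w"], p["final_b"])
        probs = nn.sigmoid(logits)
        cache["probs"] = probs
        if want_cache:
            return probs, cache
        return probs

    def backward(self, dprobs: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        """Gradient w.r.t. all parameters, given dLoss/dProbs."""
        grads: dict[str, np.ndarray] = {}
        probs = cache["probs"]
        dlogits = dprobs * probs * (1.0 - probs)
        dh, grads["final_w"], grads["final_b"] = nn.conv2d_backward(dlogits, cache["final"])
        dskips: dict[int, np.ndarray] = {}
        for lvl in range(self.config.depth):
            dh = nn.relu_backward(dh, cache[f"dec{lvl}_r2"])
            dh, grads[f"dec{lvl}_c2_w"], grads[f"dec{lvl}_c2_b"] = nn.conv2d_backward(
                dh, cache[f"dec{lvl}_c2"]
            )
            dh = nn.relu_backward(dh, cache[f"dec{lvl}_r1"])
            dh, grads[f"dec{lvl}_c1_w"], grads[f"dec{lvl}_c1_b"] = nn.conv2d_backward(
                dh, cache[f"dec{lvl}_c1"]
            )
            split = cache[f"cat{lvl}_split"]
            dskips[lvl] = dh[:, :split]
            dup = np.ascontiguousarray(dh[:, split:])
            dh, grads[f"up{lvl}_w"], grads[f"up{lvl}_b"] = nn.conv_transpose2x2_backward(
                dup, cache[f"up{lvl}"]
            )
        dh = nn.relu_backward(dh, cache["bott_r2"])
        dh, grads["bott_c2_w"], grads["bott_c2_b"] = nn.conv2d_backward(dh, cache["bott_c2"])
        dh = nn.relu_backward(dh, cache["bott_r1"])
        dh, grads["bott_c1_w"], grads["bott_c1_b"] = nn.conv2d_backward(dh, cache["bott_c1"])
        for lvl in reversed(range(self.config.depth)):
            dh = nn.maxpool2x2_backward(dh, cache[f"pool{lvl}"])
            dh = dh + dskips[lvl]
            dh = nn.relu_backward(dh, cache[f"enc{lvl}_r2"])
            dh, grads[f"enc{lvl}_c2_w"], grads[f"enc{lvl}_c2_b"] = nn.conv2d_backward(
                dh, cache[f"enc{lvl}_c2"]
            )
            dh = nn.relu_backward(dh, cache[f"enc{lvl}_r1"])
            dh, grads[f"enc{lvl}_c1_w"], grads[f"enc{lvl}_c1_b"] = nn.conv2d_backward(
                dh, cache[f"enc{lvl}_c1"]
            )
        return grads

    # -- snapshots ----------------------------------------------------------

    def n_parameters(self) -> int:
        """Brute-force enumeration of learnable array sizes."""
        return int(sum(v.size for v in self.params.values()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = state[k].copy()

    def save(self, path) -> None:
        np.savez(path, **self.params)

    @classmethod
    def load(cls, path, config: UNetConfig) -> "UNet":
        model = cls(config, seed=0)
        with np.load(path) as data:
            model.load_state_dict({k: data[k] for k in data.files})
        return model
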