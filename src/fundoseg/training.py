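"""Training of structure-specific U-Nets with a soft-Dice objective.

``SegmentationModel`` is built from arrays of preprocessed pairs plus the
architecture/optimization configs; ``fit()`` runs seeded Adam epochs and
returns a :class:`TrainingResults` holding the best-validation-loss
parameter snapshot, the per-epoch history (train/validation loss and
Jaccard accuracy), and a ``summary()`` table.

The loss is soft Dice, 1 - (2*sum(p*t) + eps) / (sum(p) + sum(t) + eps)
with eps = 1e-6, computed per image and averaged over the batch; loss
curves are conventionally plotted on a log axis.  Defaults mirror the
reference protocol: Adam, learning rate 1e-4, batch size 4, 300 epochs
(smoke-scale profiles use far fewer).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nn import Adam
from .unet import UNet, UNetConfig

EPS = 1e-6

__all__ = [
    "TrainConfig",
    "TrainingResults",
    "SegmentationModel",
    "dice_loss",
    "dice_loss_grad",
    "predict_mask",
    "pairs_to_arrays",
]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 300
    batch_size: int = 4
    learning_rate: float = 1e-4
    seed: int = 0
    threshold: float = 0.5  # probability cut for binary prediction
    device: str = "cpu"  # cpu is the deterministic reference path

    def validate(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.device != "cpu":
            raise ValueError("only the cpu training path is implemented")


def dice_loss(probs: np.ndarray, truth: np.ndarray) -> float:
    """Soft Dice loss, averaged per image over the leading axis.

    ``probs`` in [0,1] and ``truth`` (binary) must have equal shapes; a
    leading batch axis is optional.
    """
    probs = np.asarray(probs, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if probs.shape != truth.shape:
        raise ValueError(f"shape mismatch: {probs.shape} vs {truth.shape}")
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    p = probs.reshape(probs.shape[0], -1) if probs.ndim > 2 else probs.reshape(1, -1)
    t = truth.reshape(p.shape)
    inter = (p * t).sum(axis=1)
    denom = p.sum(axis=1) + t.sum(axis=1)
    losses = 1.0 - (2.0 * inter + EPS) / (denom + EPS)
    return float(losses.mean())


def dice_loss_grad(probs: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """d(soft Dice loss)/d(probs), per-image averaged as in dice_loss."""
    shape = probs.shape
    n = shape[0]
    p = probs.reshape(n, -1).astype(np.float64)
    t = truth.reshape(n, -1).astype(np.float64)
    inter = (p * t).sum(axis=1, keepdims=True)
    denom = p.sum(axis=1, keepdims=True) + t.sum(axis=1, keepdims=True) + EPS
    num = 2.0 * inter + EPS
    # loss_i = 1 - num/denom; d/dp = -(2 t * denom - num) / denom^2
    grad = -(2.0 * t * denom - num) / (denom**2)
    return (grad / n).reshape(shape).astype(np.float32)


def _jaccard_batch(probs: np.ndarray, truth: np.ndarray, threshold: float) -> float:
    pred = probs >= threshold
    t = truth > 0.5
    inter = np.logical_and(pred, t).sum(axis=(1, 2, 3))
    union = np.logical_or(pred, t).sum(axis=(1, 2, 3))
    scores = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    return float(scores.mean())


def pairs_to_arrays(pairs) -> tuple[np.ndarray, np.ndarray]:
    """Stack SamplePairs (images already normalized to [-1,1]) into
    NCHW image and N1HW target arrays."""
    x = np.stack([np.moveaxis(np.asarray(p.image, dtype=np.float32), -1, 0) for p in pairs])
    y = np.stack([np.asarray(p.mask, dtype=np.float32)[None] for p in pairs])
    return x, y


class TrainingResults:
    """Fitted parameters plus training diagnostics.

    Attributes
    ----------
    model : UNet
        Network holding the best-validation-loss parameter snapshot.
    history : pandas.DataFrame
        Columns epoch, train_loss, val_loss, train_jaccard, val_jaccard.
    best_epoch : int
        Epoch (1-based) of the lowest validation loss.
    """

    def __init__(self, model: UNet, history: pd.DataFrame, best_epoch: int,
                 structure: str = ""):
        self.model = model
        self.history = history
        self.best_epoch = best_epoch
        self.structure = structure

    @property
    def best_val_loss(self) -> float:
        return float(self.history["val_loss"].min())

    def summary(self) -> str:
        h = self.history
        lines = [
            "Segmentation training results" + (f" ({self.structure})" if self.structure else ""),
            "=" * 46,
            f"epochs run          {len(h):>10d}",
            f"best epoch          {self.best_epoch:>10d}",
            f"best val Dice loss  {self.best_val_loss:>10.4f}",
            f"final train loss    {h['train_loss'].iloc[-1]:>10.4f}",
            f"final val Jaccard   {h['val_jaccard'].iloc[-1]:>10.4f}",
            f"trainable params    {self.model.n_parameters():>10d}",
        ]
        return "\n".join(lines)

    def save_history(self, path) -> None:
        self.history.to_csv(path, index=False)

    def predict(self, images: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        """Binary masks for a batch of normalized NCHW images."""
        return predict_mask(self.model, images, threshold=threshold)


class SegmentationModel:
    """One U-Net to be fitted for one structure (disc or cup)."""

    def __init__(self, train_x: np.ndarray, train_y: np.ndarray,
                 val_x: np.ndarray, val_y: np.ndarray,
                 unet_config: UNetConfig | None = None,
                 train_config: TrainConfig | None = None,
                 structure: str = ""):
        if len(train_x) == 0 or len(val_x) == 0:
            raise ValueError("training and validation sets must be non-empty")
        if train_x.shape[2:] != val_x.shape[2:]:
            raise ValueError("train and validation spatial sizes differ")
        self.train_x = np.asarray(train_x, dtype=np.float32)
        self.train_y = np.asarray(train_y, dtype=np.float32)
        self.val_x = np.asarray(val_x, dtype=np.float32)
        self.val_y = np.asarray(val_y, dtype=np.float32)
        self.unet_config = unet_config or UNetConfig()
        self.train_config = train_config or TrainConfig()
        self.structure = structure

    @classmethod
    def from_pairs(cls, train_pairs, val_pairs, **kwargs) -> "SegmentationModel":
        tx, ty = pairs_to_arrays(train_pairs)
        vx, vy = pairs_to_arrays(val_pairs)
        return cls(tx, ty, vx, vy, **kwargs)

    def _eval_loss(self, model: UNet, x: np.ndarray, y: np.ndarray,
                   batch: int) -> tuple[float, float]:
        losses, jacs, weights = [], [], []
        for i in range(0, len(x), batch):
            xb, yb = x[i : i + batch], y[i : i + batch]
            probs = model.forward(xb)
            losses.append(dice_loss(probs, yb))
            jacs.append(_jaccard_batch(probs, yb, self.train_config.threshold))
            weights.append(len(xb))
        w = np.asarray(weights, dtype=float)
        return float(np.average(losses, weights=w)), float(np.average(jacs, weights=w))

    def fit(self, verbose: bool = False, callback=None) -> TrainingResults:
        """Seeded Adam training; retains the best-validation snapshot."""
        cfg = self.train_config
        cfg.validate()
        model = UNet(self.unet_config, seed=cfg.seed)
        optimizer = Adam(model.params, lr=cfg.learning_rate)
        shuffle_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=cfg.seed, spawn_key=(17,))
        )
        records = []
        best_state = model.state_dict()
        best_val = np.inf
        best_epoch = 0
        n = len(self.train_x)
        for epoch in range(1, cfg.epochs + 1):
            order = shuffle_rng.permutation(n)
            epoch_losses, epoch_jacs, weights = [], [], []
            for i in range(0, n, cfg.batch_size):
                idx = order[i : i + cfg.batch_size]
                xb, yb = self.train_x[idx], self.train_y[idx]
                probs, cache = model.forward(xb, want_cache=True)
                loss = dice_loss(probs, yb)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}: {loss}"
                    )
                grads = model.backward(dice_loss_grad(probs, yb), cache)
                optimizer.step(grads)
                epoch_losses.append(loss)
                epoch_jacs.append(_jaccard_batch(probs, yb, cfg.threshold))
                weights.append(len(idx))
            w = np.asarray(weights, dtype=float)
            train_loss = float(np.average(epoch_losses, weights=w))
            train_jac = float(np.average(epoch_jacs, weights=w))
            val_loss, val_jac = self._eval_loss(model, self.val_x, self.val_y, cfg.batch_size)
            records.append(
                {
                    "epoch": epoch,
                    "train_loss": train_loss,
                    "val_loss": val_loss,
                    "train_jaccard": train_jac,
                    "val_jaccard": val_jac,
                }
            )
            if val_loss < best_val:
                best_val = val_loss
                best_state = model.state_dict()
                best_epoch = epoch
            if verbose:
                print(
                    f"[{self.structure or 'model'}] epoch {epoch:3d} "
                    f"train {train_loss:.4f}  val {val_loss:.4f}  "
                    f"jac {val_jac:.4f}"
                )
            if callback is not None:
                callback(epoch, records[-1])
        model.load_state_dict(best_state)
        history = pd.DataFrame.from_records(records)
        return TrainingResults(model, history, best_epoch, structure=self.structure)


def predict_mask(model: UNet, images: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binarize the network's foreground probability at ``threshold``.

    ``images`` is NCHW (or CHW for one image), normalized to [-1, 1] like
    the training inputs; returns boolean masks of shape (N, H, W).
    """
    arr = np.asarray(images, dtype=np.float32)
    single = arr.ndim == 3
    if single:
        arr = arr[None]
    if arr.min() < -1.001 or arr.max() > 1.001:
        raise ValueError("images must be normalized to [-1, 1] before prediction")
    probs = model.forward(arr)[:, 0]
    out = probs >= threshold
    return out[0] if single else out
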