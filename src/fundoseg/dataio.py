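"""Reading, writing and preprocessing of images and label masks.

Label masks follow the ORIGA/REFUGE combined convention: background is
black [0,0,0], the optic disc gray [128,128,128], and the optic cup white
[255,255,255].  A pixel counts as "object" when every channel is >= its
threshold channel (default [128,128,128]).  Splitting a combined mask
yields a disc mask (gray plus white — the white cup pixels are part of the
disc) and a cup mask (white only), so each structure can be segmented by
its own model.

Coordinates are (row, col), 0-based, top-left origin.  Images are resized
bilinearly; masks with nearest-neighbour so they stay binary.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

CANONICAL_COLORS = np.array([[0, 0, 0], [128, 128, 128], [255, 255, 255]], dtype=np.int16)
#: lossy-format tolerance: snap labels within this Chebyshev distance
LABEL_SNAP_TOLERANCE = 16

__all__ = [
    "AugmentConfig",
    "DatasetSplit",
    "SamplePair",
    "augment",
    "binarize",
    "clean_labels",
    "load_image",
    "load_mask",
    "normalize",
    "denormalize",
    "resize_image",
    "resize_mask",
    "resize_pair",
    "save_mask",
    "split_combined_mask",
    "split_dataset",
]


@dataclass
class SamplePair:
    """An image with the binary mask of one structure (cup or disc)."""

    image: np.ndarray  # float or uint8, H x W x 3
    mask: np.ndarray  # bool, H x W
    identifier: str = ""

    def __post_init__(self) -> None:
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError(
                f"image {self.image.shape[:2]} and mask {self.mask.shape} shapes differ"
            )


@dataclass(frozen=True)
class DatasetSplit:
    train: list[str]
    validation: list[str]
    test: list[str]
    seed: int
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "train": self.train,
                    "validation": self.validation,
                    "test": self.test,
                    "seed": self.seed,
                },
                fh,
                indent=1,
            )

    @classmethod
    def load(cls, path: str | Path) -> "DatasetSplit":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["train"], d["validation"], d["test"], d["seed"])


@dataclass(frozen=True)
class AugmentConfig:
    """Training-time augmentation: random crop (window side drawn from a
    normal distribution, clamped to [50%, 100%] of the image side, then
    resized back), Gaussian blur of the image only, and random flips.

    Crop-window mean/sd are fractions of the image side.  Defaults: mean
    0.8, sd 0.1 — mild framing jitter.
    """

    crop_mean: float = 0.8
    crop_sd: float = 0.1
    blur_sigma_max: float = 1.5
    p_flip_horizontal: float = 0.5
    p_flip_vertical: float = 0.5
    p_blur: float = 0.5
    p_crop: float = 0.5


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG as an 8-bit RGB array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.uint8)


def clean_labels(label_image: np.ndarray) -> np.ndarray:
    """Snap each pixel to the nearest canonical label color.

    Tolerates lossy-format artifacts up to Chebyshev distance
    ``LABEL_SNAP_TOLERANCE``; anything farther from all three canonical
    colors is an error naming the offending values.
    """
    _require_rgb(label_image)
    px = label_image.astype(np.int16)
    # distance to each canonical color: Chebyshev over channels
    dists = np.stack(
        [np.abs(px - c).max(axis=-1) for c in CANONICAL_COLORS], axis=-1
    )  # H x W x 3
    nearest = dists.argmin(axis=-1)
    mindist = dists.min(axis=-1)
    bad = mindist > LABEL_SNAP_TOLERANCE
    if bad.any():
        offending = np.unique(label_image[bad].reshape(-1, 3), axis=0)[:8]
        raise ValueError(
            "mask contains colors outside the background/disc/cup convention: "
            + ", ".join(str(list(c)) for c in offending)
        )
    return CANONICAL_COLORS[nearest].astype(np.uint8)


def load_mask(path: str | Path) -> np.ndarray:
    """Read a combined mask and clean it to the three canonical colors."""
    return clean_labels(load_image(path))


def save_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary or combined mask as 8-bit PNG."""
    if mask.dtype == bool:
        mask = (mask * np.uint8(255))
    Image.fromarray(np.asarray(mask, dtype=np.uint8)).save(path)


def _require_rgb(arr: np.ndarray) -> None:
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError(f"expected an H x W x 3 RGB array, got shape {arr.shape}")


def binarize(label_image: np.ndarray, threshold=(128, 128, 128)) -> np.ndarray:
    """Foreground iff every channel >= its threshold channel.

    This is the all-channel reading of the ">= [128,128,128]" object rule:
    a pixel like [200,100,200] stays background because one channel is
    below threshold.
    """
    _require_rgb(label_image)
    thr = np.asarray(threshold).reshape(1, 1, 3)
    return np.all(np.asarray(label_image) >= thr, axis=-1)


def split_combined_mask(combined: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a combined mask into (disc, cup) binary masks.

    Disc = gray-or-white pixels (the white cup region is recolored gray,
    i.e. counted as disc); cup = white pixels only.  Hence cup is always a
    subset of disc.
    """
    cleaned = clean_labels(np.asarray(combined))
    disc = binarize(cleaned)  # gray and white both pass the 128 threshold
    cup = binarize(cleaned, threshold=(255, 255, 255))
    return disc, cup


def resize_image(image: np.ndarray, size: int) -> np.ndarray:
    """Bilinear resize of an RGB image to ``size`` x ``size``."""
    if size < 8:
        raise ValueError("size must be >= 8")
    pil = Image.fromarray(np.asarray(image, dtype=np.uint8))
    return np.asarray(pil.resize((size, size), Image.BILINEAR), dtype=np.uint8)


def resize_mask(mask: np.ndarray, size: int) -> np.ndarray:
    """Nearest-neighbour resize of a binary mask (stays binary)."""
    if size < 8:
        raise ValueError("size must be >= 8")
    pil = Image.fromarray((np.asarray(mask, dtype=np.uint8)) * 255)
    out = np.asarray(pil.resize((size, size), Image.NEAREST))
    return out > 127


def resize_pair(pair: SamplePair, size: int) -> SamplePair:
    return SamplePair(
        image=resize_image(pair.image, size),
        mask=resize_mask(pair.mask, size),
        identifier=pair.identifier,
    )


def normalize(image: np.ndarray) -> np.ndarray:
    """Map 8-bit pixel values affinely onto [-1, 1]: x -> x/127.5 - 1."""
    arr = np.asarray(image, dtype=np.float32)
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("normalize expects pixel values in [0, 255]")
    return arr / 127.5 - 1.0


def denormalize(image: np.ndarray) -> np.ndarray:
    """Inverse of :func:`normalize`, back to [0, 255] floats."""
    return (np.asarray(image, dtype=np.float32) + 1.0) * 127.5


def _gaussian_blur_rgb(image: np.ndarray, sigma: float) -> np.ndarray:
    from scipy.ndimage import gaussian_filter

    out = np.empty_like(image, dtype=np.float32)
    for ch in range(3):
        out[..., ch] = gaussian_filter(image[..., ch].astype(np.float32), sigma)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def augment(pair: SamplePair, rng_seed: int, config: AugmentConfig | None = None) -> SamplePair:
    """Seeded training augmentation with paired geometry.

    Crops and flips are applied identically to image and mask; Gaussian
    blur touches only the image (blurring a binary mask would corrupt the
    ground truth).  A degenerate crop window (<= 8 px) is re-drawn up to
    10 times before falling back to no crop.
    """
    config = config or AugmentConfig()
    rng = np.random.default_rng(rng_seed)
    image = np.asarray(pair.image, dtype=np.uint8)
    mask = np.asarray(pair.mask, dtype=bool)
    side = image.shape[0]

    if rng.random() < config.p_crop:
        window = 0
        for _ in range(10):
            h = int(round(rng.normal(config.crop_mean, config.crop_sd) * side))
            w = int(round(rng.normal(config.crop_mean, config.crop_sd) * side))
            h = int(np.clip(h, side // 2, side))
            w = int(np.clip(w, side // 2, side))
            if h > 8 and w > 8:
                window = 1
                break
        if window:
            r0 = int(rng.integers(0, side - h + 1))
            c0 = int(rng.integers(0, side - w + 1))
            image = image[r0 : r0 + h, c0 : c0 + w]
            mask = mask[r0 : r0 + h, c0 : c0 + w]
            # resize back so batch shapes stay fixed
            pil = Image.fromarray(image)
            image = np.asarray(pil.resize((side, side), Image.BILINEAR), dtype=np.uint8)
            mpil = Image.fromarray(mask.astype(np.uint8) * 255)
            mask = np.asarray(mpil.resize((side, side), Image.NEAREST)) > 127

    if rng.random() < config.p_flip_horizontal:
        image = image[:, ::-1]
        mask = mask[:, ::-1]
    if rng.random() < config.p_flip_vertical:
        image = image[::-1, :]
        mask = mask[::-1, :]

    if rng.random() < config.p_blur:
        sigma = rng.uniform(0.3, config.blur_sigma_max)
        image = _gaussian_blur_rgb(np.ascontiguousarray(image), sigma)

    return SamplePair(
        image=np.ascontiguousarray(image),
        mask=np.ascontiguousarray(mask),
        identifier=pair.identifier,
    )


def split_dataset(
    identifiers: list[str],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> DatasetSplit:
    """Seeded shuffle then 80-10-10 partition (floor allocation for
    validation/test, remainder to train)."""
    n = len(identifiers)
    if n < 3:
        raise ValueError("need at least 3 identifiers to populate train/validation/test")
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    order = list(np.array(identifiers, dtype=object)[rng.permutation(n)])
    n_val = max(1, int(np.floor(fractions[1] * n)))
    n_test = max(1, int(np.floor(fractions[2] * n)))
    n_train = n - n_val - n_test
    if n_train < 1:
        raise ValueError("split leaves no training items")
    return DatasetSplit(
        train=[str(x) for x in order[:n_train]],
        validation=[str(x) for x in order[n_train : n_train + n_val]],
        test=[str(x) for x in order[n_train + n_val :]],
        seed=seed,
        fractions=fractions,
    )


def foreground_fraction_warning(mask: np.ndarray, identifier: str = "") -> None:
    """Realistic scenes have minority foreground; warn (not error) otherwise."""
    frac = float(np.mean(mask))
    if frac >= 0.5:
        warnings.warn(
            f"mask {identifier or '<unnamed>'} has foreground fraction {frac:.2f} >= 0.5",
            stacklevel=2,
        )
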