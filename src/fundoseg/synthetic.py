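"""Synthetic fundus-like scenes with exact ground-truth masks.

Real fundus photographs show a bright, roughly elliptical optic disc
containing a brighter central cup, on an orange retinal background crossed
by dark vessels.  This module renders that structure geometrically so that
every downstream stage (mask splitting, segmentation training, boundary
visualization, cup-to-disc-ratio measurement) can be exercised against an
exactly known ground truth: the combined label mask is rasterized from the
same ellipses as the image, noise-free, using the background/disc/cup
convention black [0,0,0] / gray [128,128,128] / white [255,255,255].

Randomness is counter-based: scene ``i`` of a dataset depends only on the
dataset seed and ``i``, never on how many scenes are generated.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image

BACKGROUND_RGB = (0, 0, 0)
DISC_RGB = (128, 128, 128)
CUP_RGB = (255, 255, 255)

__all__ = [
    "SceneParams",
    "SyntheticScene",
    "generate_scene",
    "generate_dataset",
    "sample_params",
]


@dataclass(frozen=True)
class SceneParams:
    """Geometry and photometry of one synthetic scene.

    ``disc_center`` is in (row, col) fractions of the image side;
    ``disc_radii`` are (vertical, horizontal) pixel radii.  The cup is a
    concentric ellipse whose vertical radius is ``cdr_true`` times the
    disc's vertical radius (horizontal radius scaled by the same factor).
    """

    image_size: int = 256
    disc_center: tuple[float, float] = (0.5, 0.5)
    disc_radii: tuple[float, float] = (48.0, 40.0)
    cdr_true: float = 0.5
    vessel_count: int = 4
    noise_sd: float = 5.0
    background_rgb: tuple[int, int, int] = (180, 90, 30)
    disc_rgb: tuple[int, int, int] = (225, 170, 90)
    cup_rgb: tuple[int, int, int] = (250, 230, 160)

    def validate(self) -> None:
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        if not (0.1 <= self.cdr_true <= 0.95):
            raise ValueError(f"cdr_true must lie in [0.1, 0.95], got {self.cdr_true}")
        rv, rh = self.disc_radii
        if rv <= 0 or rh <= 0:
            raise ValueError("disc radii must be positive")
        cr, cc = (f * self.image_size for f in self.disc_center)
        if not (rv < cr < self.image_size - rv and rh < cc < self.image_size - rh):
            raise ValueError("disc ellipse must lie strictly inside the image")
        # cup = cdr_true * disc is concentric and cdr_true < 1, so containment
        # is automatic; brightness ordering is a modelling invariant.
        for a, b in ((self.cup_rgb, self.disc_rgb), (self.disc_rgb, self.background_rgb)):
            if not float(np.mean(a)) > float(np.mean(b)):
                raise ValueError("required brightness ordering: cup > disc > background")
        if self.vessel_count < 0:
            raise ValueError("vessel_count must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SyntheticScene:
    """A rendered image, its combined label mask, and the true CDR."""

    image: np.ndarray  # uint8, H x W x 3
    combined_mask: np.ndarray  # uint8, H x W x 3, values in {0, 128, 255}
    cdr_true: float
    disc_v_diameter: int = 0
    cup_v_diameter: int = 0


def _ellipse_raster(size: int, center: tuple[float, float], radii: tuple[float, float]) -> np.ndarray:
    rr, cc = np.mgrid[0:size, 0:size]
    cr, ccol = center
    rv, rh = radii
    return ((rr - cr) / rv) ** 2 + ((cc - ccol) / rh) ** 2 <= 1.0


def _vertical_extent(mask: np.ndarray) -> int:
    rows = np.flatnonzero(mask.any(axis=1))
    if rows.size == 0:
        return 0
    return int(rows[-1] - rows[0] + 1)


def _rng_for(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def generate_scene(params: SceneParams, seed: int) -> SyntheticScene:
    """Render one scene deterministically from ``(params, seed)``.

    The combined mask is rasterized from the exact disc and cup ellipses;
    vessels and noise perturb the image only, never the mask.
    """
    params.validate()
    size = params.image_size
    center = tuple(f * size for f in params.disc_center)
    disc = _ellipse_raster(size, center, params.disc_radii)
    cup_radii = (params.cdr_true * params.disc_radii[0], params.cdr_true * params.disc_radii[1])
    cup = _ellipse_raster(size, center, cup_radii)

    image = np.empty((size, size, 3), dtype=np.float64)
    image[:] = params.background_rgb
    image[disc] = params.disc_rgb
    image[cup] = params.cup_rgb

    rng = _rng_for(seed, 0)
    for _ in range(params.vessel_count):
        _draw_vessel(image, rng, center, params.disc_radii)

    if params.noise_sd > 0:
        noise_rng = _rng_for(seed, 1)
        image += noise_rng.normal(0.0, params.noise_sd, size=image.shape)

    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)

    mask = np.zeros((size, size, 3), dtype=np.uint8)
    mask[disc] = DISC_RGB
    mask[cup] = CUP_RGB

    return SyntheticScene(
        image=image,
        combined_mask=mask,
        cdr_true=params.cdr_true,
        disc_v_diameter=_vertical_extent(disc),
        cup_v_diameter=_vertical_extent(cup),
    )


def _draw_vessel(image: np.ndarray, rng: np.random.Generator, center, disc_radii) -> None:
    """Dark random-walk polyline starting near the disc, the dominant
    realistic nuisance occluding cup/disc edges."""
    size = image.shape[0]
    pos = np.array(
        [
            center[0] + rng.normal(0, disc_radii[0] / 2),
            center[1] + rng.normal(0, disc_radii[1] / 2),
        ]
    )
    heading = rng.uniform(0, 2 * np.pi)
    darkness = rng.uniform(0.45, 0.7)
    half_w = rng.integers(1, 3)
    n_steps = int(size * 1.2)
    for _ in range(n_steps):
        heading += rng.normal(0, 0.25)
        pos += np.array([np.sin(heading), np.cos(heading)])
        r, c = int(round(pos[0])), int(round(pos[1]))
        if not (0 <= r < size and 0 <= c < size):
            break
        r0, r1 = max(0, r - half_w), min(size, r + half_w + 1)
        c0, c1 = max(0, c - half_w), min(size, c + half_w + 1)
        image[r0:r1, c0:c1] *= darkness


def sample_params(rng: np.random.Generator, base: SceneParams | None = None,
                  cdr_range: tuple[float, float] = (0.3, 0.9)) -> SceneParams:
    """Draw per-scene parameters around a base configuration.

    Disc position and radii jitter mimics camera framing variation; the
    true CDR is uniform on ``cdr_range``.
    """
    base = base or SceneParams()
    size = base.image_size
    rv = rng.uniform(0.8, 1.2) * base.disc_radii[0]
    rh = rng.uniform(0.8, 1.2) * base.disc_radii[1]
    margin_r = (rv + 2) / size
    margin_c = (rh + 2) / size
    center = (
        rng.uniform(margin_r + 0.05, 1 - margin_r - 0.05),
        rng.uniform(margin_c + 0.05, 1 - margin_c - 0.05),
    )
    return replace(
        base,
        disc_center=center,
        disc_radii=(rv, rh),
        cdr_true=float(rng.uniform(*cdr_range)),
    )


def generate_dataset(
    n: int,
    out_dir: str | Path,
    seed: int,
    base_params: SceneParams | None = None,
    cdr_range: tuple[float, float] = (0.3, 0.9),
    force: bool = False,
) -> "list[dict]":
    """Write ``n`` image/mask pairs plus a manifest CSV.

    Layout: ``<out_dir>/images/scene_%04d.png``, ``<out_dir>/masks/scene_%04d.png``
    and ``<out_dir>/manifest.csv`` with columns
    scene_id, seed, cdr_true, disc_v_diam_px, cup_v_diam_px.
    Refuses to write into a non-empty directory unless ``force``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"output directory {out} is not empty (pass force=True to overwrite)")
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)

    rows = []
    for i in range(n):
        param_rng = _rng_for(seed, 2, i)
        params = sample_params(param_rng, base_params, cdr_range)
        scene_seed = int(_rng_for(seed, 3, i).integers(0, 2**31 - 1))
        scene = generate_scene(params, scene_seed)
        sid = f"scene_{i:04d}"
        Image.fromarray(scene.image).save(out / "images" / f"{sid}.png")
        Image.fromarray(scene.combined_mask).save(out / "masks" / f"{sid}.png")
        rows.append(
            {
                "scene_id": sid,
                "seed": scene_seed,
                "cdr_true": f"{scene.cdr_true:.6f}",
                "disc_v_diam_px": scene.disc_v_diameter,
                "cup_v_diam_px": scene.cup_v_diameter,
            }
        )

    with open(out / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
    return rows
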