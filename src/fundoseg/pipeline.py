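"""End-to-end orchestration: synth -> split -> train -> evaluate -> CDR.

Everything is driven by one pipeline seed that fans out to fixed-purpose
sub-seeds (dataset generation, dataset split, augmentation, disc model,
cup model), so a pipeline run is reproducible end to end on one CPU and
two runs with the same seed produce byte-identical CSV outputs.

The smoke profile trains a depth-2/base-8 U-Net on 64x64 synthetic
scenes — small enough for CPU minutes, structured enough that disc and
cup remain separable segmentation targets.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import dataio
from .cdr import compute_cdr
from .metrics import MetricsReport, evaluate
from .synthetic import SceneParams, generate_dataset
from .training import SegmentationModel, TrainConfig, TrainingResults, predict_mask
from .unet import UNet, UNetConfig

__all__ = ["PipelineConfig", "PipelineOutputs", "run_pipeline", "load_dataset_dir",
           "build_structure_arrays", "SMOKE_SCENE_PARAMS"]

#: 64x64 scene profile for CPU-scale training
SMOKE_SCENE_PARAMS = SceneParams(image_size=64, disc_radii=(13.0, 11.0),
                                 vessel_count=3, noise_sd=5.0)

# sub-seed purposes (spawn keys off the pipeline seed)
_K_DATASET, _K_SPLIT, _K_AUGMENT, _K_DISC, _K_CUP = 101, 102, 103, 104, 105


def _subseed(seed: int, key: int) -> int:
    return int(np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(key,))
    ).integers(0, 2**31 - 1))


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    n_scenes: int = 120
    scene_params: SceneParams = field(default_factory=lambda: SMOKE_SCENE_PARAMS)
    cdr_range: tuple[float, float] = (0.3, 0.9)
    unet: UNetConfig = field(default_factory=lambda: UNetConfig(depth=2, base_channels=8))
    epochs: int = 100
    #: the disc converges much faster than the cup; a shorter disc budget
    #: keeps the full smoke run in CPU minutes (None = same as epochs)
    disc_epochs: int | None = 50
    batch_size: int = 4
    learning_rate: float = 1e-4
    augment_copies: int = 2  # augmented duplicates per training pair
    threshold: float = 0.5
    cdr_method: str = "vertical"


@dataclass
class PipelineOutputs:
    split: dataio.DatasetSplit
    disc_results: TrainingResults
    cup_results: TrainingResults
    disc_report: MetricsReport
    cup_report: MetricsReport
    cdr_table: pd.DataFrame  # image_id, cdr_pred, cdr_truth_mask, cdr_true, stage, ...
    out_root: Path


def load_dataset_dir(root: str | Path):
    """Read a generated dataset directory back into memory.

    Returns (ids, images, combined_masks, manifest) where images and
    masks are dicts keyed by scene id.
    """
    root = Path(root)
    manifest = pd.read_csv(root / "manifest.csv")
    ids = list(manifest["scene_id"])
    images = {i: dataio.load_image(root / "images" / f"{i}.png") for i in ids}
    masks = {i: dataio.load_mask(root / "masks" / f"{i}.png") for i in ids}
    return ids, images, masks, manifest


def build_structure_arrays(ids, images, masks, structure: str,
                           augment_copies: int = 0, augment_seed: int = 0):
    """Normalized NCHW inputs and binary targets for one structure.

    ``structure`` selects the disc or cup half of each combined mask.
    ``augment_copies`` > 0 appends seeded augmented duplicates (train
    split only).
    """
    if structure not in ("disc", "cup"):
        raise ValueError("structure must be 'disc' or 'cup'")
    pairs = []
    for i in ids:
        disc, cup = dataio.split_combined_mask(masks[i])
        mask = disc if structure == "disc" else cup
        pairs.append(dataio.SamplePair(image=images[i], mask=mask, identifier=i))
    augmented = []
    for copy in range(augment_copies):
        for j, p in enumerate(pairs):
            augmented.append(dataio.augment(p, rng_seed=augment_seed + 7919 * copy + j))
    pairs = pairs + augmented
    x = np.stack([np.moveaxis(dataio.normalize(p.image), -1, 0) for p in pairs])
    y = np.stack([np.asarray(p.mask, dtype=np.float32)[None] for p in pairs])
    return x, y


def _train_structure(structure: str, split, ids, images, masks,
                     config: PipelineConfig, verbose: bool) -> TrainingResults:
    seed = _subseed(config.seed, _K_DISC if structure == "disc" else _K_CUP)
    epochs = config.epochs
    if structure == "disc" and config.disc_epochs is not None:
        epochs = config.disc_epochs
    tx, ty = build_structure_arrays(
        split.train, images, masks, structure,
        augment_copies=config.augment_copies,
        augment_seed=_subseed(config.seed, _K_AUGMENT),
    )
    vx, vy = build_structure_arrays(split.validation, images, masks, structure)
    model = SegmentationModel(
        tx, ty, vx, vy,
        unet_config=config.unet,
        train_config=TrainConfig(
            epochs=epochs, batch_size=config.batch_size,
            learning_rate=config.learning_rate, seed=seed,
            threshold=config.threshold,
        ),
        structure=structure,
    )
    return model.fit(verbose=verbose)


def run_pipeline(out_root: str | Path, config: PipelineConfig | None = None,
                 data_root: str | Path | None = None, verbose: bool = False,
                 force: bool = False) -> PipelineOutputs:
    """Full seeded pipeline; writes metrics.csv, cdr.csv, history CSVs.

    If ``data_root`` is None a synthetic dataset is generated under
    ``out_root/data`` first.
    """
    config = config or PipelineConfig()
    out_root = Path(out_root)
    out_root.mkdir(parents=True, exist_ok=True)

    if data_root is None:
        data_root = out_root / "data"
        generate_dataset(
            config.n_scenes, data_root, seed=_subseed(config.seed, _K_DATASET),
            base_params=config.scene_params, cdr_range=config.cdr_range, force=force,
        )
    ids, images, masks, manifest = load_dataset_dir(data_root)

    split = dataio.split_dataset(ids, seed=_subseed(config.seed, _K_SPLIT))
    split.save(out_root / "split.json")

    disc_results = _train_structure("disc", split, ids, images, masks, config, verbose)
    cup_results = _train_structure("cup", split, ids, images, masks, config, verbose)
    for res, name in ((disc_results, "disc"), (cup_results, "cup")):
        sub = out_root / name
        sub.mkdir(exist_ok=True)
        res.save_history(sub / "history.csv")
        res.model.save(sub / "checkpoint.npz")
        with open(sub / "config.json", "w") as fh:
            json.dump(
                {"unet": asdict(config.unet),
                 "train": {"epochs": len(res.history),
                           "batch_size": config.batch_size,
                           "learning_rate": config.learning_rate,
                           "threshold": config.threshold}},
                fh, indent=1)

    # evaluation on the held-out test split
    test_x_disc, test_y_disc = build_structure_arrays(split.test, images, masks, "disc")
    test_x_cup, test_y_cup = build_structure_arrays(split.test, images, masks, "cup")
    disc_pred = predict_mask(disc_results.model, test_x_disc, threshold=config.threshold)
    cup_pred = predict_mask(cup_results.model, test_x_cup, threshold=config.threshold)
    disc_report = evaluate(
        [(p, t[0] > 0.5) for p, t in zip(disc_pred, test_y_disc)],
        structure="disc", image_ids=split.test,
    )
    cup_report = evaluate(
        [(p, t[0] > 0.5) for p, t in zip(cup_pred, test_y_cup)],
        structure="cup", image_ids=split.test,
    )
    metrics_path = out_root / "metrics.csv"
    combined = pd.concat(
        [_report_frame(disc_report), _report_frame(cup_report)], ignore_index=True
    )
    combined.to_csv(metrics_path, index=False, float_format="%.6f")

    # CDR from predicted masks vs ground-truth masks vs generator truth
    truth_cdr = dict(zip(manifest["scene_id"], manifest["cdr_true"]))
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # predicted cup may poke outside predicted disc
        for j, image_id in enumerate(split.test):
            pred = compute_cdr(cup_pred[j], disc_pred[j], method=config.cdr_method)
            disc_t, cup_t = dataio.split_combined_mask(masks[image_id])
            truth = compute_cdr(cup_t, disc_t, method=config.cdr_method)
            rows.append(
                {
                    "image_id": image_id,
                    "cdr_pred": pred.cdr,
                    "stage_pred": pred.stage,
                    "cdr_truth_mask": truth.cdr,
                    "cdr_true": float(truth_cdr[image_id]),
                    "disc_v_diam_px": truth.disc_v_diameter,
                }
            )
    cdr_table = pd.DataFrame.from_records(rows)
    cdr_table.to_csv(out_root / "cdr.csv", index=False, float_format="%.6f")

    return PipelineOutputs(
        split=split, disc_results=disc_results, cup_results=cup_results,
        disc_report=disc_report, cup_report=cup_report,
        cdr_table=cdr_table, out_root=out_root,
    )


def _report_frame(report: MetricsReport) -> pd.DataFrame:
    table = report.per_image.copy()
    table.insert(1, "structure", report.structure)
    mean_row = pd.DataFrame(
        [{"image_id": "MEAN", "structure": report.structure,
          "dice": report.mean_dice, "jaccard": report.mean_jaccard}]
    )
    return pd.concat([table, mean_row], ignore_index=True)
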