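"""Seeded training loop, checkpointing, evaluation and ablation runner.

Training minimizes the compound cross-entropy/log-Dice loss with
momentum SGD.  Evaluation follows the detection pipeline: probability
map -> binarize -> connected components -> boxes -> greedy matching to
ground-truth components, with pixel Dice aggregated over the whole set.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io_preprocess, postprocess
from .network import ModelConfig, CompositeResUNet, build_model
from .nn import SGD, Tensor, no_grad
from .objective_metrics import (LossConfig, MetricsReport, aggregate_pixel_dice,
                                compound_loss, detection_metrics)


@dataclasses.dataclass
class TrainConfig:
    epochs: int = 25
    batch_size: int = 16
    learning_rate: float = 0.01   # not stated by the reference protocol
    momentum: float = 0.9
    weight_decay: float = 0.0005
    loss: LossConfig = dataclasses.field(default_factory=LossConfig)
    model: ModelConfig = dataclasses.field(default_factory=ModelConfig)
    seed: int = 0
    device: str = "cpu"
    train_manifest: str | None = None
    val_fraction: float = 0.1
    threshold: float = 0.5

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if isinstance(self.loss, dict):
            self.loss = LossConfig(**self.loss)
        if isinstance(self.model, dict):
            self.model = ModelConfig(**self.model)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclasses.dataclass
class TrainResult:
    model: CompositeResUNet
    best_state: dict
    best_epoch: int
    best_val_dice: float
    history: pd.DataFrame


def split_by_volume(samples, val_fraction: float, seed: int = 0):
    """Hold out ~val_fraction of the *volumes* (not slices) for validation."""
    volumes = sorted({s.volume_id for s in samples})
    n_val = max(1, int(round(len(volumes) * val_fraction))) if val_fraction > 0 \
        else 0
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(volumes))
    val_volumes = set(order[:n_val])
    train = [s for s in samples if s.volume_id not in val_volumes]
    val = [s for s in samples if s.volume_id in val_volumes]
    if not train:
        train, val = val, []
    return train, val


def _stack(samples, idx):
    images = np.stack([samples[i].image for i in idx])[:, None]
    masks = np.stack([samples[i].mask for i in idx])[:, None]
    return images.astype(np.float32), masks.astype(np.float32)


def train(config: TrainConfig, samples=None, log=None) -> TrainResult:
    """Train a model on SliceSamples (or on config.train_manifest).

    Saves nothing by itself; see save_checkpoint.  Fully deterministic for
    a fixed config and sample list.
    """
    if samples is None:
        if config.train_manifest is None:
            raise ValueError("either samples or config.train_manifest required")
        samples = io_preprocess.read_manifest(config.train_manifest)
    if not samples:
        raise ValueError("empty training set")

    train_set, val_set = split_by_volume(samples, config.val_fraction,
                                         config.seed)
    if not val_set:
        val_set = train_set

    rng = np.random.default_rng(config.seed)
    model = build_model(config.model, seed=config.seed)
    optimizer = SGD(model.parameters(), lr=config.learning_rate,
                    momentum=config.momentum,
                    weight_decay=config.weight_decay)

    best_state, best_epoch, best_val = None, -1, -1.0
    rows = []
    for epoch in range(config.epochs):
        model.train()
        order = rng.permutation(len(train_set))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            images, masks = _stack(train_set, idx)
            pred = model(Tensor(images))
            loss = compound_loss(pred, masks, config.loss)
            value = loss.item()
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite loss {value} at epoch {epoch}, step "
                    f"{start // config.batch_size}")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(value)

        report, _ = evaluate_model(model, val_set, threshold=config.threshold)
        row = {"epoch": epoch, "train_loss": float(np.mean(losses)),
               "val_dice": report.dice, "val_precision": report.precision,
               "val_recall": report.recall, "val_f1": report.f1}
        rows.append(row)
        if log is not None:
            log(f"epoch {epoch:3d}  loss {row['train_loss']:.4f}  "
                f"val_dice {row['val_dice']:.4f}  val_f1 {row['val_f1']:.4f}")
        if report.dice > best_val:
            best_val, best_epoch = report.dice, epoch
            best_state = model.state_dict()

    model.load_state_dict(best_state)
    return TrainResult(model=model, best_state=best_state,
                       best_epoch=best_epoch, best_val_dice=best_val,
                       history=pd.DataFrame(rows))


def evaluate_model(model: CompositeResUNet, samples, threshold: float = 0.5,
                   connectivity: int = 8, min_area: int = 0,
                   min_overlap: float | None = None,
                   merge_gap: float | None = None):
    """Full detection evaluation.

    Returns (MetricsReport, per_image DataFrame).  Lesion-level TP/FP/FN
    are summed across images; Dice is the aggregate pixel Dice of the whole
    set.  The per-image table also carries image-level flags (has_truth,
    has_pred) so image-level false positives can be derived separately.
    """
    model.eval()
    tp = fp = fn = 0
    preds, truths, rows = [], [], []
    for s in samples:
        prob = model.predict(s.image)
        pred_mask = postprocess.binarize(prob, threshold)
        boxes = postprocess.mask_to_boxes(pred_mask, connectivity, min_area)
        if merge_gap is not None:
            boxes = postprocess.merge_boxes(boxes, merge_gap)
        t, f, n = postprocess.match_to_truth(boxes, s.mask, min_overlap,
                                             connectivity)
        tp, fp, fn = tp + t, fp + f, fn + n
        preds.append(pred_mask)
        truths.append(s.mask)
        rows.append({"volume_id": s.volume_id, "slice_index": s.slice_index,
                     "tp": t, "fp": f, "fn": n,
                     "has_truth": bool(s.mask.any()),
                     "has_pred": bool(pred_mask.any())})
    dice = aggregate_pixel_dice(preds, truths)
    report = detection_metrics(tp, fp, fn, dice=dice)
    return report, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(path, model: CompositeResUNet,
                    train_config: TrainConfig | None = None) -> None:
    """Native .npz checkpoint with the ModelConfig embedded as JSON."""
    payload = {f"param/{k}": v for k, v in model.state_dict().items()}
    payload["__model_config__"] = np.array(model.config.to_json())
    if train_config is not None:
        payload["__train_config__"] = np.array(json.dumps(
            train_config.to_dict()))
    np.savez(path, **payload)


def load_checkpoint(path) -> CompositeResUNet:
    with np.load(path, allow_pickle=False) as data:
        config = ModelConfig.from_json(str(data["__model_config__"]))
        state = {k[len("param/"):]: data[k] for k in data.files
                 if k.startswith("param/")}
    model = build_model(config)
    model.load_state_dict(state)
    return model


# ---------------------------------------------------------------------------
# ablations


ABLATION_GRID = (
    ("baseline", False, False),
    ("hddc", True, False),
    ("cam", False, True),
    ("full", True, True),
)


def run_ablation(config: TrainConfig, samples, grid=ABLATION_GRID,
                 thetas=None, seeds=(0,), log=None) -> pd.DataFrame:
    """Train every (variant, theta, seed) cell on shared data.

    Returns a table with one row per cell: Recall / F1 / Precision / Dice
    on the shared validation split, plus the parameter count.
    """
    rows = []
    theta_list = [config.loss.theta] if thetas is None else list(thetas)
    for name, use_hddc, use_cam in grid:
        for theta in theta_list:
            for seed in seeds:
                cell = dataclasses.replace(
                    config,
                    seed=seed,
                    loss=dataclasses.replace(config.loss, theta=theta),
                    model=dataclasses.replace(config.model, use_hddc=use_hddc,
                                              use_cam=use_cam),
                )
                if log is not None:
                    log(f"ablation cell: {name} theta={theta} seed={seed}")
                result = train(cell, samples=samples, log=log)
                _, val_set = split_by_volume(samples, cell.val_fraction,
                                             cell.seed)
                report, _ = evaluate_model(result.model, val_set or samples,
                                           threshold=cell.threshold)
                rows.append({
                    "variant": name, "use_hddc": use_hddc, "use_cam": use_cam,
                    "theta": theta, "seed": seed,
                    "recall": report.recall, "f1": report.f1,
                    "precision": report.precision, "dice": report.dice,
                    "n_params": result.model.n_parameters(),
                })
    return pd.DataFrame(rows)
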