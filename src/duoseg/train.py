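"""Training, evaluation, prediction, and checkpointing.

The recipe: Adam (beta1 = 0.9) on the compound 0.5*BCE + Dice loss, with a
cosine learning-rate schedule annealing from ``lr`` at the first epoch to
exactly ``min_lr`` at the last.  Per-epoch training loss and validation Dice
are logged to CSV and the checkpoint with the best validation Dice is
retained.  All randomness (weight init, shuffling) derives from the config
seed, so a CPU run is bitwise reproducible.

Checkpoints are NumPy ``.npz`` archives holding every parameter/buffer plus
the YAML model config, so a model can be rebuilt from the file alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.transform import resize

from . import nn
from .config import ModelConfig, TrainConfig
from .errors import ConfigError
from .losses import combined_loss
from .metrics import evaluate_masks
from .model import SegmentationModel, build_model
from .nn import Tensor

__all__ = [
    "load_manifest",
    "load_pair",
    "train",
    "TrainResult",
    "save_checkpoint",
    "load_checkpoint",
    "evaluate",
    "predict",
]

logger = logging.getLogger(__name__)


# ------------------------------------------------------------------- data IO
def _to_gray01(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 3:  # collapse RGB(A)
        arr = arr[..., :3].mean(axis=-1)
    if arr.max() > 1.0:
        arr = arr / 255.0
    return arr


def load_pair(image_path, mask_path, input_size: int):
    """Load an (image, mask) pair, resizing to input_size if needed."""
    image = _to_gray01(iio.imread(image_path))
    mask = np.asarray(iio.imread(mask_path))
    if mask.ndim == 3:
        mask = mask[..., 0]
    mask = (mask > 127).astype(np.float64) if mask.max() > 1 else (mask > 0).astype(np.float64)
    if image.shape != (input_size, input_size):
        image = resize(image, (input_size, input_size), order=1, anti_aliasing=True)
        mask = resize(mask, (input_size, input_size), order=0, anti_aliasing=False)
        mask = (mask > 0.5).astype(np.float64)
    return image, mask


def load_manifest(manifest_path, split: str | None, input_size: int):
    """Load all (image, mask) pairs for one split of a CSV manifest."""
    df = pd.read_csv(manifest_path)
    if split is not None:
        df = df[df["split"] == split]
    if df.empty:
        raise ConfigError(f"manifest split {split!r} is empty: {manifest_path}")
    missing = [p for p in list(df["image_path"]) + list(df["mask_path"]) if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"missing files: {missing}")
    images, masks = [], []
    for _, row in df.iterrows():
        image, mask = load_pair(row["image_path"], row["mask_path"], input_size)
        images.append(image)
        masks.append(mask)
    return np.stack(images)[:, None], np.stack(masks)[:, None]


# --------------------------------------------------------------- checkpoints
def save_checkpoint(model: SegmentationModel, path) -> None:
    state = model.state_dict()
    state["__config__"] = np.frombuffer(model.cfg.to_yaml().encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path) -> SegmentationModel:
    archive = np.load(path)
    cfg = ModelConfig.from_yaml(bytes(archive["__config__"]).decode())
    model = build_model(cfg, seed=0)
    model.load_state_dict({k: archive[k] for k in archive.files if k != "__config__"})
    return model.eval()


# ------------------------------------------------------------------ training
@dataclass
class TrainResult:
    history: pd.DataFrame
    checkpoint_path: Path
    best_val_dice: float


def _mean_dice(model: SegmentationModel, images: np.ndarray, masks: np.ndarray, batch: int = 8) -> float:
    model.eval()
    scores = []
    with nn.no_grad():
        for i in range(0, len(images), batch):
            pred = model.predict_mask(Tensor(images[i : i + batch]))
            for p, g in zip(pred, masks[i : i + batch]):
                from .metrics import confusion, dice as dice_metric

                scores.append(dice_metric(confusion(p[0], g[0].astype(np.uint8))))
    return float(np.mean(scores))


def train(
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    manifest_path,
    out_dir,
    max_steps: int | None = None,
    val_split: str = "val",
    stop_at_val_dice: float | None = None,
) -> TrainResult:
    """Train a model on the train split of a manifest; keep the best-val checkpoint."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    images, masks = load_manifest(manifest_path, "train", train_cfg.input_size)
    try:
        val_images, val_masks = load_manifest(manifest_path, val_split, train_cfg.input_size)
    except ConfigError:
        logger.info("no %s split; validating on the training split", val_split)
        val_images, val_masks = images, masks

    model = build_model(model_cfg, seed=train_cfg.seed)
    opt = nn.Adam(model.parameters(), lr=train_cfg.lr)
    shuffle_rng = np.random.default_rng(train_cfg.seed + 1)

    ckpt_path = out / "best.npz"
    history_rows = []
    best_val = -1.0
    steps_done = 0
    n = len(images)
    for epoch in range(train_cfg.epochs):
        opt.lr = nn.cosine_lr(epoch, train_cfg.epochs, train_cfg.lr, train_cfg.min_lr)
        model.train()
        order = shuffle_rng.permutation(n)
        losses = []
        for start in range(0, n, train_cfg.batch_size):
            idx = order[start : start + train_cfg.batch_size]
            xb = Tensor(images[idx])
            yb = masks[idx]
            if train_cfg.augment:
                flips = shuffle_rng.random(len(idx)) < 0.5
                xb = Tensor(np.where(flips[:, None, None, None], xb.data[..., ::-1], xb.data))
                yb = np.where(flips[:, None, None, None], yb[..., ::-1], yb)
            prob = model(xb)
            loss = combined_loss(prob, yb)
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite loss {loss.item()} at epoch {epoch}, step {steps_done}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
            steps_done += 1
            if max_steps is not None and steps_done >= max_steps:
                break
        val_dice = _mean_dice(model, val_images, val_masks)
        history_rows.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_dice": val_dice, "lr": opt.lr}
        )
        if val_dice > best_val:
            best_val = val_dice
            save_checkpoint(model, ckpt_path)
        if max_steps is not None and steps_done >= max_steps:
            break
        if stop_at_val_dice is not None and val_dice >= stop_at_val_dice:
            break

    history = pd.DataFrame(history_rows)
    history.to_csv(out / "history.csv", index=False)
    return TrainResult(history=history, checkpoint_path=ckpt_path, best_val_dice=best_val)


# ---------------------------------------------------------------- evaluation
def evaluate(model: SegmentationModel, manifest_path, split: str, input_size: int, spacing: float = 1.0):
    """Per-image and mean IoU/Dice/ACC/HD95 on one manifest split."""
    images, masks = load_manifest(manifest_path, split, input_size)
    model.eval()
    pairs = []
    with nn.no_grad():
        for i in range(0, len(images), 8):
            pred = model.predict_mask(Tensor(images[i : i + 8]))
            pairs.extend(
                (p[0], g[0].astype(np.uint8)) for p, g in zip(pred, masks[i : i + 8])
            )
    per_image = evaluate_masks(pairs, spacing=spacing)
    summary = {
        "iou": float(per_image["iou"].mean()),
        "dice": float(per_image["dice"].mean()),
        "acc": float(per_image["acc"].mean()),
        "hd95": float(per_image["hd95"].dropna().mean()) if per_image["hd95"].notna().any() else float("nan"),
        "n_images": int(len(per_image)),
    }
    return per_image, summary


def predict(model: SegmentationModel, image_path, out_path, input_size: int | None = None) -> np.ndarray:
    """Segment one image file and write the binary mask as a {0,255} PNG."""
    image = _to_gray01(iio.imread(image_path))
    side = input_size or image.shape[0]
    if side % 32:
        raise ConfigError(f"inference side {side} not divisible by 32")
    original_shape = image.shape
    if image.shape != (side, side):
        image = resize(image, (side, side), order=1, anti_aliasing=True)
    mask = model.predict_mask(Tensor(image[None, None]))[0, 0]
    if mask.shape != original_shape:
        mask = resize(mask.astype(float), original_shape, order=0) > 0.5
    out = (mask.astype(np.uint8)) * 255
    iio.imwrite(out_path, out)
    return out
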