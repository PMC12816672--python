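"""Training schedule and inference for the residual encoder-decoder.

Defaults mirror the production configuration (batch 32, initial learning
rate 0.05 decayed by e^-0.1 per epoch from epoch 11, stop at epoch 50,
70/30 train/test split) while the architecture size stays a knob so the
model trains on a single CPU in minutes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np

from .network import ResUNet, SGDMomentum, weighted_bce_with_logits
from .preprocess import TileSet, normalize_bands, tile, untile

__all__ = [
    "TrainConfig",
    "update_lr",
    "lr_schedule",
    "train_segmenter",
    "segment",
    "select_tiles",
    "save_model",
    "load_model",
]

LR_DECAY_FACTOR = float(np.exp(-0.1))


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 32
    lr_initial: float = 0.05
    lr_decay_start_epoch: int = 11
    max_epochs: int = 50
    split_fraction: float = 0.70
    seed: int = 0
    model_width: int = 16
    levels: int = 4
    pos_weight: float = 8.0
    momentum: float = 0.9

    def __post_init__(self) -> None:
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must be in (0, 1)")
        if self.lr_initial <= 0:
            raise ValueError("lr_initial must be positive")


def update_lr(lr_current: float) -> float:
    """One decay step: ``lr_new = lr_current * e^{-0.1}``."""
    if lr_current <= 0:
        raise ValueError("learning rate must be positive")
    return lr_current * LR_DECAY_FACTOR


def lr_schedule(epoch: int, config: TrainConfig) -> float:
    """Closed form of the per-epoch schedule (epochs are 1-indexed).

    ``lr(e) = lr0 * exp(-0.1 * max(0, e - decay_start + 1))``.
    """
    steps = max(0, epoch - config.lr_decay_start_epoch + 1)
    return config.lr_initial * float(np.exp(-0.1 * steps))


def select_tiles(tiles: np.ndarray, labels: np.ndarray, confounders: np.ndarray | None = None):
    """Indices of tiles worth training on: any FA pixel or any confounder pixel.

    Mirrors the practice of training only on sub-images containing typical
    features or potentially misleading patterns.
    """
    keep = []
    for k in range(tiles.shape[0]):
        has_fa = np.nansum(labels[k]) > 0
        has_conf = confounders is not None and (confounders[k] > 0).any()
        if has_fa or has_conf:
            keep.append(k)
    return np.asarray(keep, dtype=int)


def train_segmenter(
    tiles: np.ndarray,
    labels: np.ndarray,
    config: TrainConfig | None = None,
    val_tiles: np.ndarray | None = None,
    val_labels: np.ndarray | None = None,
):
    """Train the residual encoder-decoder on labelled tiles.

    Parameters
    ----------
    tiles
        (T, C, H, W) float array, NaN marking padded / invalid cells.
    labels
        (T, H, W) binary truth masks.
    config
        Schedule and architecture knobs; defaults follow the production
        setup with a desk-scale network.

    Returns
    -------
    (model, history)
        The trained model and a list of per-epoch dicts with keys
        ``epoch``, ``lr``, ``loss`` (and ``val_loss`` when a validation set
        is supplied).  Deterministic for a fixed config/seed.
    """
    if config is None:
        config = TrainConfig()
    tiles = np.asarray(tiles, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if tiles.shape[0] == 0:
        raise ValueError("empty tile set")
    if labels.shape[0] != tiles.shape[0] or labels.shape[-2:] != tiles.shape[-2:]:
        raise ValueError("label/tile shape mismatch")
    if np.nansum(labels) <= 0:
        raise ValueError("training labels contain no positive pixel")

    model = ResUNet(
        in_channels=tiles.shape[1],
        base_width=config.model_width,
        levels=config.levels,
        seed=config.seed,
    )
    opt = SGDMomentum(model, lr=config.lr_initial, momentum=config.momentum)
    rng = np.random.default_rng(config.seed)
    valid = np.isfinite(tiles).all(axis=1) & np.isfinite(labels)
    y = np.nan_to_num(labels, nan=0.0)

    history = []
    n = tiles.shape[0]
    for epoch in range(1, config.max_epochs + 1):
        opt.lr = lr_schedule(epoch, config)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = model.forward(tiles[idx], train=True)[:, 0]
            loss, dlogits = weighted_bce_with_logits(
                logits, y[idx], valid[idx], pos_weight=config.pos_weight
            )
            model.backward(dlogits[:, None])
            opt.step()
            losses.append(loss)
        rec = {"epoch": epoch, "lr": opt.lr, "loss": float(np.mean(losses))}
        if val_tiles is not None and val_labels is not None:
            vlogits = model.forward(val_tiles, train=False)[:, 0]
            vvalid = np.isfinite(val_tiles).all(axis=1) & np.isfinite(val_labels)
            vloss, _ = weighted_bce_with_logits(
                vlogits, np.nan_to_num(val_labels, nan=0.0), vvalid, config.pos_weight
            )
            rec["val_loss"] = vloss
        history.append(rec)
    return model, history


def segment(scene, model: ResUNet, threshold: float = 0.5, tile_size: int = 256) -> np.ndarray:
    """Binary FA mask for a scene from a trained model.

    The scene is normalised, tiled (NaN-padded), pushed through the model in
    evaluation mode, reassembled, and thresholded; invalid and padded cells
    are excluded (False).
    """
    stack, _ = normalize_bands(scene)
    ts = tile(stack, tile_size=tile_size)
    probs = model.predict_proba(ts.tiles)
    prob_tiles = TileSet(
        tiles=probs[:, None],
        origins=ts.origins,
        tile_size=ts.tile_size,
        source_shape=ts.source_shape,
    )
    prob = untile(prob_tiles)[0]
    mask = prob >= threshold
    return mask & scene.valid_mask & np.isfinite(stack).all(axis=0)


def save_model(model: ResUNet, history, path) -> None:
    """Single-file portable checkpoint (.npz) with config embedded."""
    meta = json.dumps({"config": model.config, "history": list(history)})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **model.state_arrays())


def load_model(path) -> tuple[ResUNet, list]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
        model = ResUNet(**meta["config"])
        model.load_state_arrays({k: data[k] for k in data.files if k != "__meta__"})
    return model, meta["history"]
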