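"""Fully and weakly supervised tile training with hard mining.

Fully supervised (FS) epochs draw class-balanced interleaved batches:
positives uniformly over annotated-tile anchors of neoplastic slides,
negatives from negative slides with per-anchor sampling weights that are
refreshed after each epoch by sliding-window inference (false positives
become more likely to be drawn).  Weakly supervised (WS) epochs alternate
inference and training: each slide's top-k highest-probability tiles are
pushed into a fixed-capacity buffer with the slide's label, and whenever
the buffer reaches capacity it is shuffled, consumed in gradient-step
batches and cleared.  Both regimes share Adam with stepped learning-rate
decay, photometric augmentation, optional partial fine-tuning and early
stopping on slide-level validation loss.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .annotation import AnnotationSet, SlideRecord, tile_is_positive
from .backbone import HEAD, NORM_AFFINE, Adam, TileClassifier, bce_loss
from .errors import ContractError, InvalidConfigError, TrainingError
from .inference import HeatmapGrid, predict_heatmap, wsi_score
from .slide_io import SlidePyramid, TileGrid, TileImage, build_tile_grid, detect_tissue, read_tile

__all__ = [
    "TrainConfig",
    "AugmentJitter",
    "SamplingWeights",
    "HardMiningBuffer",
    "TrainState",
    "SlideContext",
    "Trainer",
    "lr_at_epoch",
    "update_negative_weights",
    "select_hard_tiles",
    "augment_tile",
    "trainable_parameter_mask",
    "early_stop_update",
    "prepare_slides",
]

MODE_FS = "FS"
MODE_WS = "WS"
MODE_FS_THEN_WS = "FS_then_WS"


@dataclass(frozen=True)
class AugmentJitter:
    """Photometric jitter half-widths; zeros mean identity."""

    brightness: float = 16.0  # additive offset range, pixel units
    saturation: float = 0.2  # multiplicative half-width around 1
    contrast: float = 0.2  # multiplicative half-width around 1


@dataclass(frozen=True)
class TrainConfig:
    tile_size: int = 1024
    working_magnification: float = 10.0
    min_tissue_fraction: float = 0.05
    batch_size: int = 32
    k_top_tiles: int = 8
    buffer_capacity_N: int = 256
    learning_rate: float = 0.001
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    lr_decay_factor: float = 0.95
    lr_decay_period_epochs: int = 2
    early_stop_patience: int = 10
    max_epochs: int = 100
    mode: str = MODE_WS
    init: str = "random"
    fine_tune: str = "full"  # {"full", "partial"}
    augment: AugmentJitter = field(default_factory=AugmentJitter)
    seed: int = 0

    def __post_init__(self):
        if self.k_top_tiles > self.buffer_capacity_N:
            raise InvalidConfigError("k_top_tiles must not exceed buffer_capacity_N")
        if self.buffer_capacity_N % self.batch_size != 0:
            raise InvalidConfigError("buffer_capacity_N must be divisible by batch_size")
        if self.batch_size % 2 != 0:
            raise InvalidConfigError("batch_size must be even (balanced FS batches)")
        if self.mode not in {MODE_FS, MODE_WS, MODE_FS_THEN_WS}:
            raise InvalidConfigError(f"unknown mode {self.mode!r}")


def lr_at_epoch(epoch: int, config: TrainConfig) -> float:
    """Stepped decay: lr = base * factor^floor(epoch / period)."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return config.learning_rate * config.lr_decay_factor ** (
        epoch // config.lr_decay_period_epochs
    )


@dataclass
class SamplingWeights:
    """Per negative slide, per-anchor weights (row-major grid order, sum 1)."""

    per_slide: dict[str, np.ndarray]

    def for_slide(self, slide_id: str, n_anchors: int) -> np.ndarray:
        w = self.per_slide.get(slide_id)
        if w is None or len(w) != n_anchors:
            return np.full(n_anchors, 1.0 / n_anchors) if n_anchors else np.empty(0)
        return w


def update_negative_weights(
    negative_heatmaps: dict[str, HeatmapGrid], epsilon: float = 0.01
) -> SamplingWeights:
    """Weight of anchor i proportional to ``epsilon + p_i``, per slide.

    The additive floor keeps never-predicted regions reachable; an empty
    heatmap falls back to uniform weights with a warning.
    """
    per_slide = {}
    for slide_id, heatmap in negative_heatmaps.items():
        p = heatmap.probabilities()
        if p.size == 0:
            warnings.warn(f"slide {slide_id}: empty heatmap; uniform weights", stacklevel=2)
            per_slide[slide_id] = np.empty(0)
            continue
        w = epsilon + p
        per_slide[slide_id] = w / w.sum()
    return SamplingWeights(per_slide=per_slide)


def select_hard_tiles(
    heatmap: HeatmapGrid, k: int, grid: TileGrid | None = None
) -> list[tuple[int, int]]:
    """The k highest-probability positions; ties break row-major.

    Returns level-0 anchors when ``grid`` is given, lattice (row, col)
    cells otherwise.  Fewer than k positions -> all of them.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    cells = np.argwhere(heatmap.evaluated)  # row-major order
    if cells.size == 0:
        warnings.warn(f"slide {heatmap.slide_id}: empty heatmap", stacklevel=2)
        return []
    probs = heatmap.values[cells[:, 0], cells[:, 1]]
    order = np.argsort(-probs, kind="stable")[:k]
    selected = [(int(r), int(c)) for r, c in cells[order]]
    if grid is None:
        return selected
    cell_to_anchor = dict(zip(grid.anchor_cells, grid.anchors))
    return [cell_to_anchor[cell] for cell in selected]


@dataclass
class HardMiningBuffer:
    """Fixed-capacity store of (slide_id, anchor, label) training entries."""

    capacity: int
    entries: list[tuple[str, tuple[int, int], int]] = field(default_factory=list)

    def push(self, slide_id: str, anchor: tuple[int, int], label: int) -> None:
        if self.is_full:
            raise TrainingError("push into a full buffer; flush first")
        self.entries.append((slide_id, anchor, int(label)))

    @property
    def is_full(self) -> bool:
        return len(self.entries) >= self.capacity

    def drain(self, rng: np.random.Generator, batch_size: int):
        """Shuffle, yield batches, clear."""
        order = rng.permutation(len(self.entries))
        shuffled = [self.entries[i] for i in order]
        for start in range(0, len(shuffled), batch_size):
            yield shuffled[start : start + batch_size]
        self.entries.clear()

    def __len__(self) -> int:
        return len(self.entries)


def augment_tile(
    tile: TileImage | np.ndarray, rng: np.random.Generator, jitter: AugmentJitter
) -> np.ndarray:
    """Brightness/saturation/contrast jitter, clipped to [0, 255].

    Zero-width jitter ranges reproduce the input exactly; a fixed rng seed
    reproduces the augmentation exactly.
    """
    pixels = tile.pixels if isinstance(tile, TileImage) else tile
    x = pixels.astype(float)
    brightness = rng.uniform(-jitter.brightness, jitter.brightness)
    saturation = rng.uniform(1 - jitter.saturation, 1 + jitter.saturation)
    contrast = rng.uniform(1 - jitter.contrast, 1 + jitter.contrast)

    gray = x.mean(axis=2, keepdims=True)
    x = gray + saturation * (x - gray)
    mean = x.mean()
    x = mean + contrast * (x - mean)
    x = x + brightness
    return np.clip(x, 0, 255).round().astype(np.uint8)


def trainable_parameter_mask(model: TileClassifier, mode: str) -> dict[str, bool]:
    """Partial mode unfreezes only normalisation-affine and head parameters."""
    groups = model.parameter_groups()
    if mode == "full":
        return {name: True for name in groups}
    if mode != "partial":
        raise ValueError(f"unknown fine-tune mode {mode!r}")
    if HEAD not in groups.values():
        raise ContractError("backbone declares no final-classifier parameter group")
    return {name: group in (NORM_AFFINE, HEAD) for name, group in groups.items()}


@dataclass
class TrainState:
    """Early-stopping bookkeeping; best epoch is the argmin of val losses."""

    epoch: int = 0
    val_losses: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_loss: float = math.inf
    epochs_since_improvement: int = 0
    best_checkpoint: dict | None = None


def early_stop_update(
    state: TrainState, new_val_loss: float, patience: int
) -> tuple[bool, int]:
    """Record a validation loss; stop after ``patience`` non-improvements.

    Improvement is strictly-lower-than-best (min-delta 0).  NaN loss raises
    :class:`TrainingError`.
    """
    if math.isnan(new_val_loss):
        raise TrainingError("validation loss is NaN")
    state.val_losses.append(float(new_val_loss))
    epoch = len(state.val_losses) - 1
    if new_val_loss < state.best_loss:
        state.best_loss = float(new_val_loss)
        state.best_epoch = epoch
        state.epochs_since_improvement = 0
    else:
        state.epochs_since_improvement += 1
    return state.epochs_since_improvement >= patience, state.best_epoch


# ---------------------------------------------------------------------------
# Slide preparation


@dataclass
class SlideContext:
    """Everything training needs about one slide, precomputed once."""

    record: SlideRecord
    pyramid: SlidePyramid
    grid: TileGrid
    annotations: AnnotationSet
    positive_anchor_idx: np.ndarray | None = None  # indices into grid.anchors

    @property
    def slide_id(self) -> str:
        return self.record.slide_id

    @property
    def label(self) -> int:
        return 1 if self.record.is_neoplastic else 0


def prepare_slides(
    records: Sequence[SlideRecord],
    annotations: dict[str, AnnotationSet],
    config: TrainConfig,
    open_slide: Callable[[SlideRecord], SlidePyramid] | None = None,
    thumb_max_dim: int = 2048,
) -> list[SlideContext]:
    """Open slides, mask tissue, build grids and index positive anchors."""
    opener = open_slide or (
        lambda rec: SlidePyramid.open(
            rec.path, scan_magnification=rec.scan_magnification, slide_id=rec.slide_id
        )
    )
    contexts = []
    for rec in records:
        pyramid = opener(rec)
        mask = detect_tissue(pyramid, thumb_max_dim=thumb_max_dim)
        grid = build_tile_grid(
            pyramid,
            mask,
            tile_size=config.tile_size,
            stride=config.tile_size // 2,
            working_magnification=config.working_magnification,
            min_tissue_fraction=config.min_tissue_fraction,
        )
        annset = annotations.get(rec.slide_id, AnnotationSet(slide_id=rec.slide_id))
        ctx = SlideContext(record=rec, pyramid=pyramid, grid=grid, annotations=annset)
        if rec.is_neoplastic and len(annset):
            span = grid.level0_tile_span
            idx = [
                i
                for i, anchor in enumerate(grid.anchors)
                if tile_is_positive(anchor, (span, span), annset)
            ]
            ctx.positive_anchor_idx = np.asarray(idx, dtype=int)
        contexts.append(ctx)
    return contexts


# ---------------------------------------------------------------------------
# Trainer


class Trainer:
    """Orchestrates FS/WS epochs, validation and early stopping."""

    def __init__(
        self,
        model: TileClassifier,
        train_slides: Sequence[SlideContext],
        val_slides: Sequence[SlideContext],
        config: TrainConfig,
    ):
        self.model = model
        self.train_slides = list(train_slides)
        self.val_slides = list(val_slides)
        self.config = config
        self.optimizer = Adam(beta1=config.adam_beta1, beta2=config.adam_beta2)
        self.trainable = trainable_parameter_mask(model, config.fine_tune)
        root = np.random.default_rng(config.seed)
        # independent streams so FS/WS/augment draws never interleave
        self._rng_sample, self._rng_buffer, self._rng_augment, self._rng_order = (
            root.spawn(4)
        )
        self.buffer = HardMiningBuffer(capacity=config.buffer_capacity_N)
        self.negative_weights = SamplingWeights(per_slide={})
        self.state = TrainState()
        self.log: list[dict] = []
        self._epoch = 0

    # -- shared helpers -----------------------------------------------------

    def _read(self, ctx: SlideContext, anchor, augment: bool) -> np.ndarray:
        tile = read_tile(
            ctx.pyramid, anchor, self.config.tile_size, self.config.working_magnification
        )
        if augment:
            return augment_tile(tile, self._rng_augment, self.config.augment)
        return tile.pixels

    def _gradient_step(self, tiles: np.ndarray, labels: np.ndarray) -> float:
        loss, grads = self.model.loss_and_grads(tiles, labels)
        if math.isnan(loss):
            raise TrainingError("training loss is NaN")
        lr = lr_at_epoch(self._epoch, self.config)
        self.optimizer.step(self.model.params, grads, lr, self.trainable)
        return loss

    def validation_loss(self) -> float:
        """Slide-level BCE of max-aggregated scores over validation slides."""
        scores, labels = [], []
        for ctx in self.val_slides:
            heatmap = predict_heatmap(ctx.pyramid, self.model, ctx.grid)
            scores.append(wsi_score(heatmap))
            labels.append(ctx.label)
        return bce_loss(np.asarray(scores), np.asarray(labels))

    # -- fully supervised ---------------------------------------------------

    def _fs_pools(self):
        positives = []
        for ctx in self.train_slides:
            if not ctx.record.is_neoplastic:
                continue
            if ctx.positive_anchor_idx is None or len(ctx.positive_anchor_idx) == 0:
                raise InvalidConfigError(
                    f"neoplastic slide {ctx.slide_id} has no annotated positive tiles; "
                    "fully supervised sampling requires annotations"
                )
            positives.extend((ctx, int(i)) for i in ctx.positive_anchor_idx)
        negatives = [ctx for ctx in self.train_slides if not ctx.record.is_neoplastic]
        if not positives or not negatives:
            raise InvalidConfigError(
                "fully supervised training needs >=1 annotated neoplastic and >=1 negative slide"
            )
        return positives, negatives

    def make_fs_batch(self, augment: bool = True) -> tuple[np.ndarray, np.ndarray]:
        """Balanced interleaved batch: P,N,P,N,... with replacement."""
        half = self.config.batch_size // 2
        positives, negatives = self._fs_pools()
        rng = self._rng_sample

        pos_picks = rng.integers(0, len(positives), size=half)
        tiles, labels = [], []
        for slot in range(half):
            ctx, anchor_i = positives[pos_picks[slot]]
            tiles.append(self._read(ctx, ctx.grid.anchors[anchor_i], augment))
            labels.append(1)

            neg_ctx = negatives[rng.integers(0, len(negatives))]
            w = self.negative_weights.for_slide(neg_ctx.slide_id, len(neg_ctx.grid.anchors))
            anchor_j = rng.choice(len(neg_ctx.grid.anchors), p=w)
            tiles.append(self._read(neg_ctx, neg_ctx.grid.anchors[anchor_j], augment))
            labels.append(0)

        # interleave by construction: even slots positive, odd negative
        order = np.empty(self.config.batch_size, dtype=int)
        order[0::2] = 2 * np.arange(half)
        order[1::2] = 2 * np.arange(half) + 1
        batch = np.stack([tiles[i] for i in order])
        return batch, np.array([labels[i] for i in order])

    def fs_epoch(self) -> dict:
        """Fixed number of balanced-batch steps, then hard-mining refresh."""
        positives, negatives = self._fs_pools()
        half = self.config.batch_size // 2
        n_steps = max(1, len(positives) // half)
        losses = []
        for _ in range(n_steps):
            tiles, labels = self.make_fs_batch()
            losses.append(self._gradient_step(tiles, labels))
        heatmaps = {
            ctx.slide_id: predict_heatmap(ctx.pyramid, self.model, ctx.grid)
            for ctx in negatives
        }
        self.negative_weights = update_negative_weights(heatmaps)
        return {"phase": "FS", "steps": n_steps, "train_loss": float(np.mean(losses))}

    # -- weakly supervised --------------------------------------------------

    def ws_epoch(self) -> dict:
        """One seeded permutation pass; every slide contributes its top-k."""
        k = self.config.k_top_tiles
        order = self._rng_order.permutation(len(self.train_slides))
        losses, n_flushes = [], 0
        for idx in order:
            ctx = self.train_slides[idx]
            if len(ctx.grid) == 0:
                warnings.warn(f"slide {ctx.slide_id}: empty tile grid; skipped", stacklevel=2)
                continue
            heatmap = predict_heatmap(ctx.pyramid, self.model, ctx.grid)
            for anchor in select_hard_tiles(heatmap, k, ctx.grid):
                self.buffer.push(ctx.slide_id, anchor, ctx.label)
                if self.buffer.is_full:
                    losses.extend(self._flush_buffer())
                    n_flushes += 1
        return {
            "phase": "WS",
            "flushes": n_flushes,
            "buffer_fill": len(self.buffer),
            "train_loss": float(np.mean(losses)) if losses else None,
        }

    def _flush_buffer(self) -> list[float]:
        ctx_by_id = {ctx.slide_id: ctx for ctx in self.train_slides}
        losses = []
        for batch in self.buffer.drain(self._rng_buffer, self.config.batch_size):
            tiles = np.stack(
                [self._read(ctx_by_id[sid], anchor, augment=True) for sid, anchor, _ in batch]
            )
            labels = np.array([label for _, _, label in batch])
            losses.append(self._gradient_step(tiles, labels))
        return losses

    # -- driver -------------------------------------------------------------

    def _run_phase(self, epoch_fn, max_epochs: int) -> None:
        self.state = TrainState()
        self.state.best_checkpoint = self.model.state_dict()
        for _ in range(max_epochs):
            entry = epoch_fn()
            entry["epoch"] = self._epoch
            entry["lr"] = lr_at_epoch(self._epoch, self.config)
            val_loss = self.validation_loss()
            entry["val_loss"] = val_loss
            improved_before = self.state.best_loss
            stop, _ = early_stop_update(
                self.state, val_loss, self.config.early_stop_patience
            )
            if val_loss < improved_before:
                self.state.best_checkpoint = self.model.state_dict()
            self.log.append(entry)
            self._epoch += 1
            if stop:
                break
        if self.state.best_checkpoint is not None:
            self.model.load_state_dict(self.state.best_checkpoint)

    def fit(self) -> TileClassifier:
        """Train per the configured mode; returns the best-validation model."""
        mode = self.config.mode
        if mode in (MODE_FS, MODE_FS_THEN_WS):
            self._run_phase(self.fs_epoch, self.config.max_epochs)
        if mode in (MODE_WS, MODE_FS_THEN_WS):
            self._run_phase(self.ws_epoch, self.config.max_epochs)
        return self.model
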