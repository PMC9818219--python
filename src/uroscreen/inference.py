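"""Sliding-window prediction, heatmap assembly, slide scoring and overlays.

A heatmap cell holds the probability of the tile anchored at that lattice
position; positions filtered out by the tissue rule carry a NaN sentinel so
"no cells here" stays distinguishable from "confidently negative".  The
slide score is the maximum over non-sentinel cells.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .backbone import TileClassifier
from .errors import ContractError
from .slide_io import SlidePyramid, TileGrid, read_tile

__all__ = [
    "HeatmapGrid",
    "WsiPrediction",
    "predict_heatmap",
    "wsi_score",
    "render_overlay",
    "save_heatmap",
    "load_heatmap",
    "write_predictions_csv",
]

SENTINEL = np.nan


@dataclass
class HeatmapGrid:
    """Per-anchor neoplastic probabilities on the stride lattice."""

    values: np.ndarray  # float (n_rows, n_cols); NaN = not evaluated
    stride_px: int
    tile_size_px: int
    slide_id: str

    @property
    def evaluated(self) -> np.ndarray:
        return ~np.isnan(self.values)

    @property
    def n_tiles_evaluated(self) -> int:
        return int(self.evaluated.sum())

    def probabilities(self) -> np.ndarray:
        """Non-sentinel values in row-major lattice order."""
        return self.values[self.evaluated]

    def argmax_cell(self) -> tuple[int, int] | None:
        """(row, col) of the highest-probability cell, None if empty."""
        if not self.n_tiles_evaluated:
            return None
        flat = np.where(np.isnan(self.values), -np.inf, self.values)
        r, c = np.unravel_index(int(np.argmax(flat)), flat.shape)
        return int(r), int(c)


@dataclass
class WsiPrediction:
    slide_id: str
    score: float
    heatmap: HeatmapGrid
    n_tiles_evaluated: int


def predict_heatmap(
    slide: SlidePyramid,
    model: TileClassifier,
    grid: TileGrid,
    batch_size: int = 32,
) -> HeatmapGrid:
    """One forward pass per retained anchor, assembled into the lattice."""
    if model.input_size != grid.tile_size_px:
        raise ContractError(
            f"model expects {model.input_size}-px tiles but grid uses {grid.tile_size_px}-px"
        )
    values = np.full(grid.shape, SENTINEL, dtype=float)
    anchors = grid.anchors
    for start in range(0, len(anchors), batch_size):
        batch_anchors = anchors[start : start + batch_size]
        tiles = np.stack(
            [
                read_tile(slide, a, grid.tile_size_px, grid.working_magnification).pixels
                for a in batch_anchors
            ]
        )
        probs = model.predict_proba(tiles)
        for (r, c), p in zip(grid.anchor_cells[start : start + batch_size], probs):
            values[r, c] = p
    return HeatmapGrid(
        values=values,
        stride_px=grid.stride_px,
        tile_size_px=grid.tile_size_px,
        slide_id=slide.slide_id,
    )


def wsi_score(heatmap: HeatmapGrid) -> float:
    """Maximum probability over evaluated tiles; 0 for an empty heatmap."""
    if not heatmap.n_tiles_evaluated:
        warnings.warn(
            f"slide {heatmap.slide_id}: heatmap has no evaluated tiles; score 0",
            stacklevel=2,
        )
        return 0.0
    return float(np.nanmax(heatmap.values))


def predict_slide(
    slide: SlidePyramid, model: TileClassifier, grid: TileGrid, batch_size: int = 32
) -> WsiPrediction:
    heatmap = predict_heatmap(slide, model, grid, batch_size=batch_size)
    return WsiPrediction(
        slide_id=slide.slide_id,
        score=wsi_score(heatmap),
        heatmap=heatmap,
        n_tiles_evaluated=heatmap.n_tiles_evaluated,
    )


def render_overlay(
    heatmap: HeatmapGrid,
    slide_thumbnail: np.ndarray,
    slide_id: str | None = None,
    colormap: str = "jet",
    alpha: float = 0.45,
) -> np.ndarray:
    """Alpha-blend the colour-mapped heatmap over a slide thumbnail.

    The jet map runs blue (low probability) to red (high); sentinel cells
    stay fully transparent.  Output has the thumbnail's dimensions.
    """
    from matplotlib import colormaps

    if slide_id is not None and slide_id != heatmap.slide_id:
        raise ValueError(
            f"thumbnail slide {slide_id!r} does not match heatmap slide {heatmap.slide_id!r}"
        )
    th, tw = slide_thumbnail.shape[:2]
    nr, nc = heatmap.values.shape
    # nearest-neighbour upsample of the lattice to thumbnail scale
    rows = np.minimum((np.arange(th) * nr) // th, nr - 1)
    cols = np.minimum((np.arange(tw) * nc) // tw, nc - 1)
    up = heatmap.values[np.ix_(rows, cols)]

    cmap = colormaps[colormap]
    rgba = cmap(np.nan_to_num(up, nan=0.0))
    colour = (rgba[..., :3] * 255.0)
    out = slide_thumbnail.astype(float).copy()
    blend_mask = ~np.isnan(up)
    out[blend_mask] = (1 - alpha) * out[blend_mask] + alpha * colour[blend_mask]
    return np.clip(out, 0, 255).round().astype(np.uint8)


def save_heatmap(heatmap: HeatmapGrid, path: str | Path) -> None:
    """Write ``<path>.npz`` plus a JSON sidecar with the lattice metadata."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), values=heatmap.values)
    sidecar = {
        "slide_id": heatmap.slide_id,
        "stride_px": heatmap.stride_px,
        "tile_size_px": heatmap.tile_size_px,
        "shape": list(heatmap.values.shape),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_heatmap(path: str | Path) -> HeatmapGrid:
    path = Path(path)
    values = np.load(path.with_suffix(".npz"))["values"]
    meta = json.loads(path.with_suffix(".json").read_text())
    return HeatmapGrid(
        values=values,
        stride_px=meta["stride_px"],
        tile_size_px=meta["tile_size_px"],
        slide_id=meta["slide_id"],
    )


def write_predictions_csv(predictions: list[WsiPrediction], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["slide_id", "score", "n_tiles"])
        for pred in predictions:
            writer.writerow([pred.slide_id, f"{pred.score:.8f}", pred.n_tiles_evaluated])


def read_predictions_csv(path: str | Path) -> dict[str, float]:
    scores: dict[str, float] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            scores[row["slide_id"]] = float(row["score"])
    return scores
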