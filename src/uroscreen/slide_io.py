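"""Slide reading, Otsu tissue masking and tile enumeration/extraction.

All coordinates are 0-based, half-open and expressed in the level-0 pixel
frame.  Tile size and stride are given in working-magnification pixels and
converted to level-0 lengths with the scan/working magnification ratio
(factor 2 for a x20 scan read at x10).
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from PIL import Image

from .annotation import SlideRecord
from .errors import DegenerateHistogramError, OutOfBoundsError

__all__ = [
    "SlidePyramid",
    "TissueMask",
    "TileGrid",
    "TileImage",
    "otsu_threshold",
    "detect_tissue",
    "build_tile_grid",
    "read_tile",
    "read_manifest",
    "write_manifest",
]

PAD_VALUE = 255  # white LBC background

_GRAY_WEIGHTS = np.array([0.2125, 0.7154, 0.0721])


class SlidePyramid:
    """A multiresolution slide; plain images are single-level pyramids.

    Supports pyramidal or single-page TIFF (via :mod:`tifffile`) and plain
    PNG (via Pillow).  Level 0 is the largest level; the nominal scan
    magnification comes from the manifest.
    """

    def __init__(
        self,
        slide_id: str,
        levels: list[np.ndarray],
        scan_magnification: float = 20.0,
        path: str | None = None,
    ):
        if not levels:
            raise IOError("slide has no image levels")
        areas = [lv.shape[0] * lv.shape[1] for lv in levels]
        order = np.argsort(areas)[::-1]
        self._levels = [np.ascontiguousarray(levels[i]) for i in order]
        self.slide_id = slide_id
        self.scan_magnification = float(scan_magnification)
        self.path = path

    @classmethod
    def open(
        cls, path: str | Path, scan_magnification: float = 20.0, slide_id: str | None = None
    ) -> "SlidePyramid":
        path = Path(path)
        if not path.exists():
            raise IOError(f"slide file not found: {path}")
        sid = slide_id or path.stem
        suffix = path.suffix.lower()
        if suffix in {".tif", ".tiff", ".svs"}:
            with tifffile.TiffFile(str(path)) as tf:
                levels = [page.asarray() for page in tf.pages]
        else:
            levels = [np.asarray(Image.open(path).convert("RGB"))]
        levels = [_as_rgb(lv) for lv in levels]
        return cls(sid, levels, scan_magnification=scan_magnification, path=str(path))

    @classmethod
    def from_array(
        cls, image: np.ndarray, slide_id: str = "slide", scan_magnification: float = 20.0
    ) -> "SlidePyramid":
        return cls(slide_id, [_as_rgb(np.asarray(image))], scan_magnification)

    @property
    def level_dimensions(self) -> list[tuple[int, int]]:
        """(width, height) per level, level 0 first."""
        return [(lv.shape[1], lv.shape[0]) for lv in self._levels]

    @property
    def dimensions(self) -> tuple[int, int]:
        return self.level_dimensions[0]

    def read_region(self, x: int, y: int, width: int, height: int) -> np.ndarray:
        """Read a level-0 region; out-of-bounds area is padded white.

        Raises :class:`OutOfBoundsError` if the region is entirely outside
        the slide.
        """
        W, H = self.dimensions
        if x >= W or y >= H or x + width <= 0 or y + height <= 0:
            raise OutOfBoundsError(
                f"region ({x},{y},{width},{height}) lies outside slide {W}x{H}"
            )
        out = np.full((height, width, 3), PAD_VALUE, dtype=np.uint8)
        x0, y0 = max(x, 0), max(y, 0)
        x1, y1 = min(x + width, W), min(y + height, H)
        out[y0 - y : y1 - y, x0 - x : x1 - x] = self._levels[0][y0:y1, x0:x1]
        return out

    def thumbnail(self, max_dim: int) -> tuple[np.ndarray, int]:
        """Integer-downsampled RGB thumbnail and its downsample factor."""
        W, H = self.dimensions
        factor = max(1, math.ceil(max(W, H) / max_dim))
        img = self._levels[0]
        th, tw = math.ceil(H / factor), math.ceil(W / factor)
        pad_h, pad_w = th * factor - H, tw * factor - W
        if pad_h or pad_w:
            img = np.pad(
                img,
                ((0, pad_h), (0, pad_w), (0, 0)),
                mode="constant",
                constant_values=PAD_VALUE,
            )
        thumb = (
            img.reshape(th, factor, tw, factor, 3)
            .mean(axis=(1, 3))
            .round()
            .astype(np.uint8)
        )
        return thumb, factor


def _as_rgb(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:
        arr = arr[..., :3]
    return arr.astype(np.uint8, copy=False)


@dataclass
class TissueMask:
    """Binary foreground mask at thumbnail resolution."""

    grid: np.ndarray  # bool (h, w)
    downsample_factor: int  # level-0 pixels per mask cell side
    threshold_used: int

    @property
    def tissue_fraction(self) -> float:
        return float(self.grid.mean()) if self.grid.size else 0.0


def otsu_threshold(histogram: np.ndarray) -> int:
    """Otsu threshold on a 256-bin grayscale histogram.

    Returns the threshold t maximising between-class variance for the split
    foreground = {intensity < t}, background = {intensity >= t}; ties are
    broken toward the lowest maximising t.  Raises
    :class:`DegenerateHistogramError` if only one bin is populated.
    """
    hist = np.asarray(histogram, dtype=float)
    if hist.shape != (256,):
        raise ValueError("histogram must have 256 bins")
    total = hist.sum()
    if total <= 0:
        raise ValueError("histogram is empty")
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError("histogram has a single populated bin")

    p = hist / total
    bins = np.arange(256, dtype=float)
    # cumulative class probability / mean below each candidate threshold t
    omega = np.cumsum(p)  # omega[t-1] = P(intensity < t)
    mu = np.cumsum(p * bins)
    mu_total = mu[-1]

    # candidate thresholds t = 1..255; classes: [0, t) and [t, 256)
    w0 = omega[:-1]
    w1 = 1.0 - w0
    m0 = np.divide(mu[:-1], w0, out=np.zeros(255), where=w0 > 0)
    m1 = np.divide(mu_total - mu[:-1], w1, out=np.zeros(255), where=w1 > 0)
    sigma_b = w0 * w1 * (m0 - m1) ** 2
    return int(np.argmax(sigma_b)) + 1  # lowest argmax via np.argmax tie rule


def detect_tissue(slide: SlidePyramid, thumb_max_dim: int = 2048) -> TissueMask:
    """Build the tissue mask from a grayscale thumbnail via Otsu.

    Foreground = pixels strictly below the threshold (cells are darker than
    the bright background).  A degenerate (single-valued) thumbnail yields an
    empty mask with a warning.
    """
    thumb, factor = slide.thumbnail(thumb_max_dim)
    gray = np.clip(thumb.astype(float) @ _GRAY_WEIGHTS, 0, 255).astype(np.uint8)
    hist = np.bincount(gray.ravel(), minlength=256).astype(np.int64)
    try:
        threshold = otsu_threshold(hist)
    except DegenerateHistogramError:
        warnings.warn(
            f"slide {slide.slide_id}: degenerate intensity histogram; empty tissue mask",
            stacklevel=2,
        )
        return TissueMask(np.zeros(gray.shape, dtype=bool), factor, 0)
    return TissueMask(gray < threshold, factor, threshold)


@dataclass
class TileGrid:
    """Stride lattice of tile anchors restricted to tissue.

    ``anchors`` are level-0 top-left coordinates in row-major order;
    ``shape`` is the full lattice (n_rows, n_cols) before tissue filtering
    and ``anchor_cells`` gives each retained anchor's (row, col) in it.
    """

    anchors: list[tuple[int, int]]
    anchor_cells: list[tuple[int, int]]
    shape: tuple[int, int]
    tile_size_px: int
    stride_px: int
    working_magnification: float
    scan_magnification: float

    @property
    def level0_tile_span(self) -> int:
        return round(self.tile_size_px * self.scan_magnification / self.working_magnification)

    @property
    def level0_stride_span(self) -> int:
        return round(self.stride_px * self.scan_magnification / self.working_magnification)

    def __len__(self) -> int:
        return len(self.anchors)


def _axis_positions(extent: int, span: int, stride: int) -> list[int]:
    """Stride-lattice positions covering [0, extent), padded edge included."""
    if extent <= span:
        return [0]
    n_full = (extent - span) // stride + 1
    xs = [i * stride for i in range(n_full)]
    if xs[-1] + span < extent:
        xs.append(n_full * stride)
    return xs


def build_tile_grid(
    slide: SlidePyramid,
    mask: TissueMask,
    tile_size: int = 1024,
    stride: int = 512,
    working_magnification: float = 10.0,
    min_tissue_fraction: float = 0.05,
) -> TileGrid:
    """Enumerate row-major stride-lattice anchors and keep tissue tiles.

    An anchor is retained iff the tissue fraction under its (possibly
    edge-padded) footprint is >= ``min_tissue_fraction`` and nonzero.
    Out-of-slide footprint area counts as non-tissue.
    """
    if stride > tile_size:
        raise ValueError("stride must not exceed tile size")
    W, H = slide.dimensions
    ratio = slide.scan_magnification / working_magnification
    span = round(tile_size * ratio)
    stride_span = round(stride * ratio)

    xs = _axis_positions(W, span, stride_span)
    ys = _axis_positions(H, span, stride_span)

    mh, mw = mask.grid.shape
    f = mask.downsample_factor
    integral = np.zeros((mh + 1, mw + 1), dtype=np.int64)
    np.cumsum(np.cumsum(mask.grid, axis=0), axis=1, out=integral[1:, 1:])

    anchors: list[tuple[int, int]] = []
    cells: list[tuple[int, int]] = []
    for r, y in enumerate(ys):
        my0, my1 = y / f, (y + span) / f
        iy0, iy1 = int(np.clip(math.floor(my0), 0, mh)), int(np.clip(math.ceil(my1), 0, mh))
        for c, x in enumerate(xs):
            mx0, mx1 = x / f, (x + span) / f
            ix0 = int(np.clip(math.floor(mx0), 0, mw))
            ix1 = int(np.clip(math.ceil(mx1), 0, mw))
            tissue = integral[iy1, ix1] - integral[iy0, ix1] - integral[iy1, ix0] + integral[iy0, ix0]
            denom = (my1 - my0) * (mx1 - mx0)  # full footprint in mask cells
            frac = tissue / denom if denom > 0 else 0.0
            if tissue > 0 and frac >= min_tissue_fraction:
                anchors.append((x, y))
                cells.append((r, c))
    return TileGrid(
        anchors=anchors,
        anchor_cells=cells,
        shape=(len(ys), len(xs)),
        tile_size_px=tile_size,
        stride_px=stride,
        working_magnification=working_magnification,
        scan_magnification=slide.scan_magnification,
    )


@dataclass
class TileImage:
    """One working-magnification tile; always exactly tile_size squared."""

    pixels: np.ndarray  # uint8 (tile_size, tile_size, 3)
    anchor: tuple[int, int]
    working_magnification: float


def read_tile(
    slide: SlidePyramid,
    anchor: tuple[int, int],
    tile_size: int = 1024,
    working_magnification: float = 10.0,
) -> TileImage:
    """Read the level-0 window under an anchor and resample to tile_size.

    The level-0 read window side is ``tile_size * scan_mag / working_mag``;
    integer factors use exact block-mean pooling, the identity factor is a
    pixel-identical crop.  Edge tiles are padded white.
    """
    ratio = slide.scan_magnification / working_magnification
    span = round(tile_size * ratio)
    x, y = anchor
    region = slide.read_region(x, y, span, span)
    if span == tile_size:
        pixels = region
    elif span % tile_size == 0:
        f = span // tile_size
        sums = region.reshape(tile_size, f, tile_size, f, 3).sum(
            axis=(1, 3), dtype=np.uint32
        )
        pixels = ((sums + f * f // 2) // (f * f)).astype(np.uint8)  # block mean, half-up
    else:
        from skimage.transform import resize

        pixels = (
            resize(region, (tile_size, tile_size, 3), preserve_range=True, anti_aliasing=True)
            .round()
            .astype(np.uint8)
        )
    return TileImage(pixels=pixels, anchor=(x, y), working_magnification=working_magnification)


# ---------------------------------------------------------------------------
# Manifest CSV

_MANIFEST_FIELDS = ["slide_id", "path", "cytology_class", "split", "scan_magnification"]


def write_manifest(records: Sequence[SlideRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_MANIFEST_FIELDS)
        writer.writeheader()
        for rec in records:
            writer.writerow(
                {
                    "slide_id": rec.slide_id,
                    "path": rec.path,
                    "cytology_class": rec.cytology_class.value,
                    "split": rec.split,
                    "scan_magnification": rec.scan_magnification,
                }
            )


def read_manifest(path: str | Path) -> list[SlideRecord]:
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(
                SlideRecord(
                    slide_id=row["slide_id"],
                    path=row["path"],
                    cytology_class=row["cytology_class"],
                    split=row.get("split", "train"),
                    scan_magnification=float(row.get("scan_magnification", 20.0) or 20.0),
                )
            )
    return records
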