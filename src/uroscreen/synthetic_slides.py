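"""Seed-reproducible synthetic LBC-like slides with paired annotations.

A slide is a bright background sprinkled with small-nucleus cells, debris
and crystals; neoplastic slides additionally carry a few sparse clusters of
enlarged, darker, more eccentric nuclei.  Each neoplastic cell gets exactly
one enclosing annotation polygon.  The truth mask records nuclei and
debris/crystals (the objects dark enough to survive Otsu), not the pale
cytoplasm halos.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import polygon as draw_polygon

from .annotation import (
    AnnotationLabel,
    AnnotationPolygon,
    AnnotationSet,
    SlideRecord,
)
from .errors import InvalidConfigError
from .slide_io import write_manifest

__all__ = [
    "SyntheticSlideConfig",
    "SyntheticSlideBundle",
    "generate_slide",
    "generate_cohort",
    "write_cohort",
    "synthetic_manifest",
]

# round-robin class assignment for synthetic manifests
_NEGATIVE_CLASSES = ["I", "II"]
_NEOPLASTIC_CLASSES = ["III", "IV", "V"]
_LABEL_FOR_CLASS = {
    "III": AnnotationLabel.ATYPICAL,
    "IV": AnnotationLabel.LGUC,
    "V": AnnotationLabel.HGUC,
}


@dataclass(frozen=True)
class SyntheticSlideConfig:
    """Generative knobs for one synthetic slide.

    The neoplastic nucleus radius range must sit strictly above the normal
    range so the two cell populations are separable by size; darkening adds
    the hyperchromatism cue.
    """

    width: int = 4096
    height: int = 4096
    n_normal_cells: int = 400
    n_neoplastic_clusters: int = 0
    cells_per_cluster: tuple[int, int] = (4, 8)
    normal_nucleus_radius: tuple[float, float] = (8.0, 14.0)
    neoplastic_nucleus_radius: tuple[float, float] = (22.0, 34.0)
    neoplastic_chromatin_darkening: int = 60
    n_debris: int = 30
    n_crystals: int = 10
    background_intensity: int = 235
    seed: int = 0

    def validate(self) -> None:
        if min(self.width, self.height) < 2 * max(self.neoplastic_nucleus_radius):
            raise InvalidConfigError(
                "slide dimensions must be at least twice the largest nucleus radius"
            )
        for name in (
            "n_normal_cells",
            "n_neoplastic_clusters",
            "n_debris",
            "n_crystals",
        ):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")
        if self.neoplastic_nucleus_radius[0] <= self.normal_nucleus_radius[1]:
            raise InvalidConfigError(
                "neoplastic nucleus radius range must lie strictly above the normal range"
            )
        if not 0 <= self.background_intensity <= 255:
            raise InvalidConfigError("background_intensity must be in [0, 255]")


@dataclass
class SyntheticSlideBundle:
    """One generated slide with its annotations, record and truth mask."""

    image: np.ndarray  # uint8 (H, W, 3)
    annotations: AnnotationSet
    record: SlideRecord
    truth_mask: np.ndarray  # bool (H, W): nuclei + debris + crystals


def _paint_ellipse(img, mask, cy, cx, ry, rx, angle, color):
    rr, cc = draw_ellipse(cy, cx, ry, rx, shape=img.shape[:2], rotation=angle)
    img[rr, cc] = color
    if mask is not None:
        mask[rr, cc] = True
    return rr, cc


def _draw_cell(img, mask, rng, cy, cx, nucleus_r, darkening=0, eccentric=False, nc_halo=2.4):
    """Draw cytoplasm halo then nucleus; returns the nucleus outline polygon."""
    angle = rng.uniform(0, math.pi)
    if eccentric:
        ry = nucleus_r * rng.uniform(1.05, 1.3)
        rx = nucleus_r * rng.uniform(0.7, 0.95)
    else:
        ry = nucleus_r * rng.uniform(0.9, 1.1)
        rx = nucleus_r * rng.uniform(0.85, 1.05)
    # pale bluish cytoplasm (not in the truth mask)
    cyt_r = max(ry, rx) * nc_halo
    cyt_color = np.array([205, 215, 228]) + rng.integers(-8, 9, size=3)
    _paint_ellipse(img, None, cy, cx, cyt_r, cyt_r, 0.0, np.clip(cyt_color, 0, 255))
    # chromatin-dense nucleus
    base = np.array([95, 70, 135], dtype=float) - darkening
    base += rng.integers(-10, 11, size=3)
    _paint_ellipse(img, mask, cy, cx, ry, rx, angle, np.clip(base, 0, 255))
    # enclosing polygon: 12-gon around the nucleus, 30% margin
    t = np.linspace(0, 2 * math.pi, 12, endpoint=False)
    ey, ex = 1.3 * ry * np.sin(t), 1.3 * rx * np.cos(t)
    ca, sa = math.cos(angle), math.sin(angle)
    # skimage's ellipse rotation convention: rotate (row, col) offsets
    py = cy + ey * ca + ex * sa
    px = cx - ey * sa + ex * ca
    return np.stack([px, py], axis=1)  # (x, y) vertices


def _draw_shard(img, mask, rng, cy, cx, size, color):
    n = rng.integers(4, 8)
    t = np.sort(rng.uniform(0, 2 * math.pi, size=n))
    r = rng.uniform(0.3 * size, size, size=n)
    ys, xs = cy + r * np.sin(t), cx + r * np.cos(t)
    rr, cc = draw_polygon(ys, xs, shape=img.shape[:2])
    img[rr, cc] = color
    mask[rr, cc] = True


def generate_slide(config: SyntheticSlideConfig) -> SyntheticSlideBundle:
    """Render one synthetic slide deterministically from ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    H, W = config.height, config.width
    bg = config.background_intensity
    img = np.full((H, W, 3), bg, dtype=np.uint8)
    # faint background texture
    noise = rng.normal(0, 2.0, size=(H, W, 1))
    img = np.clip(img.astype(float) + noise, 0, 255)
    truth = np.zeros((H, W), dtype=bool)

    for _ in range(config.n_normal_cells):
        r = rng.uniform(*config.normal_nucleus_radius)
        cy, cx = rng.uniform(0, H), rng.uniform(0, W)
        _draw_cell(img, truth, rng, cy, cx, r, darkening=0, eccentric=False, nc_halo=2.6)

    polygons: list[AnnotationPolygon] = []
    margin = 3 * config.neoplastic_nucleus_radius[1]
    for _ in range(config.n_neoplastic_clusters):
        ccy = rng.uniform(margin, H - margin)
        ccx = rng.uniform(margin, W - margin)
        n_cells = int(rng.integers(config.cells_per_cluster[0], config.cells_per_cluster[1] + 1))
        spread = 1.6 * config.neoplastic_nucleus_radius[1]
        for _ in range(n_cells):
            r = rng.uniform(*config.neoplastic_nucleus_radius)
            cy = np.clip(ccy + rng.normal(0, spread), r, H - r)
            cx = np.clip(ccx + rng.normal(0, spread), r, W - r)
            verts = _draw_cell(
                img,
                truth,
                rng,
                cy,
                cx,
                r,
                darkening=config.neoplastic_chromatin_darkening,
                eccentric=True,
                nc_halo=1.4,  # high N/C ratio: thin cytoplasm rim
            )
            polygons.append(AnnotationPolygon(label=AnnotationLabel.HGUC, vertices=verts))

    for _ in range(config.n_debris):
        size = rng.uniform(3, 9)
        color = rng.integers(60, 130, size=3)
        _draw_shard(img, truth, rng, rng.uniform(0, H), rng.uniform(0, W), size, color)
    for _ in range(config.n_crystals):
        size = rng.uniform(6, 16)
        shade = rng.integers(120, 180)
        color = np.array([shade, shade, min(255, shade + 20)])
        _draw_shard(img, truth, rng, rng.uniform(0, H), rng.uniform(0, W), size, color)

    # soften edges so nuclei read as anti-aliased blobs, not binary stamps
    img = gaussian_filter(img, sigma=(0.6, 0.6, 0))
    img = np.clip(img, 0, 255).round().astype(np.uint8)

    neoplastic = config.n_neoplastic_clusters > 0
    record = SlideRecord(
        slide_id=f"synthetic-{config.seed}",
        path="",
        cytology_class="V" if neoplastic else "I",
        split="train",
    )
    annset = AnnotationSet(slide_id=record.slide_id, polygons=polygons)
    return SyntheticSlideBundle(image=img, annotations=annset, record=record, truth_mask=truth)


def generate_cohort(
    n_negative: int,
    n_neoplastic: int,
    base_config: SyntheticSlideConfig | None = None,
    seed: int = 0,
    split: str = "train",
) -> list[SyntheticSlideBundle]:
    """Generate ``n_negative`` then ``n_neoplastic`` slides.

    Per-slide seed = cohort seed + slide index (stable contract).  Cytology
    classes are assigned round-robin: negatives I/II, neoplastics III/IV/V;
    annotation labels follow the class so each grade appears.
    """
    if n_negative < 0 or n_neoplastic < 0:
        raise InvalidConfigError("cohort counts must be >= 0")
    base = base_config or SyntheticSlideConfig()
    bundles = []
    for i in range(n_negative + n_neoplastic):
        neo = i >= n_negative
        cfg = replace(
            base,
            seed=seed + i,
            n_neoplastic_clusters=base.n_neoplastic_clusters if neo and base.n_neoplastic_clusters > 0 else (3 if neo else 0),
        )
        bundle = generate_slide(cfg)
        if neo:
            j = i - n_negative
            cls = _NEOPLASTIC_CLASSES[j % len(_NEOPLASTIC_CLASSES)]
            label = _LABEL_FOR_CLASS[cls]
            for poly in bundle.annotations.polygons:
                poly.label = label
        else:
            cls = _NEGATIVE_CLASSES[i % len(_NEGATIVE_CLASSES)]
        sid = f"{'neo' if neo else 'neg'}-{i:04d}"
        bundle.record = SlideRecord(
            slide_id=sid, path="", cytology_class=cls, split=split
        )
        bundle.annotations.slide_id = sid
        bundles.append(bundle)
    return bundles


def write_cohort(bundles: list[SyntheticSlideBundle], out_dir: str | Path) -> Path:
    """Write slides/*.tiff, annotations/*.geojson and manifest.csv."""
    from .annotation import write_annotations

    out = Path(out_dir)
    (out / "slides").mkdir(parents=True, exist_ok=True)
    (out / "annotations").mkdir(parents=True, exist_ok=True)
    records = []
    for bundle in bundles:
        sid = bundle.record.slide_id
        slide_path = out / "slides" / f"{sid}.tiff"
        tifffile.imwrite(str(slide_path), bundle.image)
        bundle.record.path = str(slide_path)
        if bundle.record.is_neoplastic:
            write_annotations(bundle.annotations, out / "annotations" / f"{sid}.geojson")
        records.append(bundle.record)
    manifest = out / "manifest.csv"
    write_manifest(records, manifest)
    return manifest


def synthetic_manifest(
    n_negative: int, n_neoplastic: int, seed: int = 0, split: str = "test"
) -> list[SlideRecord]:
    """Lightweight records-only manifest (no images) for split-design work."""
    records = []
    for i in range(n_negative):
        records.append(
            SlideRecord(
                slide_id=f"neg-{i:04d}",
                path="",
                cytology_class=_NEGATIVE_CLASSES[i % 2],
                split=split,
            )
        )
    for j in range(n_neoplastic):
        records.append(
            SlideRecord(
                slide_id=f"neo-{j:04d}",
                path="",
                cytology_class=_NEOPLASTIC_CLASSES[j % 3],
                split=split,
            )
        )
    return records
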