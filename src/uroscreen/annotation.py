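"""Cytology class system, annotation labels, polygon sets and the
tile-positivity rule.

Coordinates are level-0 pixel units (x right, y down), 0-based.  Tile
footprints are half-open rectangles ``[x, x+w) x [y, y+h)``; a tile is
positive when at least one annotated cell polygon intersects it with
positive area.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import Polygon, box

from .errors import SchemaError

__all__ = [
    "CytologyClass",
    "AnnotationLabel",
    "SlideRecord",
    "AnnotationPolygon",
    "AnnotationSet",
    "binary_label",
    "group_to_neoplastic",
    "tile_is_positive",
    "read_annotations",
    "write_annotations",
]


class CytologyClass(Enum):
    """Five-tier cytodiagnostic grading; I-II negative, III-V neoplastic."""

    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    V = "V"

    @classmethod
    def parse(cls, token: str) -> "CytologyClass":
        try:
            return cls(str(token).strip())
        except ValueError:
            raise SchemaError(f"unknown cytology class {token!r}; expected I-V") from None


class AnnotationLabel(Enum):
    """Per-cell annotation labels; all three group to neoplastic."""

    ATYPICAL = "atypical_cell"
    LGUC = "lguc_cell"
    HGUC = "hguc_cell"

    @classmethod
    def parse(cls, token: str) -> "AnnotationLabel":
        try:
            return cls(str(token))
        except ValueError:
            raise SchemaError(
                f"unknown annotation label {token!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None


NEGATIVE = "negative"
NEOPLASTIC = "neoplastic"

_NEGATIVE_CLASSES = frozenset({CytologyClass.I, CytologyClass.II})


def binary_label(cls: CytologyClass | str) -> str:
    """Map a cytology class to the binary slide label.

    Classes I and II map to ``"negative"``; III, IV and V to ``"neoplastic"``.
    """
    if not isinstance(cls, CytologyClass):
        cls = CytologyClass.parse(cls)
    return NEGATIVE if cls in _NEGATIVE_CLASSES else NEOPLASTIC


def group_to_neoplastic(label: AnnotationLabel | str) -> bool:
    """All three per-cell annotation labels count as neoplastic."""
    if not isinstance(label, AnnotationLabel):
        label = AnnotationLabel.parse(label)
    return True


@dataclass
class SlideRecord:
    """One slide's identity, diagnosis, derived binary label and split."""

    slide_id: str
    path: str
    cytology_class: CytologyClass
    split: str = "train"
    scan_magnification: float = 20.0

    def __post_init__(self):
        if not isinstance(self.cytology_class, CytologyClass):
            self.cytology_class = CytologyClass.parse(self.cytology_class)

    @property
    def label(self) -> str:
        return binary_label(self.cytology_class)

    @property
    def is_neoplastic(self) -> bool:
        return self.label == NEOPLASTIC


@dataclass
class AnnotationPolygon:
    """A closed polygonal outline around one annotated cell."""

    label: AnnotationLabel
    vertices: np.ndarray  # (n, 2) float array of (x, y) level-0 coordinates

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise SchemaError("polygon vertices must be an (n, 2) array")
        if len(self.vertices) < 3:
            raise SchemaError("polygon needs at least 3 vertices")
        if not isinstance(self.label, AnnotationLabel):
            self.label = AnnotationLabel.parse(self.label)

    def to_shapely(self) -> Polygon:
        return Polygon(self.vertices)


@dataclass
class AnnotationSet:
    """All annotation polygons of one slide (may be empty)."""

    slide_id: str
    polygons: list[AnnotationPolygon] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.polygons)

    def __iter__(self):
        return iter(self.polygons)


def tile_is_positive(
    anchor: tuple[float, float],
    tile_span: tuple[float, float],
    annotations: AnnotationSet | Iterable[AnnotationPolygon],
) -> bool:
    """True iff any annotation polygon intersects the half-open tile
    rectangle with positive area.

    Degenerate (zero-area or self-intersecting) polygons are skipped with a
    warning.  Boundary-touching polygons do not count: the intersection must
    have positive area, which matches the half-open footprint convention.
    """
    x, y = anchor
    w, h = tile_span
    rect = box(x, y, x + w, y + h)
    polys = annotations.polygons if isinstance(annotations, AnnotationSet) else annotations
    for poly in polys:
        shp = poly.to_shapely()
        if not shp.is_valid or shp.area <= 0:
            warnings.warn(
                f"skipping degenerate annotation polygon (label={poly.label.value})",
                stacklevel=2,
            )
            continue
        if shp.intersection(rect).area > 0:
            return True
    return False


# ---------------------------------------------------------------------------
# GeoJSON dialect
#
# One FeatureCollection per slide.  Geometry is a standard GeoJSON Polygon
# whose coordinates are level-0 pixel units (NOT lon/lat); each Feature
# carries its cell label in properties["label"].


def write_annotations(annset: AnnotationSet, path: str | Path) -> None:
    features = []
    for poly in annset.polygons:
        ring = [[float(x), float(y)] for x, y in poly.vertices]
        if ring[0] != ring[-1]:
            ring = ring + [ring[0]]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {"label": poly.label.value},
            }
        )
    doc = {
        "type": "FeatureCollection",
        "properties": {"slide_id": annset.slide_id, "coordinate_units": "pixel"},
        "features": features,
    }
    Path(path).write_text(json.dumps(doc))


def read_annotations(path: str | Path, slide_id: str | None = None) -> AnnotationSet:
    """Read a per-slide GeoJSON annotation file.

    Raises :class:`SchemaError` on unknown labels or non-polygon geometry and
    ``json.JSONDecodeError`` on malformed JSON.
    """
    doc = json.loads(Path(path).read_text())
    if doc.get("type") != "FeatureCollection":
        raise SchemaError("expected a GeoJSON FeatureCollection")
    sid = slide_id or doc.get("properties", {}).get("slide_id") or Path(path).stem
    polygons = []
    for feat in doc.get("features", []):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Polygon":
            raise SchemaError(f"unsupported geometry type {geom.get('type')!r}")
        props = feat.get("properties") or {}
        label = AnnotationLabel.parse(props.get("label"))
        ring = geom["coordinates"][0]
        verts = np.asarray(ring, dtype=float)
        # drop the closing vertex if the ring repeats it
        if len(verts) > 3 and np.array_equal(verts[0], verts[-1]):
            verts = verts[:-1]
        polygons.append(AnnotationPolygon(label=label, vertices=verts))
    return AnnotationSet(slide_id=sid, polygons=polygons)


def load_annotations_dir(
    directory: str | Path, records: Sequence[SlideRecord]
) -> dict[str, AnnotationSet]:
    """Load ``<slide_id>.geojson`` for each record; missing file -> empty set."""
    directory = Path(directory)
    out: dict[str, AnnotationSet] = {}
    for rec in records:
        path = directory / f"{rec.slide_id}.geojson"
        if path.exists():
            out[rec.slide_id] = read_annotations(path, slide_id=rec.slide_id)
        else:
            out[rec.slide_id] = AnnotationSet(slide_id=rec.slide_id)
    return out
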