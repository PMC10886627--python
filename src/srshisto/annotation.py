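"""Tissue-class vocabulary and polygon annotations.

Annotations are closed polygons in image pixel coordinates (0-based,
origin top-left, y increasing downward — the QuPath image convention),
each labeled with one of six tissue classes.  They are read from and
written to GeoJSON FeatureCollections in the dialect QuPath exports:
each feature carries ``properties.classification.name``; a plain
``properties.name`` is accepted as a fallback on read.
"""

from __future__ import annotations

import json
import logging
import uuid
from dataclasses import dataclass, field
from enum import Enum

from shapely.geometry import MultiPolygon, Polygon, box, mapping, shape

log = logging.getLogger(__name__)

__all__ = [
    "TissueClass",
    "Annotation",
    "AnnotationSet",
    "UnknownClassError",
    "AnnotationFormatError",
    "parse_class_name",
    "load_annotations",
    "write_annotations",
    "transfer_annotations",
]


class TissueClass(Enum):
    """The closed six-class vocabulary of the oral-tissue classifier.

    The enum order (tumor, stroma, adipose, muscle, squamous epithelium,
    glandular) is the canonical internal class order used for class
    distributions, confusion matrices and model outputs.
    """

    TUMOR = "tumor"
    STROMA = "stroma"
    ADIPOSE = "adipose"
    MUSCLE = "muscle"
    SQUAMOUS_EPITHELIUM = "squamous_epithelium"
    GLANDULAR = "glandular"

    @property
    def index(self) -> int:
        return list(TissueClass).index(self)


N_CLASSES = len(TissueClass)

#: Display names as a pathologist (or QuPath) would write them.
DISPLAY_NAMES: dict[TissueClass, str] = {
    TissueClass.TUMOR: "Tumor",
    TissueClass.STROMA: "Stroma",
    TissueClass.ADIPOSE: "Adipose tissue",
    TissueClass.MUSCLE: "Muscle",
    TissueClass.SQUAMOUS_EPITHELIUM: "Squamous epithelium",
    TissueClass.GLANDULAR: "Glandular tissue",
}

# Alias table for reading free-text class names; keys are normalized
# (lower-case, spaces/hyphens collapsed to underscores).
_ALIASES: dict[str, TissueClass] = {}
for _tc in TissueClass:
    _ALIASES[_tc.value] = _tc
_ALIASES.update(
    {
        "tumour": TissueClass.TUMOR,
        "adipose_tissue": TissueClass.ADIPOSE,
        "fat": TissueClass.ADIPOSE,
        "squamous": TissueClass.SQUAMOUS_EPITHELIUM,
        "epithelium": TissueClass.SQUAMOUS_EPITHELIUM,
        "glandular_tissue": TissueClass.GLANDULAR,
        "gland": TissueClass.GLANDULAR,
    }
)


class UnknownClassError(ValueError):
    """A class name outside the six-class vocabulary was encountered."""


class AnnotationFormatError(ValueError):
    """The GeoJSON input is malformed or carries unsupported geometry."""


def parse_class_name(name: str) -> TissueClass:
    """Map a free-text class name onto the vocabulary.

    Matching is case-insensitive and tolerant of spaces/hyphens
    (``"Squamous epithelium"`` → ``SQUAMOUS_EPITHELIUM``).  Raises
    :class:`UnknownClassError` for anything outside the alias table.
    """
    key = name.strip().lower().replace("-", "_").replace(" ", "_")
    try:
        return _ALIASES[key]
    except KeyError:
        raise UnknownClassError(
            f"unknown tissue class {name!r}; expected one of "
            f"{sorted({t.value for t in TissueClass})}"
        ) from None


@dataclass
class Annotation:
    """One labeled polygon (outer ring plus optional holes)."""

    polygon: Polygon
    tissue_class: TissueClass
    annotation_id: str = field(default_factory=lambda: uuid.uuid4().hex[:12])

    def __post_init__(self) -> None:
        if not isinstance(self.polygon, Polygon):
            raise AnnotationFormatError(
                f"annotation geometry must be a Polygon, got {type(self.polygon).__name__}"
            )
        if self.polygon.area <= 0:
            raise AnnotationFormatError("annotation polygon has zero area")

    @property
    def area(self) -> float:
        return self.polygon.area


@dataclass
class AnnotationSet:
    """All annotations of one specimen image."""

    image_id: str
    annotations: list[Annotation] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.annotations)

    def __iter__(self):
        return iter(self.annotations)

    def by_class(self, tissue_class: TissueClass) -> list[Annotation]:
        return [a for a in self.annotations if a.tissue_class == tissue_class]

    @property
    def classes(self) -> set[TissueClass]:
        return {a.tissue_class for a in self.annotations}


def _feature_class_name(feature: dict) -> str | None:
    props = feature.get("properties") or {}
    cls = props.get("classification")
    if isinstance(cls, dict) and "name" in cls:
        return cls["name"]
    if isinstance(cls, str):
        return cls
    return props.get("name")


def _clip_to_bounds(geom, image_bounds: tuple[int, int] | None):
    """Clip geometry to the image rectangle (height, width) if given."""
    if image_bounds is None:
        return geom
    h, w = image_bounds
    clipped = geom.intersection(box(0.0, 0.0, float(w), float(h)))
    return clipped


def _iter_polygon_parts(geom):
    if isinstance(geom, Polygon):
        if not geom.is_empty:
            yield geom
    elif isinstance(geom, MultiPolygon):
        for part in geom.geoms:
            if not part.is_empty:
                yield part
    elif geom.geom_type == "GeometryCollection":
        for part in geom.geoms:
            yield from _iter_polygon_parts(part)
    else:
        raise AnnotationFormatError(
            f"unsupported geometry type {geom.geom_type!r}; expected Polygon or MultiPolygon"
        )


def load_annotations(
    geojson_path,
    image_id: str | None = None,
    image_bounds: tuple[int, int] | None = None,
    strict: bool = True,
) -> AnnotationSet:
    """Read a QuPath-style GeoJSON FeatureCollection.

    Parameters
    ----------
    geojson_path
        Path to the GeoJSON file.
    image_id
        Id recorded on the returned set; defaults to the file stem.
    image_bounds
        ``(height, width)`` of the source image; polygons are clipped to
        this rectangle so coordinates never exceed the image.
    strict
        If True (default) an unknown class name raises
        :class:`UnknownClassError`; if False the feature is skipped with
        a logged warning.

    Multi-polygon features yield one :class:`Annotation` per part, all
    sharing the feature's class.
    """
    geojson_path = str(geojson_path)
    with open(geojson_path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise AnnotationFormatError(f"malformed GeoJSON in {geojson_path}: {exc}") from exc
    if doc.get("type") != "FeatureCollection":
        raise AnnotationFormatError(
            f"{geojson_path}: expected a FeatureCollection, got {doc.get('type')!r}"
        )
    if image_id is None:
        import os

        image_id = os.path.splitext(os.path.basename(geojson_path))[0]

    annotations: list[Annotation] = []
    for i, feature in enumerate(doc.get("features", [])):
        name = _feature_class_name(feature)
        if name is None:
            raise AnnotationFormatError(f"feature {i} carries no classification name")
        try:
            tissue_class = parse_class_name(name)
        except UnknownClassError:
            if strict:
                raise
            log.warning("skipping feature %d with unknown class %r", i, name)
            continue
        geom = shape(feature["geometry"])
        geom = _clip_to_bounds(geom, image_bounds)
        feat_id = feature.get("id")
        for j, part in enumerate(_iter_polygon_parts(geom)):
            aid = f"{feat_id}-{j}" if feat_id else uuid.uuid4().hex[:12]
            annotations.append(Annotation(part, tissue_class, aid))
    return AnnotationSet(image_id=image_id, annotations=annotations)


def write_annotations(aset: AnnotationSet, path) -> None:
    """Write an AnnotationSet as a QuPath-dialect GeoJSON FeatureCollection."""
    features = []
    for ann in aset.annotations:
        features.append(
            {
                "type": "Feature",
                "id": ann.annotation_id,
                "geometry": mapping(ann.polygon),
                "properties": {
                    "objectType": "annotation",
                    "classification": {"name": DISPLAY_NAMES[ann.tissue_class]},
                },
            }
        )
    doc = {"type": "FeatureCollection", "features": features}
    with open(str(path), "w") as fh:
        json.dump(doc, fh)


def transfer_annotations(
    src: AnnotationSet,
    target_image_id: str,
    source_shape: tuple[int, int] | None = None,
    target_shape: tuple[int, int] | None = None,
) -> AnnotationSet:
    """Transfer annotations between pixel-aligned modalities.

    The virtual-H&E render is generated pixel-for-pixel from the raw
    two-channel image, so annotations drawn on one apply to the other by
    an identity coordinate map; only ``image_id`` changes.  If both
    shapes are supplied they must match.
    """
    if source_shape is not None and target_shape is not None and source_shape != target_shape:
        raise ValueError(
            f"cannot transfer annotations between images of different size: "
            f"{source_shape} vs {target_shape}"
        )
    return AnnotationSet(
        image_id=target_image_id,
        annotations=[
            Annotation(a.polygon, a.tissue_class, a.annotation_id) for a in src.annotations
        ],
    )
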