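"""Annotation-driven tiling of specimen images into labeled patches.

Images are divided into a non-overlapping grid of square tiles (default
250x250 px, stride = tile size, anchored at the top-left corner;
incomplete edge tiles are dropped).  A tile receives a class label only
if at least 99% of its area lies inside the annotated regions of a
single class; tiles below the threshold for every class — and tiles
where two classes both pass, which would carry contradictory label
information — are excluded from the dataset.

Coverage semantics: a pixel belongs to a class iff its center
``(x + 0.5, y + 0.5)`` lies inside the union of that class's polygons;
a tile's coverage for a class is the fraction of its pixels belonging to
the class.  Tiles are half-open rectangles ``[x, x+size) x [y, y+size)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.ops import unary_union

from .annotation import AnnotationSet, TissueClass

__all__ = [
    "TileRecord",
    "TileDataset",
    "tile_grid",
    "class_masks",
    "coverage_by_class",
    "label_tile",
    "build_dataset",
    "extract_tile_pixels",
]

DEFAULT_TILE_SIZE = 250
DEFAULT_COVERAGE_THRESHOLD = 0.99


@dataclass(frozen=True)
class TileRecord:
    """One retained, labeled tile with its provenance."""

    image_id: str
    x: int  # column of the top-left pixel
    y: int  # row of the top-left pixel
    size: int
    label: TissueClass
    coverage: float

    @property
    def origin_xy(self) -> tuple[int, int]:
        return (self.x, self.y)


@dataclass
class TileDataset:
    """All retained tiles of a cohort plus per-image and per-class tallies."""

    tiles: list[TileRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.tiles)

    def __iter__(self):
        return iter(self.tiles)

    @property
    def class_counts(self) -> dict[TissueClass, int]:
        counts = {tc: 0 for tc in TissueClass}
        for t in self.tiles:
            counts[t.label] += 1
        return counts

    @property
    def image_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.tiles:
            seen.setdefault(t.image_id, None)
        return list(seen)

    def tiles_for_images(self, image_ids) -> list[TileRecord]:
        wanted = set(image_ids)
        return [t for t in self.tiles if t.image_id in wanted]

    def subset(self, image_ids) -> "TileDataset":
        return TileDataset(self.tiles_for_images(image_ids))

    def to_manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "image_id": t.image_id,
                    "x": t.x,
                    "y": t.y,
                    "size": t.size,
                    "label": t.label.value,
                    "coverage": t.coverage,
                }
                for t in self.tiles
            ],
            columns=["image_id", "x", "y", "size", "label", "coverage"],
        )

    def write_manifest(self, path) -> None:
        self.to_manifest().to_csv(str(path), index=False)

    @classmethod
    def from_manifest(cls, path_or_df) -> "TileDataset":
        df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(str(path_or_df))
        tiles = [
            TileRecord(
                image_id=str(r.image_id),
                x=int(r.x),
                y=int(r.y),
                size=int(r.size),
                label=TissueClass(r.label),
                coverage=float(r.coverage),
            )
            for r in df.itertuples()
        ]
        return cls(tiles)


def tile_grid(image_height: int, image_width: int, tile_size: int, stride: int | None = None):
    """Top-left origins ``(x, y)`` of the grid tiles fully inside the image.

    Stride defaults to the tile size (a partition); tiles that would
    extend past the image edge are dropped, so an image smaller than one
    tile yields an empty list.
    """
    if image_height <= 0 or image_width <= 0 or tile_size <= 0:
        raise ValueError("image dimensions and tile size must be positive")
    stride = stride or tile_size
    origins = []
    for y in range(0, image_height - tile_size + 1, stride):
        for x in range(0, image_width - tile_size + 1, stride):
            origins.append((x, y))
    return origins


def class_masks(aset: AnnotationSet, image_shape: tuple[int, int]) -> dict[TissueClass, np.ndarray]:
    """Boolean pixel-membership masks, one per class present in ``aset``.

    A pixel is set iff its center lies inside the union of the class's
    polygons.  Computed once per image; tile coverages are then cheap
    sub-grid sums.
    """
    h, w = image_shape
    xs = np.arange(w, dtype=np.float64) + 0.5
    ys = np.arange(h, dtype=np.float64) + 0.5
    gx, gy = np.meshgrid(xs, ys)
    flat_x, flat_y = gx.ravel(), gy.ravel()
    masks: dict[TissueClass, np.ndarray] = {}
    for tc in TissueClass:
        polys = [a.polygon for a in aset.by_class(tc)]
        if not polys:
            continue
        geom = unary_union(polys)
        shapely.prepare(geom)
        inside = shapely.contains_xy(geom, flat_x, flat_y)
        masks[tc] = inside.reshape(h, w)
    return masks


def coverage_by_class(
    origin_xy: tuple[int, int],
    tile_size: int,
    aset: AnnotationSet,
    image_shape: tuple[int, int],
    masks: dict[TissueClass, np.ndarray] | None = None,
) -> dict[TissueClass, float]:
    """Per-class covered-pixel fraction of one tile.

    Fractions need not sum to 1 (unannotated pixels) and can exceed 1 in
    total where annotations of different classes overlap.
    """
    x, y = origin_xy
    h, w = image_shape
    if x < 0 or y < 0 or x + tile_size > w or y + tile_size > h:
        raise ValueError(f"tile at {origin_xy} size {tile_size} exceeds image {image_shape}")
    if masks is None:
        masks = class_masks(aset, image_shape)
    n_pix = tile_size * tile_size
    out: dict[TissueClass, float] = {}
    for tc in TissueClass:
        m = masks.get(tc)
        if m is None:
            out[tc] = 0.0
        else:
            out[tc] = float(m[y : y + tile_size, x : x + tile_size].sum()) / n_pix
    return out


def label_tile(
    coverage: dict[TissueClass, float],
    threshold: float = DEFAULT_COVERAGE_THRESHOLD,
) -> tuple[TissueClass, float] | None:
    """Assign a label from per-class coverages, or exclude the tile.

    A tile is labeled with class c iff coverage(c) >= threshold.  If two
    classes both pass (possible only with overlapping annotations), the
    tile carries contradictory information and is excluded; below the
    threshold for every class it is excluded as insufficiently labeled.
    Returns ``(label, coverage)`` or ``None``.
    """
    passing = [(tc, cov) for tc, cov in coverage.items() if cov >= threshold]
    if len(passing) != 1:
        return None
    return passing[0]


def build_dataset(
    images,
    annotation_sets,
    tile_size: int = DEFAULT_TILE_SIZE,
    threshold: float = DEFAULT_COVERAGE_THRESHOLD,
    stride: int | None = None,
) -> TileDataset:
    """Tile every image and keep the tiles passing the coverage rule.

    ``images`` may be SRSImage objects or ``(image_id, (height, width))``
    pairs; each must have a matching AnnotationSet by image_id.  The
    result is deterministic and independent of annotation order.
    """
    by_id = {a.image_id: a for a in annotation_sets}
    tiles: list[TileRecord] = []
    for img in images:
        if hasattr(img, "image_id"):
            image_id, shape = img.image_id, img.shape
        else:
            image_id, shape = img
        if image_id not in by_id:
            raise KeyError(f"no AnnotationSet for image {image_id!r}")
        aset = by_id[image_id]
        masks = class_masks(aset, shape)
        for origin in tile_grid(shape[0], shape[1], tile_size, stride):
            cov = coverage_by_class(origin, tile_size, aset, shape, masks=masks)
            labeled = label_tile(cov, threshold)
            if labeled is not None:
                tc, c = labeled
                tiles.append(TileRecord(image_id, origin[0], origin[1], tile_size, tc, c))
    return TileDataset(tiles)


def extract_tile_pixels(image, rec: TileRecord) -> np.ndarray:
    """Copy the exact ``size x size x 3`` sub-grid of a tile (no resampling)."""
    if hasattr(image, "planes"):
        arr = image.planes
    elif hasattr(image, "rgb"):
        arr = image.rgb
    else:
        arr = np.asarray(image)
    h, w = arr.shape[:2]
    if rec.x < 0 or rec.y < 0 or rec.x + rec.size > w or rec.y + rec.size > h:
        raise ValueError(f"tile {rec} out of bounds for image of shape {(h, w)}")
    return arr[rec.y : rec.y + rec.size, rec.x : rec.x + rec.size, ...].copy()
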