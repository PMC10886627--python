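"""Synthetic two-channel Raman specimen generator.

No public accession of the real intraoperative imaging data exists, so
this module generates cohorts with the same *statistical structure* the
pipeline expects: per-specimen images carrying a handful of polygonal
tissue regions (perturbed Voronoi cells, so the polygon-coverage tiling
path is genuinely exercised, including partial-coverage exclusions at
region borders), per-class joint (CH2, CH3) intensity signatures that
encode the underlying biochemistry qualitatively — lipid-rich adipose
tissue is CH2-dominant, protein/DNA-rich tumor, epithelium and gland
are CH3-dominant, stroma and muscle sit between with distinct textures
— plus Gaussian speckle noise and a per-image intensity offset
emulating acquisition-gain variation.  Default class mixture follows
the published relative class abundances of the study cohort
(tumor 0.23, stroma 0.23, adipose 0.07, muscle 0.03, squamous 0.39,
glandular 0.05).

Intensity levels are self-consistent placeholders in [0, ~1]; the real
instrument's value range is not publicly specified and no fidelity to
it is claimed.  A ``hard_mode`` flag collapses the tumor-vs-squamous
signature gap to emulate the dominant confusion seen on real data.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import gaussian_filter
from shapely.geometry import MultiPoint, Polygon, box
from shapely.ops import voronoi_diagram
from shapely import affinity

from .annotation import Annotation, AnnotationSet, TissueClass, write_annotations
from .image import SRSImage, write_srs_tiff

__all__ = [
    "ClassSignature",
    "CohortSpec",
    "DEFAULT_MIXTURE",
    "default_signatures",
    "generate_specimen",
    "generate_cohort",
]

TEXTURES = ("vacuoles", "striations", "nuclei_dots", "fibrous", "layered", "ring_glands")

#: Relative tile-class abundances of the study cohort (its Table of
#: class distributions, "total" row).
DEFAULT_MIXTURE: dict[TissueClass, float] = {
    TissueClass.TUMOR: 0.23,
    TissueClass.STROMA: 0.23,
    TissueClass.ADIPOSE: 0.07,
    TissueClass.MUSCLE: 0.03,
    TissueClass.SQUAMOUS_EPITHELIUM: 0.39,
    TissueClass.GLANDULAR: 0.05,
}


@dataclass(frozen=True)
class ClassSignature:
    """Base (CH2, CH3) intensities and texture of one tissue class."""

    tissue_class: TissueClass
    mean_ch2: float
    mean_ch3: float
    texture: str
    texture_scale_px: float = 10.0
    texture_amp: float = 0.06
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.mean_ch2 < 0 or self.mean_ch3 < 0 or self.noise_sd < 0:
            raise ValueError("signature intensities and noise must be nonnegative")
        if self.texture not in TEXTURES:
            raise ValueError(f"unknown texture {self.texture!r}")


_BASE_SIGNATURES: dict[TissueClass, tuple[float, float, str, float]] = {
    # class: (mean_ch2, mean_ch3, texture, texture_scale_px)
    TissueClass.TUMOR: (0.25, 0.85, "nuclei_dots", 6.0),
    TissueClass.STROMA: (0.55, 0.45, "fibrous", 10.0),
    TissueClass.ADIPOSE: (0.90, 0.30, "vacuoles", 12.0),
    TissueClass.MUSCLE: (0.45, 0.65, "striations", 8.0),
    TissueClass.SQUAMOUS_EPITHELIUM: (0.12, 0.55, "layered", 20.0),
    TissueClass.GLANDULAR: (0.70, 0.80, "ring_glands", 16.0),
}


def default_signatures(
    separation_margin: float = 1.0,
    noise_sd: float = 0.05,
    hard_mode: bool = False,
) -> dict[TissueClass, ClassSignature]:
    """Class signatures with a tunable separation margin.

    ``separation_margin`` scales every class's (CH2, CH3) mean pair
    radially about the grand mean, so smaller margins make classes
    harder to tell apart without changing their ordering.  In
    ``hard_mode`` the squamous-epithelium signature is moved next to the
    tumor signature (same texture, near-identical means), emulating the
    morphological similarity of normal mucosa and carcinoma.
    """
    center2 = float(np.mean([v[0] for v in _BASE_SIGNATURES.values()]))
    center3 = float(np.mean([v[1] for v in _BASE_SIGNATURES.values()]))
    sigs: dict[TissueClass, ClassSignature] = {}
    for tc, (m2, m3, tex, scale) in _BASE_SIGNATURES.items():
        sigs[tc] = ClassSignature(
            tissue_class=tc,
            mean_ch2=max(0.02, center2 + separation_margin * (m2 - center2)),
            mean_ch3=max(0.02, center3 + separation_margin * (m3 - center3)),
            texture=tex,
            texture_scale_px=scale,
            noise_sd=noise_sd,
        )
    if hard_mode:
        t = sigs[TissueClass.TUMOR]
        sigs[TissueClass.SQUAMOUS_EPITHELIUM] = replace(
            sigs[TissueClass.SQUAMOUS_EPITHELIUM],
            mean_ch2=t.mean_ch2 + 0.01,
            mean_ch3=t.mean_ch3 - 0.01,
            texture=t.texture,
            texture_scale_px=t.texture_scale_px,
        )
    return sigs


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort."""

    n_images: int = 80
    image_size: tuple[int, int] = (1000, 1000)  # (height, width)
    mixture: dict[TissueClass, float] = field(default_factory=lambda: dict(DEFAULT_MIXTURE))
    regions_range: tuple[int, int] = (1, 4)
    layout: str = "voronoi"  # or "single_full"
    separation_margin: float = 1.0
    hard_mode: bool = False
    noise_sd: float = 0.05
    image_offset_sd: float = 0.02
    background_level: float = 0.02
    region_shrink: float = 0.96
    n_patients: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.mixture.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"class mixture must sum to 1, got {total}")
        if any(self.mixture.get(tc, 0.0) <= 0.0 for tc in TissueClass):
            raise ValueError(
                "every class needs positive mixture weight: the split boundary "
                "condition requires each class to be present in the cohort"
            )
        if self.layout not in ("voronoi", "single_full"):
            raise ValueError(f"unknown layout rule {self.layout!r}")
        if not 1 <= self.regions_range[0] <= self.regions_range[1]:
            raise ValueError("regions_range must be an increasing pair of positive ints")

    @property
    def signatures(self) -> dict[TissueClass, ClassSignature]:
        return default_signatures(self.separation_margin, self.noise_sd, self.hard_mode)

    def image_id(self, index: int) -> str:
        return f"S{index:03d}"

    def patient_id(self, index: int) -> str:
        return f"P{index % self.n_patients + 1}"


def _mixture_array(spec: CohortSpec) -> np.ndarray:
    return np.array([spec.mixture[tc] for tc in TissueClass], dtype=np.float64)


def _forced_class(spec: CohortSpec, image_index: int) -> TissueClass | None:
    """Class guaranteed a region on this image, cycling over the vocabulary.

    Every other image carries one forced region (class ``(i/2) mod 6``)
    so each class appears in roughly ``n_images/12`` specimens — enough
    for the split's every-class-present condition — while keeping the
    forced quota small against the target mixture (rare classes like
    muscle sit at only a few percent of tiles).
    """
    if spec.layout == "single_full" or image_index % 2 == 0:
        idx = (image_index // 2 if spec.layout != "single_full" else image_index)
        return list(TissueClass)[idx % len(TissueClass)]
    return None


def _sampling_mixture(spec: CohortSpec) -> np.ndarray:
    """Mixture for non-forced regions, compensating the forced quota.

    The forced regions claim about ``1 / (12 * mean_regions_per_image)``
    of all regions per class; the freely sampled regions are drawn from
    the target mixture minus that share, keeping the realized tile
    mixture close to the target.
    """
    p = _mixture_array(spec)
    k_mean = 0.5 * (spec.regions_range[0] + spec.regions_range[1])
    forced_share = 1.0 / (12.0 * k_mean)
    q = np.maximum(p - forced_share, 0.004)
    return q / q.sum()


def _voronoi_regions(points: np.ndarray, h: int, w: int, shrink: float) -> list[Polygon]:
    canvas = box(0.0, 0.0, float(w), float(h))
    if len(points) == 1:
        return [affinity.scale(canvas, shrink, shrink)]
    cells = voronoi_diagram(MultiPoint(points.tolist()), envelope=canvas)
    regions: list[Polygon] = []
    for pt in points:
        cell = next(
            (g for g in cells.geoms if g.contains(shapely.points(pt[0], pt[1]))), None
        )
        if cell is None:
            continue
        clipped = cell.intersection(canvas)
        if clipped.is_empty:
            continue
        if clipped.geom_type == "MultiPolygon":
            clipped = max(clipped.geoms, key=lambda g: g.area)
        regions.append(affinity.scale(clipped, shrink, shrink))
    return regions


def _texture_field(kind: str, shape: tuple[int, int], scale: float,
                   rng: np.random.Generator) -> np.ndarray:
    """A roughly zero-mean, unit-amplitude texture pattern."""
    h, w = shape
    if kind == "striations":
        theta = rng.uniform(0.0, np.pi)
        yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
        f = np.sin(2 * np.pi * (xx * np.cos(theta) + yy * np.sin(theta)) / scale)
    elif kind == "layered":
        yy = np.repeat(np.arange(h, dtype=np.float64)[:, None], w, axis=1)
        f = np.sin(2 * np.pi * yy / scale + rng.uniform(0.0, 2 * np.pi))
    elif kind == "fibrous":
        f = gaussian_filter(rng.standard_normal((h, w)), (scale / 8.0, scale / 2.0))
    elif kind in ("vacuoles", "nuclei_dots"):
        f = gaussian_filter(rng.standard_normal((h, w)), scale / 4.0)
        thr = np.quantile(f, 0.75)
        f = np.where(f > thr, 1.0, -0.2) if kind == "nuclei_dots" else np.where(f > thr, -1.0, 0.2)
    elif kind == "ring_glands":
        f = np.zeros((h, w))
        n_rings = max(1, int(h * w / (25.0 * scale * scale)))
        yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
        for _ in range(n_rings):
            cy, cx = rng.uniform(0, h), rng.uniform(0, w)
            r = np.hypot(yy - cy, xx - cx)
            f += np.exp(-(((r - scale) / (scale / 4.0)) ** 2))
    else:  # pragma: no cover - guarded by ClassSignature
        raise ValueError(kind)
    peak = np.abs(f).max()
    if peak > 0:
        f = f / peak
    return f - f.mean()


def _region_mask(poly: Polygon, shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    xs = np.arange(w, dtype=np.float64) + 0.5
    ys = np.arange(h, dtype=np.float64) + 0.5
    gx, gy = np.meshgrid(xs, ys)
    shapely.prepare(poly)
    return shapely.contains_xy(poly, gx.ravel(), gy.ravel()).reshape(h, w)


def generate_specimen(
    spec: CohortSpec, image_index: int, rng: np.random.Generator | None = None
) -> tuple[SRSImage, AnnotationSet]:
    """Generate one specimen image with its polygon annotations.

    Deterministic given ``(spec.seed, image_index)`` unless an explicit
    rng is supplied.  Alternate images carry one region of a forced,
    cycling class (see :func:`_forced_class`); all other regions are
    drawn from the quota-compensated class mixture.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, image_index]))
    h, w = spec.image_size
    sigs = spec.signatures
    classes = list(TissueClass)
    forced = _forced_class(spec, image_index)

    if spec.layout == "single_full":
        regions = [box(0.0, 0.0, float(w), float(h))]
        region_classes = [forced]
    else:
        lo, hi = spec.regions_range
        min_area = 0.02 * h * w
        for _attempt in range(20):
            k = int(rng.integers(lo, hi + 1))
            margin = 0.08
            pts = np.column_stack(
                [
                    rng.uniform(margin * w, (1 - margin) * w, k),
                    rng.uniform(margin * h, (1 - margin) * h, k),
                ]
            )
            regions = _voronoi_regions(pts, h, w, spec.region_shrink)
            if len(regions) == k and all(r.area >= min_area for r in regions):
                break
        q = _sampling_mixture(spec)
        n_sampled = len(regions) - (1 if forced is not None else 0)
        sampled = [classes[int(i)] for i in rng.choice(len(classes), size=n_sampled, p=q)]
        region_classes = ([forced] if forced is not None else []) + sampled

    offset = rng.normal(0.0, spec.image_offset_sd)
    ch2 = np.full((h, w), spec.background_level, dtype=np.float64)
    ch3 = np.full((h, w), spec.background_level, dtype=np.float64)
    annotations = []
    image_id = spec.image_id(image_index)
    for ri, (poly, tc) in enumerate(zip(regions, region_classes)):
        sig = sigs[tc]
        mask = _region_mask(poly, (h, w))
        field_ = sig.texture_amp * _texture_field(
            sig.texture, (h, w), sig.texture_scale_px, rng
        )
        ch2[mask] = sig.mean_ch2 + offset + field_[mask]
        ch3[mask] = sig.mean_ch3 + offset + field_[mask]
        annotations.append(Annotation(poly, tc, f"{image_id}-r{ri}"))
    ch2 += rng.normal(0.0, spec.noise_sd, (h, w))
    ch3 += rng.normal(0.0, spec.noise_sd, (h, w))
    img = SRSImage(
        image_id=image_id,
        ch2=np.clip(ch2, 0.0, None),
        ch3=np.clip(ch3, 0.0, None),
    )
    return img, AnnotationSet(image_id=image_id, annotations=annotations)


def generate_cohort(spec: CohortSpec, outdir=None):
    """Generate the full cohort; optionally persist it to disk.

    Returns ``(specimens, manifest)`` where ``specimens`` is a list of
    ``(SRSImage, AnnotationSet)`` and ``manifest`` a DataFrame with one
    row per image (image_id, patient_id, classes present).  With
    ``outdir`` set, each specimen is written as a two-channel TIFF with
    JSON sidecar plus a GeoJSON annotation file, and the manifest as
    ``manifest.csv`` — exactly the formats the ingest path reads.
    """
    specimens = []
    rows = []
    for i in range(spec.n_images):
        img, aset = generate_specimen(spec, i)
        specimens.append((img, aset))
        rows.append(
            {
                "image_id": img.image_id,
                "patient_id": spec.patient_id(i),
                "height": img.shape[0],
                "width": img.shape[1],
                "n_regions": len(aset),
                "classes": ";".join(sorted({a.tissue_class.value for a in aset})),
            }
        )
    manifest = pd.DataFrame(rows)
    if outdir is not None:
        outdir = str(outdir)
        os.makedirs(outdir, exist_ok=True)
        for img, aset in specimens:
            write_srs_tiff(img, os.path.join(outdir, f"{img.image_id}.tiff"))
            write_annotations(aset, os.path.join(outdir, f"{img.image_id}.geojson"))
        manifest.to_csv(os.path.join(outdir, "manifest.csv"), index=False)
    return specimens, manifest
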