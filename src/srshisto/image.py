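"""Two-channel stimulated-Raman image model and virtual-H&E rendering.

An :class:`SRSImage` holds two aligned intensity grids: the Raman signal
at 2845 cm^-1 (CH2 bonds, lipid-rich structures) and at 2930 cm^-1 (CH3
bonds, protein/DNA-rich structures).  Downstream models consume a
three-channel tensor (CH2, CH3, CH3-CH2); for visual assessment the two
channels are rendered into an RGB image reminiscent of an H&E-stained
slide ("virtual H&E" / SRH) via a documented two-endmember linear color
mixing: protein/DNA signal pulls toward a hematoxylin-like purple, lipid
signal toward an eosin-like pink, and zero signal leaves white
background.  The vendor look-up table used on clinical instruments is
proprietary; this rendering is a fully specified stand-in with the same
qualitative behavior, not a reproduction of the vendor's colors.

Images are stored row-major, origin at top-left, 0-based indices, as
nonnegative float32 grids.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import tifffile
from PIL import Image as PILImage

__all__ = [
    "SRSImage",
    "ThreeChannelImage",
    "SRHImage",
    "LUTParams",
    "ImageFormatError",
    "build_three_channel",
    "normalize_for_model",
    "render_srh",
    "read_srs_tiff",
    "write_srs_tiff",
    "write_png",
]

#: Default pixel size of the line-scanning acquisition, in nanometres.
DEFAULT_PIXEL_SIZE_NM = 467.0
#: Default scan depth below the coverslip, in micrometres (metadata only).
DEFAULT_SCAN_DEPTH_UM = 10.0


class ImageFormatError(ValueError):
    """Raised for files that are not valid two-channel SRS TIFFs."""


def _as_intensity_grid(arr, name: str) -> np.ndarray:
    a = np.asarray(arr, dtype=np.float32)
    if a.ndim != 2:
        raise ValueError(f"{name} must be a 2-D grid, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")
    if a.min() < 0:
        raise ValueError(f"{name} contains negative intensities")
    return a


@dataclass
class SRSImage:
    """Two aligned Raman intensity channels plus acquisition metadata.

    ``ch2`` is the signal at wavenumber 2845 cm^-1 (CH2 bonds), ``ch3``
    at 2930 cm^-1 (CH3 bonds).  Both are nonnegative 2-D float grids of
    identical shape.
    """

    image_id: str
    ch2: np.ndarray
    ch3: np.ndarray
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    scan_depth_um: float = DEFAULT_SCAN_DEPTH_UM

    def __post_init__(self) -> None:
        self.ch2 = _as_intensity_grid(self.ch2, "ch2")
        self.ch3 = _as_intensity_grid(self.ch3, "ch3")
        if self.ch2.shape != self.ch3.shape:
            raise ValueError(
                f"channel dimensions differ: ch2 {self.ch2.shape} vs ch3 {self.ch3.shape}"
            )
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.ch2.shape


@dataclass
class ThreeChannelImage:
    """Model input tensor: planes (CH2, CH3, CH3-CH2).

    The third plane stores the signed spectral difference; adipose tissue
    (lipid-dominant, CH2 > CH3) is negative there, so it is not clipped.
    """

    image_id: str
    planes: np.ndarray  # (H, W, 3), float32

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes, dtype=np.float32)
        if self.planes.ndim != 3 or self.planes.shape[2] != 3:
            raise ValueError(f"planes must have shape (H, W, 3), got {self.planes.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.planes.shape[:2]


@dataclass
class LUTParams:
    """Endmember colors of the two-stain linear mixing render.

    ``intensity_scale`` divides both channels before mixing; intensities
    at or above the scale are treated as fully stained.
    """

    hematoxylin_rgb: tuple[float, float, float] = (0.35, 0.16, 0.55)
    eosin_rgb: tuple[float, float, float] = (0.92, 0.55, 0.65)
    background_rgb: tuple[float, float, float] = (1.0, 1.0, 1.0)
    intensity_scale: float = 1.0

    def to_dict(self) -> dict:
        return {
            "hematoxylin_rgb": list(self.hematoxylin_rgb),
            "eosin_rgb": list(self.eosin_rgb),
            "background_rgb": list(self.background_rgb),
            "intensity_scale": self.intensity_scale,
        }


@dataclass
class SRHImage:
    """Virtual-H&E RGB render of an SRSImage, values in [0, 1]."""

    image_id: str
    rgb: np.ndarray  # (H, W, 3) in [0, 1]
    lut_params: LUTParams = field(default_factory=LUTParams)

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb, dtype=np.float32)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError(f"rgb must have shape (H, W, 3), got {self.rgb.shape}")
        if self.rgb.min() < 0 or self.rgb.max() > 1:
            raise ValueError("rgb values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.rgb.shape[:2]


def build_three_channel(img: SRSImage) -> ThreeChannelImage:
    """Stack (CH2, CH3, CH3-CH2) into the model input tensor.

    The difference plane is computed elementwise in one pass; the input
    image is not modified.
    """
    planes = np.stack([img.ch2, img.ch3, img.ch3 - img.ch2], axis=-1)
    return ThreeChannelImage(image_id=img.image_id, planes=planes)


def normalize_for_model(
    t: ThreeChannelImage,
    strategy: str = "per_channel_minmax",
    fixed_range: tuple[float, float] = (-1.0, 1.0),
) -> ThreeChannelImage:
    """Map each plane into [0, 1].

    ``per_channel_minmax`` rescales each plane by its own min/max within
    this image (removes acquisition-gain differences between specimens);
    ``global_fixed_range`` applies one affine map given by
    ``fixed_range`` to all planes, then clips.  A constant plane maps to
    all zeros.
    """
    planes = t.planes.astype(np.float32)
    if strategy == "per_channel_minmax":
        out = np.empty_like(planes)
        for k in range(3):
            p = planes[..., k]
            lo, hi = float(p.min()), float(p.max())
            if hi > lo:
                out[..., k] = (p - lo) / (hi - lo)
            else:
                out[..., k] = 0.0
    elif strategy == "global_fixed_range":
        lo, hi = fixed_range
        if not hi > lo:
            raise ValueError("fixed_range must be increasing")
        out = np.clip((planes - lo) / (hi - lo), 0.0, 1.0).astype(np.float32)
    else:
        raise ValueError(f"unknown normalization strategy {strategy!r}")
    return ThreeChannelImage(image_id=t.image_id, planes=out)


def srh_pixel(ch2: float, ch3: float, lut: LUTParams) -> tuple[float, float, float]:
    """Render a single pixel; scalar reference form of :func:`render_srh`.

    Total stain weight is ``min((ch2 + ch3) / scale, 1)``; within the
    stained fraction, color interpolates from the eosin endmember to the
    hematoxylin endmember by the CH3 share ``ch3 / (ch2 + ch3)``.  Zero
    signal renders the background color.
    """
    s = lut.intensity_scale
    total = ch2 + ch3
    if total <= 0.0:
        return lut.background_rgb
    t = min(total / s, 1.0)
    f = ch3 / total
    out = []
    for bg, he, eo in zip(lut.background_rgb, lut.hematoxylin_rgb, lut.eosin_rgb):
        stain = f * he + (1.0 - f) * eo
        out.append((1.0 - t) * bg + t * stain)
    return tuple(out)


def render_srh(img: SRSImage, lut_params: LUTParams | None = None) -> SRHImage:
    """Render a virtual-H&E RGB image from the two Raman channels.

    Deterministic and pure: the same image and parameters always produce
    the same render.  Increasing CH3 at fixed CH2 monotonically pulls the
    pixel toward the hematoxylin (purple) endmember, matching how
    nucleus-dense tissue darkens in a real H&E slide.
    """
    lut = lut_params or LUTParams()
    ch2 = img.ch2.astype(np.float64)
    ch3 = img.ch3.astype(np.float64)
    total = ch2 + ch3
    t = np.minimum(total / lut.intensity_scale, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(total > 0, ch3 / np.where(total > 0, total, 1.0), 0.0)
    rgb = np.empty(img.shape + (3,), dtype=np.float64)
    for k, (bg, he, eo) in enumerate(
        zip(lut.background_rgb, lut.hematoxylin_rgb, lut.eosin_rgb)
    ):
        stain = f * he + (1.0 - f) * eo
        chan = (1.0 - t) * bg + t * stain
        rgb[..., k] = np.where(total > 0, chan, bg)
    return SRHImage(image_id=img.image_id, rgb=np.clip(rgb, 0.0, 1.0), lut_params=lut)


# ---------------------------------------------------------------------------
# I/O: two-channel TIFF with a JSON metadata sidecar, PNG for renders.

def _sidecar_path(tiff_path: str) -> str:
    return os.path.splitext(tiff_path)[0] + ".json"


def write_srs_tiff(img: SRSImage, path) -> None:
    """Write channels (CH2 first, CH3 second) as a float32 2-page TIFF.

    Acquisition metadata goes to a JSON sidecar next to the TIFF so the
    round trip is lossless and bit-exact.
    """
    path = str(path)
    stack = np.stack([img.ch2, img.ch3], axis=0).astype(np.float32)
    tifffile.imwrite(path, stack)
    with open(_sidecar_path(path), "w") as fh:
        json.dump(
            {
                "image_id": img.image_id,
                "channel_order": ["CH2", "CH3"],
                "pixel_size_nm": img.pixel_size_nm,
                "scan_depth_um": img.scan_depth_um,
            },
            fh,
            indent=1,
        )


def read_srs_tiff(path) -> SRSImage:
    """Read a two-channel SRS TIFF written by :func:`write_srs_tiff`."""
    path = str(path)
    try:
        stack = tifffile.imread(path)
    except (tifffile.TiffFileError, FileNotFoundError, ValueError) as exc:
        raise ImageFormatError(f"cannot read SRS TIFF {path}: {exc}") from exc
    stack = np.asarray(stack)
    if stack.ndim == 2:
        raise ImageFormatError(
            f"{path}: found a single-channel image; an SRS TIFF must carry "
            f"exactly 2 channels (CH2, CH3)"
        )
    if stack.ndim != 3 or stack.shape[0] != 2:
        raise ImageFormatError(
            f"{path}: expected 2 channels (CH2, CH3), got array of shape {stack.shape}"
        )
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if os.path.exists(sidecar):
        with open(sidecar) as fh:
            meta = json.load(fh)
    image_id = meta.get("image_id") or os.path.splitext(os.path.basename(path))[0]
    return SRSImage(
        image_id=image_id,
        ch2=stack[0],
        ch3=stack[1],
        pixel_size_nm=meta.get("pixel_size_nm", DEFAULT_PIXEL_SIZE_NM),
        scan_depth_um=meta.get("scan_depth_um", DEFAULT_SCAN_DEPTH_UM),
    )


def write_png(rgb: np.ndarray, path) -> None:
    """Write an RGB array in [0, 1] as an 8-bit PNG."""
    arr = np.asarray(rgb)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB array, got {arr.shape}")
    u8 = np.clip(np.round(arr * 255.0), 0, 255).astype(np.uint8)
    PILImage.fromarray(u8, mode="RGB").save(str(path))
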