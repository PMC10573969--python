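"""Collagen fiber content from Masson-trichrome-stained sections.

Masson trichrome renders collagen blue/green and muscle/cytoplasm red, so
collagen-positive pixels can be isolated by a hue window in HSV space and
the fiber content of a region of interest is the positive-pixel area
fraction:

    Vf (%) = collagen area (px) / ROI area (px) * 100.

Per-slice measurements are averaged per region.  The segmentation rule
(hue window, saturation floor) is an explicit, configurable choice and is
recorded in every report.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.color import rgb2hsv
from skimage.draw import polygon2mask

from .constitutive import ValidationError

__all__ = [
    "StainedImage",
    "ROI",
    "SegmentationParams",
    "FiberContentMeasurement",
    "RegionContentSummary",
    "segment_collagen",
    "measure_vf",
    "summarize_region",
]


@dataclass(frozen=True)
class StainedImage:
    """An RGB Masson-stained section (8- or 16-bit channels)."""

    pixels: np.ndarray
    scale_um_px: float | None = None
    slice_id: str = ""
    region: str | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 3 or px.shape[2] < 3 or px.size == 0:
            raise ValidationError("pixels must be a non-empty HxWx3 RGB raster")
        if px.dtype not in (np.uint8, np.uint16):
            raise ValidationError("8- or 16-bit channels required")

    @classmethod
    def read(cls, path: str | Path, **meta) -> "StainedImage":
        px = iio.imread(path)
        if px.ndim == 3 and px.shape[2] == 4:
            px = px[..., :3]
        return cls(pixels=px, slice_id=meta.pop("slice_id", Path(path).stem), **meta)

    def write(self, path: str | Path) -> None:
        iio.imwrite(path, self.pixels)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def as_float_rgb(self) -> np.ndarray:
        info = np.iinfo(self.pixels.dtype)
        return self.pixels[..., :3].astype(float) / info.max


@dataclass(frozen=True)
class ROI:
    """Region of interest: axis-aligned rectangle or polygon.

    Rectangles are 0-based half-open: (row0, col0, row1, col1) selects
    rows [row0, row1) and cols [col0, col1).  Polygons are (N, 2) arrays of
    (row, col) vertices.
    """

    rect: tuple[int, int, int, int] | None = None
    polygon: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.rect is None) == (self.polygon is None):
            raise ValidationError("give exactly one of rect or polygon")
        if self.rect is not None:
            r0, c0, r1, c1 = self.rect
            if r1 <= r0 or c1 <= c0:
                raise ValidationError("rectangle must have positive area")
        else:
            poly = np.asarray(self.polygon, dtype=float)
            object.__setattr__(self, "polygon", poly)
            if poly.ndim != 2 or poly.shape[0] < 3 or poly.shape[1] != 2:
                raise ValidationError("polygon needs >= 3 (row, col) vertices")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean membership mask on an image of the given shape."""
        if self.rect is not None:
            r0, c0, r1, c1 = self.rect
            if r0 < 0 or c0 < 0 or r1 > shape[0] or c1 > shape[1]:
                raise ValidationError(f"ROI {self.rect} exceeds image bounds {shape}")
            m = np.zeros(shape, dtype=bool)
            m[r0:r1, c0:c1] = True
            return m
        poly = self.polygon
        if poly.min() < 0 or poly[:, 0].max() > shape[0] or poly[:, 1].max() > shape[1]:
            raise ValidationError("polygon exceeds image bounds")
        m = polygon2mask(shape, poly)
        if not m.any():
            raise ValidationError("polygon ROI selects no pixels")
        return m

    @classmethod
    def from_json_obj(cls, obj: dict) -> "ROI":
        if "rect" in obj:
            return cls(rect=tuple(int(v) for v in obj["rect"]))
        if "polygon" in obj:
            return cls(polygon=np.asarray(obj["polygon"], dtype=float))
        raise ValidationError("ROI JSON needs a 'rect' or 'polygon' key")


@dataclass(frozen=True)
class SegmentationParams:
    """Hue-window collagen classifier for Masson staining.

    Collagen stains blue/green: keep pixels with HSV hue inside
    [hue_lo, hue_hi] and saturation >= sat_min.  Hue is on [0, 1).
    """

    hue_lo: float = 0.45
    hue_hi: float = 0.75
    sat_min: float = 0.15

    def __post_init__(self) -> None:
        if not 0 <= self.hue_lo < self.hue_hi <= 1:
            raise ValidationError("require 0 <= hue_lo < hue_hi <= 1")
        if not 0 <= self.sat_min <= 1:
            raise ValidationError("sat_min must lie in [0, 1]")


@dataclass(frozen=True)
class FiberContentMeasurement:
    """Collagen pixel count over ROI pixel count, as a percentage."""

    collagen_px: int
    roi_px: int
    slice_id: str = ""
    region: str | None = None

    def __post_init__(self) -> None:
        if self.roi_px <= 0:
            raise ValidationError("ROI area must be > 0")
        if not 0 <= self.collagen_px <= self.roi_px:
            raise ValidationError("collagen pixel count out of range")

    @property
    def vf(self) -> float:
        return 100.0 * self.collagen_px / self.roi_px


@dataclass(frozen=True)
class RegionContentSummary:
    """Per-region collagen content: per-slice Vf values and their mean."""

    region: str
    per_slice_vf: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.per_slice_vf) == 0:
            raise ValidationError("need at least one per-slice value")

    @property
    def mean_vf(self) -> float:
        return float(np.mean(self.per_slice_vf))


def segment_collagen(
    img: StainedImage, roi: ROI, params: SegmentationParams | None = None
) -> np.ndarray:
    """Boolean mask of collagen-positive pixels, restricted to the ROI.

    Deterministic for fixed parameters; pixels outside the ROI are False.
    """
    params = params or SegmentationParams()
    roi_mask = roi.mask(img.shape)
    hsv = rgb2hsv(img.as_float_rgb())
    hue, sat = hsv[..., 0], hsv[..., 1]
    positive = (hue >= params.hue_lo) & (hue <= params.hue_hi) & (sat >= params.sat_min)
    return positive & roi_mask


def measure_vf(
    mask: np.ndarray, roi: ROI, shape: tuple[int, int] | None = None, **meta
) -> FiberContentMeasurement:
    """Vf from a collagen mask and its ROI (exact integer pixel ratio)."""
    mask = np.asarray(mask, dtype=bool)
    roi_mask = roi.mask(shape if shape is not None else mask.shape)
    if mask.shape != roi_mask.shape:
        raise ValidationError("mask and ROI shapes differ")
    if np.any(mask & ~roi_mask):
        raise ValidationError("mask has positive pixels outside the ROI")
    return FiberContentMeasurement(
        collagen_px=int(mask.sum()), roi_px=int(roi_mask.sum()), **meta
    )


def summarize_region(
    vf_values: Sequence[float], region: str
) -> RegionContentSummary:
    """Arithmetic mean of per-slice Vf values for one region, full precision."""
    if len(vf_values) == 0:
        raise ValidationError("cannot summarize an empty set of measurements")
    return RegionContentSummary(region=region, per_slice_vf=tuple(float(v) for v in vf_values))


def content_table(summaries: Sequence[RegionContentSummary]) -> pd.DataFrame:
    """Region x slice Vf table with a trailing mean column."""
    nmax = max(len(s.per_slice_vf) for s in summaries)
    rows = {}
    for s in summaries:
        vals = list(s.per_slice_vf) + [np.nan] * (nmax - len(s.per_slice_vf))
        rows[s.region] = vals + [s.mean_vf]
    cols = [f"slice_{i + 1}" for i in range(nmax)] + ["mean_vf"]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)
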