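"""Aggregate-area quantification in grayscale drop snapshots.

Dark aggregates on a light background are segmented by global thresholding
(Otsu by default, fixed threshold as an override), connected components
(8-connectivity) smaller than a minimum pixel count are discarded as
speckle, and an optional region-of-interest polygon excludes the probe and
window reflections.  Areas are reported both in px² and, through the
mm-per-pixel calibration, in mm².  All parameters used are logged into the
outputs for audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import draw as skdraw
from skimage import filters as skfilters
from skimage import measure as skmeasure
from skimage import morphology as skmorph

from .errors import ConfigError, ValidationError


@dataclass
class GrayImage:
    """8-bit grayscale image with physical calibration.

    ``roi`` is an optional polygon of (row, col) vertices; pixels outside it
    are ignored by segmentation.
    """

    pixels: np.ndarray
    mm_per_pixel: float
    roi: list[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValidationError("image must be a non-empty 2-D array")
        if self.mm_per_pixel <= 0:
            raise ValidationError("mm_per_pixel must be positive")
        if self.pixels.dtype != np.uint8:
            self.pixels = np.clip(self.pixels, 0, 255).astype(np.uint8)

    @classmethod
    def from_file(cls, path: str | Path, mm_per_pixel: float,
                  roi: list[tuple[float, float]] | None = None) -> "GrayImage":
        import imageio.v3 as iio

        arr = iio.imread(path)
        if arr.ndim == 3:  # collapse color/alpha to luminance
            arr = arr[..., :3].mean(axis=-1)
        return cls(arr, mm_per_pixel, roi)

    def to_file(self, path: str | Path) -> None:
        import imageio.v3 as iio

        iio.imwrite(path, self.pixels)


@dataclass
class SegmentationResult:
    mask: np.ndarray            # bool foreground
    n_components: int
    threshold: float | None     # None when degenerate
    threshold_mode: str
    min_component_px: int
    degenerate: bool = False

    @property
    def area_px2(self) -> float:
        return float(self.mask.sum())


@dataclass
class AreaSeries:
    times: list[float]
    area_px2: list[float]
    area_mm2: list[float]
    n_components: list[int]
    threshold_mode: str
    min_component_px: int
    mm_per_pixel: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times,
            "area_px2": self.area_px2,
            "area_mm2": self.area_mm2,
            "n_components": self.n_components,
        })


def segment_aggregate(img: GrayImage, threshold_mode: str = "otsu",
                      threshold: float | None = None,
                      min_component_px: int = 25) -> SegmentationResult:
    """Binary mask of dark aggregates plus a connected-component count.

    Pixels at or below the threshold are foreground (ties count as
    aggregate, mirroring the closed-interval convention of the contact
    score); components (8-connectivity) smaller than ``min_component_px``
    pixels are removed.  A uniform image under Otsu yields an empty mask
    with the ``degenerate`` flag set rather than an arbitrary split.
    """
    if threshold_mode not in ("otsu", "fixed"):
        raise ConfigError(f"unknown threshold_mode {threshold_mode!r}")
    if min_component_px < 0:
        raise ValidationError("min_component_px must be ≥ 0")
    px = img.pixels
    roi_mask = np.ones(px.shape, dtype=bool)
    if img.roi is not None:
        roi_mask = skdraw.polygon2mask(px.shape, np.asarray(img.roi))
        if not roi_mask.any():
            raise ValidationError("ROI polygon covers no pixels")
    sample = px[roi_mask]
    if threshold_mode == "fixed":
        if threshold is None:
            raise ConfigError("threshold_mode='fixed' requires a threshold value")
        thr = float(threshold)
    else:
        if sample.max() == sample.min():
            return SegmentationResult(
                np.zeros(px.shape, dtype=bool), 0, None, threshold_mode,
                min_component_px, degenerate=True)
        thr = float(skfilters.threshold_otsu(sample))
    mask = (px <= thr) & roi_mask
    if min_component_px > 1:
        mask = skmorph.remove_small_objects(mask, max_size=min_component_px - 1,
                                            connectivity=2)
    n_comp = int(skmeasure.label(mask, connectivity=2).max())
    return SegmentationResult(mask, n_comp, thr, threshold_mode,
                              min_component_px)


def aggregate_area_series(images: list[GrayImage], times: list[float],
                          threshold_mode: str = "otsu",
                          threshold: float | None = None,
                          min_component_px: int = 25) -> AreaSeries:
    """Segmented aggregate area per snapshot, in px² and mm²."""
    if not images:
        raise ValidationError("need ≥ 1 image")
    if len(times) != len(images):
        raise ValidationError("times and images must have equal length")
    calib = images[0].mm_per_pixel
    for i, img in enumerate(images):
        if img.mm_per_pixel != calib:
            raise ValidationError(
                f"calibration mismatch: image {i} has {img.mm_per_pixel} "
                f"mm/px, expected {calib}"
            )
    area_px2, area_mm2, n_comp = [], [], []
    for img in images:
        seg = segment_aggregate(img, threshold_mode, threshold,
                                min_component_px)
        area_px2.append(seg.area_px2)
        area_mm2.append(seg.area_px2 * calib * calib)
        n_comp.append(seg.n_components)
    return AreaSeries([float(t) for t in times], area_px2, area_mm2, n_comp,
                      threshold_mode, min_component_px, calib)
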