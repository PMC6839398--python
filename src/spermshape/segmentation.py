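"""Segmentation of grayscale nucleus images into clean closed outlines.

Thresholding (Otsu by default) followed by connected-component filtering,
border clearing and marching-squares contour extraction. Outlines are
returned in micrometres, counterclockwise, in a y-up mathematical frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.segmentation import clear_border

from .geometry import Outline, resample_closed, smooth_closed
from .synthetic import GrayImage

__all__ = ["SegmentationConfig", "segment_nuclei", "extract_outline",
           "smooth_resample"]


@dataclass
class SegmentationConfig:
    threshold_method: str = "otsu"     # "otsu" or "fixed"
    fixed_threshold: float | None = None
    min_area: float = 5.0              # µm²
    max_area: float = 100.0            # µm²


def segment_nuclei(image: GrayImage,
                   config: SegmentationConfig = SegmentationConfig()
                   ) -> list[np.ndarray]:
    """Binary mask per qualifying nucleus.

    Components touching the image border are discarded; components outside
    the [min_area, max_area] window (in µm²) are discarded. An image with
    no qualifying component yields an empty list.
    """
    px = np.asarray(image.pixels, dtype=float)
    if px.size == 0:
        raise ValueError("empty image")
    if config.threshold_method == "fixed":
        if config.fixed_threshold is None:
            raise ValueError("fixed threshold requested but none given")
        thresh = config.fixed_threshold
    elif config.threshold_method == "otsu":
        if np.ptp(px) == 0:
            return []
        thresh = threshold_otsu(px)
    else:
        raise ValueError(f"unknown threshold method {config.threshold_method!r}")
    binary = px > thresh
    binary = clear_border(binary)
    binary = ndimage.binary_fill_holes(binary)
    labels, n = ndimage.label(binary)
    masks = []
    px_area = image.pixel_size ** 2
    for lab in range(1, n + 1):
        mask = labels == lab
        area = mask.sum() * px_area
        if config.min_area <= area <= config.max_area:
            masks.append(mask)
    return masks


def extract_outline(mask: np.ndarray, pixel_size: float = 1.0,
                    smooth_window: float = 0.02) -> Outline:
    """Border polygon of a single-component mask, in µm, counterclockwise.

    The marching-squares contour at the half-intensity level is lightly
    smoothed (circular moving average over ``smooth_window`` of the
    perimeter) to suppress pixelation before any angle measurement.
    """
    mask = np.asarray(mask).astype(bool)
    filled = ndimage.binary_fill_holes(mask)
    _, n = ndimage.label(filled)
    if n != 1:
        raise ValueError(f"mask must contain exactly one component, found {n}")
    padded = np.pad(filled, 1).astype(float)
    contours = measure.find_contours(padded, 0.5)
    contour = max(contours, key=len)
    rows = contour[:, 0] - 1.0
    cols = contour[:, 1] - 1.0
    # y-up mathematical frame: flip rows
    x = cols * pixel_size
    y = (mask.shape[0] - 1 - rows) * pixel_size
    verts = np.column_stack([x, y])
    if np.allclose(verts[0], verts[-1]):
        verts = verts[:-1]
    verts = smooth_closed(verts, smooth_window)
    return Outline(verts)


def smooth_resample(outline: Outline, n_points: int = 200,
                    smooth_window: float = 0.0) -> Outline:
    """Resample an outline to ``n_points`` vertices equally spaced by arc
    length, so all profiles share an index space.

    Pure resampling preserves perimeter and area; an optional moving
    average over ``smooth_window`` of the perimeter can be requested for
    outlines that were not already smoothed at extraction (smoothing
    legitimately shortens a wiggly border, so it is off by default here).
    """
    if n_points < 50:
        raise ValueError("n_points must be >= 50")
    verts = smooth_closed(outline.vertices, smooth_window)
    return Outline(resample_closed(verts, n_points))
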