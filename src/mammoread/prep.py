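"""Image standardization and ROI extraction ahead of feature computation.

Pipeline order is resample (bicubic, to 0.1 mm/pixel by default) ->
zero-mean/unit-variance intensity normalization -> rectangular ROI crop
-> grey-level quantization (mean +/- 3 SD clip, 64 equal-width levels).
Normalization statistics default to the whole image; a mask-restricted
option exists because the original analysis does not say which it used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import zoom

logger = logging.getLogger(__name__)

DEFAULT_TARGET_SPACING = 0.1  # mm / pixel
DEFAULT_GREY_LEVELS = 64


@dataclass
class PreparedImage:
    """A standardized 2-D image with its provenance."""

    array: np.ndarray
    spacing: float  # mm / pixel, current
    provenance: dict = field(default_factory=dict)


@dataclass
class QuantizedROI:
    """Integer grey-level array with levels 0 .. L-1."""

    array: np.ndarray
    levels: int
    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        if self.array.size == 0:
            raise ValueError("empty ROI")
        if self.array.max(initial=0) >= self.levels:
            raise ValueError("quantized values must be < levels")


def normalize_intensity(image: np.ndarray, spacing: float = 1.0,
                        mask: Optional[np.ndarray] = None) -> PreparedImage:
    """Standardize intensities to zero mean and unit variance.

    Statistics come from ``mask`` pixels when given, else the whole
    image; the same affine is applied everywhere, so the output is
    invariant to affine rescalings of the input.
    """
    arr = np.asarray(image, dtype=float)
    sel = arr[mask] if mask is not None else arr
    mean = float(sel.mean())
    sd = float(sel.std())
    if sd < 1e-12:
        raise ValueError("cannot normalize a constant image")
    out = (arr - mean) / sd
    return PreparedImage(array=out, spacing=spacing,
                         provenance={"norm_mean": mean, "norm_sd": sd,
                                     "masked": mask is not None})


def intensity_histograms(before: np.ndarray, after: np.ndarray, bins: int = 64):
    """Pre/post-normalization histogram pair for the validation check."""
    h0, e0 = np.histogram(np.asarray(before).ravel(), bins=bins)
    h1, e1 = np.histogram(np.asarray(after).ravel(), bins=bins)
    return {"before": (h0, e0), "after": (h1, e1)}


def resample(image: np.ndarray, original_spacing: float,
             target_spacing: float = DEFAULT_TARGET_SPACING) -> PreparedImage:
    """Bicubic resampling onto the target pixel spacing.

    Output size is round(original size x original/target) per axis.
    """
    if original_spacing <= 0 or target_spacing <= 0:
        raise ValueError("spacings must be positive")
    arr = np.asarray(image, dtype=float)
    factor = original_spacing / target_spacing
    if factor > 20:
        logger.warning("upsampling factor %.1f > 20; expect interpolation "
                       "artefacts", factor)
    if abs(factor - 1.0) < 1e-12:
        out = arr.copy()
    else:
        target_shape = (int(round(arr.shape[0] * factor)),
                        int(round(arr.shape[1] * factor)))
        exact = (target_shape[0] / arr.shape[0], target_shape[1] / arr.shape[1])
        out = zoom(arr, exact, order=3, mode="reflect", grid_mode=True)
    return PreparedImage(array=out, spacing=target_spacing,
                         provenance={"original_spacing": original_spacing,
                                     "original_shape": arr.shape,
                                     "zoom_factor": factor})


def rescale_bbox(bbox: tuple[int, int, int, int], original_spacing: float,
                 target_spacing: float) -> tuple[int, int, int, int]:
    """Map an inclusive bbox from original-spacing to target-spacing pixels."""
    f = original_spacing / target_spacing
    x0, y0, x1, y1 = bbox
    return (int(np.floor(x0 * f)), int(np.floor(y0 * f)),
            int(np.ceil((x1 + 1) * f)) - 1, int(np.ceil((y1 + 1) * f)) - 1)


def extract_roi(image: PreparedImage,
                bbox: tuple[int, int, int, int]) -> np.ndarray:
    """Copy of the inclusive-bbox sub-array."""
    x0, y0, x1, y1 = bbox
    rows, cols = image.array.shape
    if not (0 <= x0 <= x1 < cols and 0 <= y0 <= y1 < rows):
        raise ValueError(f"bbox {bbox} outside image of shape {image.array.shape}")
    roi = image.array[y0:y1 + 1, x0:x1 + 1].copy()
    image.provenance.setdefault("rois", []).append(bbox)
    return roi


def quantize(roi: np.ndarray, levels: int = DEFAULT_GREY_LEVELS,
             clip_sd: float = 3.0) -> QuantizedROI:
    """Clip to mean +/- clip_sd*SD, then equal-width binning into L levels."""
    arr = np.asarray(roi, dtype=float)
    if arr.size == 0:
        raise ValueError("empty ROI")
    mean, sd = float(arr.mean()), float(arr.std())
    if sd < 1e-12:
        logger.warning("constant ROI: quantizing to all-zero levels")
        edges = np.linspace(mean - 0.5, mean + 0.5, levels + 1)
        return QuantizedROI(np.zeros(arr.shape, dtype=np.int64), levels, edges)
    lo, hi = mean - clip_sd * sd, mean + clip_sd * sd
    clipped = np.clip(arr, lo, hi)
    cmin, cmax = float(clipped.min()), float(clipped.max())
    if cmax - cmin < 1e-12:
        edges = np.linspace(cmin - 0.5, cmin + 0.5, levels + 1)
        return QuantizedROI(np.zeros(arr.shape, dtype=np.int64), levels, edges)
    # bin over the clipped data range so the full level span is used
    edges = np.linspace(cmin, cmax, levels + 1)
    q = np.digitize(clipped, edges[1:-1], right=False)
    return QuantizedROI(q.astype(np.int64), levels, edges)
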