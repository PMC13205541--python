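"""ROI-guided binarisation of the enhanced image into a per-view vitiligo mask.

Each operator-drawn patch ROI is thresholded independently on the enhanced
monochrome image (pixel = vitiligo iff intensity strictly exceeds the
threshold).  The effective threshold per ROI is resolved by precedence:
per-ROI override, then a global threshold if supplied, then Otsu's method
computed over the ROI's own intensities.  The view mask is the union of the
per-ROI masks intersected with the rasterised face outline, so every vitiligo
pixel lies inside the face by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .errors import ConfigurationError, DegenerateRoiError, ValidationError
from .filters import FilterSpec, apply_filter
from .image_model import (
    PatchMask,
    ViewAnnotation,
    WoodsLightImage,
    rasterize_polygon,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentationResult:
    """Mask plus per-ROI provenance for one view.

    ROIs may overlap; the mask is their union, so per-ROI pixel counts can
    sum to more than the mask total.  Downstream indices always use the
    union mask.
    """

    mask: PatchMask
    face_mask: np.ndarray
    per_roi_pixel_counts: tuple[int, ...]
    thresholds_used: tuple[float, ...]
    filter_spec: FilterSpec

    def __post_init__(self) -> None:
        if len(self.per_roi_pixel_counts) != len(self.thresholds_used):
            raise ValidationError(
                "per_roi_pixel_counts and thresholds_used must align"
            )


def binarize_roi(
    mono: np.ndarray, roi_mask: np.ndarray, threshold: float
) -> np.ndarray:
    """Threshold the monochrome image inside an ROI.

    Output pixel = 1 iff the ROI contains it AND its intensity is strictly
    greater than ``threshold``; strictness makes threshold 1 yield an empty
    mask, the safe degenerate case.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ConfigurationError(f"threshold must be in [0, 1], got {threshold}")
    mono = np.asarray(mono)
    roi = np.asarray(roi_mask, dtype=bool)
    if mono.shape != roi.shape:
        raise ValidationError(
            f"shape mismatch: mono {mono.shape} vs ROI {roi.shape}"
        )
    return roi & (mono > threshold)


def auto_threshold(mono: np.ndarray, roi_mask: np.ndarray) -> float:
    """Otsu threshold over the intensities inside the ROI (256 bins).

    Replaces the interactive operator's choice with a reproducible default;
    a constant ROI has no between-class structure and raises
    :class:`DegenerateRoiError` instructing a manual override.
    """
    roi = np.asarray(roi_mask, dtype=bool)
    values = np.asarray(mono)[roi]
    if values.size == 0 or np.all(values == values.flat[0]):
        raise DegenerateRoiError(
            "ROI has no intensity variation; supply a manual threshold "
            "override for this patch"
        )
    # Explicit histogram pins the binning convention: 256 uniform bins over
    # the ROI's intensity range.
    hist, edges = np.histogram(values, bins=256)
    centers = (edges[:-1] + edges[1:]) / 2
    return float(threshold_otsu(hist=(hist, centers)))


def segment_view(
    img: WoodsLightImage,
    ann: ViewAnnotation,
    spec: FilterSpec | None = None,
    global_threshold: float | None = None,
) -> SegmentationResult:
    """Run enhancement + per-ROI binarisation for one annotated view."""
    if spec is None:
        spec = FilterSpec()
    if ann.view != img.view:
        raise ValidationError(
            f"annotation view {ann.view!r} does not match image view "
            f"{img.view!r}"
        )
    if global_threshold is not None and not 0.0 <= global_threshold <= 1.0:
        raise ConfigurationError(
            f"global threshold must be in [0, 1], got {global_threshold}"
        )
    mono = apply_filter(img, spec)
    h, w = mono.shape
    face_mask = rasterize_polygon(ann.face, w, h)

    union = np.zeros((h, w), dtype=bool)
    counts: list[int] = []
    thresholds: list[float] = []
    for roi in ann.patches:
        roi_mask = rasterize_polygon(roi, w, h)
        if roi.threshold_override is not None:
            t = roi.threshold_override
        elif global_threshold is not None:
            t = float(global_threshold)
        else:
            t = auto_threshold(mono, roi_mask)
        binary = binarize_roi(mono, roi_mask, t)
        counts.append(int(binary.sum()))
        thresholds.append(t)
        union |= binary
    union &= face_mask
    return SegmentationResult(
        mask=PatchMask(union),
        face_mask=face_mask,
        per_roi_pixel_counts=tuple(counts),
        thresholds_used=tuple(thresholds),
        filter_spec=spec,
    )


def dice_coefficient(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValidationError(f"shape mismatch: {a.shape} vs {b.shape}")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / total
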