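"""Contrast enhancement: channel combination plus CLAHE.

Under Wood's light, depigmented skin fluoresces bright bluish-white while
pigmented skin stays dark, so the first pipeline stage collapses the RGB
photograph into a monochrome image that maximises patch/skin contrast.  The
default enhancer is contrast-limited adaptive histogram equalisation (CLAHE):
the image is divided into tiles, each tile's histogram is clipped (bounding
noise amplification) and equalised, and per-pixel mappings are bilinearly
interpolated between neighbouring tiles.

All monochrome images in this package are float arrays with values in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import ConfigurationError
from .image_model import WoodsLightImage

_EPS = 1.0  # one 8-bit intensity unit, guards the ratio combiner


def _as_float_channels(img: WoodsLightImage) -> tuple[np.ndarray, ...]:
    px = img.pixels.astype(np.float64)
    return px[..., 0], px[..., 1], px[..., 2]


CHANNEL_COMBINERS: dict[str, Callable[..., np.ndarray]] = {
    "red": lambda r, g, b: r,
    "green": lambda r, g, b: g,
    "blue": lambda r, g, b: b,
    "luminance": lambda r, g, b: 0.299 * r + 0.587 * g + 0.114 * b,
    "blue_minus_red": lambda r, g, b: b - r,
    "blue_over_sum": lambda r, g, b: b / (r + g + b + _EPS),
}


@dataclass(frozen=True)
class FilterSpec:
    """Resolved enhancement settings, embedded in every report.

    ``clahe_clip_limit`` is the normalised contrast limit in (0, 1]: the
    fraction of each tile's pixel count a histogram bin may hold beyond the
    uniform level before the excess is redistributed.  1.0 disables clipping.
    """

    channel_combiner: str = "blue"
    clahe_enabled: bool = True
    clahe_clip_limit: float = 0.01
    clahe_tiles: tuple[int, int] = (8, 8)
    nbins: int = 256

    def __post_init__(self) -> None:
        if self.channel_combiner not in CHANNEL_COMBINERS:
            raise ConfigurationError(
                f"unknown channel combiner {self.channel_combiner!r}; "
                f"valid names: {sorted(CHANNEL_COMBINERS)}"
            )
        if self.clahe_clip_limit <= 0:
            raise ConfigurationError("clahe_clip_limit must be > 0")
        rows, cols = self.clahe_tiles
        if rows < 1 or cols < 1:
            raise ConfigurationError("clahe_tiles counts must be >= 1")
        if self.nbins < 2:
            raise ConfigurationError("nbins must be >= 2")

    def to_dict(self) -> dict:
        return {
            "channel_combiner": self.channel_combiner,
            "clahe_enabled": self.clahe_enabled,
            "clahe_clip_limit": self.clahe_clip_limit,
            "clahe_tiles": list(self.clahe_tiles),
            "nbins": self.nbins,
        }


def combine_channels(img: WoodsLightImage, combiner: str) -> np.ndarray:
    """Collapse RGB to monochrome and min-max rescale to [0, 1].

    Rescaling is per image (not per ROI) so that thresholds chosen later are
    comparable across images.  A constant image maps to all zeros — no
    contrast means no patch evidence.
    """
    if combiner not in CHANNEL_COMBINERS:
        raise ConfigurationError(
            f"unknown channel combiner {combiner!r}; "
            f"valid names: {sorted(CHANNEL_COMBINERS)}"
        )
    raw = CHANNEL_COMBINERS[combiner](*_as_float_channels(img))
    lo, hi = float(raw.min()), float(raw.max())
    if hi == lo:
        return np.zeros(raw.shape, dtype=np.float64)
    return (raw - lo) / (hi - lo)


def _clipped_cdf_mapping(
    values: np.ndarray, nbins: int, clip_limit: float
) -> np.ndarray:
    """Equalisation mapping (bin -> [0,1]) from a clipped histogram.

    The mapping is the empirical CDF of the clipped histogram, as in the
    classical formulation: with no clipping a value maps to the fraction of
    pixels at or below it.
    """
    hist = np.bincount(values, minlength=nbins).astype(np.float64)
    npix = hist.sum()
    min_clip = np.ceil(npix / nbins)
    frac = min(clip_limit, 1.0)
    clip = min_clip + round(frac * (npix - min_clip))
    excess = np.maximum(hist - clip, 0.0).sum()
    if excess > 0:
        hist = np.minimum(hist, clip)
        # Uniform redistribution of the clipped mass; a second pass mops up
        # what the first pushes back over the limit.
        for _ in range(2):
            hist += excess / nbins
            over = np.maximum(hist - clip, 0.0)
            excess = over.sum()
            if excess == 0:
                break
            hist -= over
        hist += excess / nbins
    return np.cumsum(hist) / npix


def clahe_enhance(
    mono: np.ndarray,
    clip_limit: float = 0.01,
    tiles: tuple[int, int] = (8, 8),
    nbins: int = 256,
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalisation on a [0, 1] image.

    With 1x1 tiling and ``clip_limit`` = 1 this reduces exactly to global
    histogram equalisation: each grey level maps to its empirical CDF value.
    """
    if clip_limit <= 0:
        raise ConfigurationError("clip_limit must be > 0")
    rows, cols = tiles
    if rows < 1 or cols < 1:
        raise ConfigurationError("tile counts must be >= 1")
    mono = np.asarray(mono, dtype=np.float64)
    h, w = mono.shape

    pad_h = (-h) % rows
    pad_w = (-w) % cols
    work = np.pad(mono, ((0, pad_h), (0, pad_w)), mode="reflect") if (
        pad_h or pad_w
    ) else mono
    ph, pw = work.shape
    th, tw = ph // rows, pw // cols

    bins = np.clip((work * nbins).astype(np.int64), 0, nbins - 1)

    mappings = np.empty((rows, cols, nbins), dtype=np.float64)
    for r in range(rows):
        for c in range(cols):
            tile = bins[r * th : (r + 1) * th, c * tw : (c + 1) * tw]
            mappings[r, c] = _clipped_cdf_mapping(
                tile.ravel(), nbins, clip_limit
            )

    # Bilinear interpolation between the four surrounding tile mappings.
    gy = np.clip((np.arange(ph) + 0.5) / th - 0.5, 0, rows - 1)
    gx = np.clip((np.arange(pw) + 0.5) / tw - 0.5, 0, cols - 1)
    r0 = np.floor(gy).astype(int)
    c0 = np.floor(gx).astype(int)
    r1 = np.minimum(r0 + 1, rows - 1)
    c1 = np.minimum(c0 + 1, cols - 1)
    wr = (gy - r0)[:, None]
    wc = (gx - c0)[None, :]

    r0g, r1g = r0[:, None], r1[:, None]
    c0g, c1g = c0[None, :], c1[None, :]
    out = (
        (1 - wr) * (1 - wc) * mappings[r0g, c0g, bins]
        + (1 - wr) * wc * mappings[r0g, c1g, bins]
        + wr * (1 - wc) * mappings[r1g, c0g, bins]
        + wr * wc * mappings[r1g, c1g, bins]
    )
    return out[:h, :w]


def apply_filter(img: WoodsLightImage, spec: FilterSpec) -> np.ndarray:
    """Run the full Step-1 enhancement: channel combination, then CLAHE."""
    mono = combine_channels(img, spec.channel_combiner)
    if spec.clahe_enabled:
        mono = clahe_enhance(
            mono, spec.clahe_clip_limit, spec.clahe_tiles, spec.nbins
        )
    return mono
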