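"""Face Vitiligo Index (FVI), F-VASI conversion and longitudinal change.

Per view i, the depigmented fraction is p_v,i / p_f,i — vitiligo pixels over
total face pixels — which normalises away image size, resolution and face
dimensions.  The FVI averages these fractions over the available views
(frontal, left, right):

    FVI = (1/n) * sum_i p_v,i / p_f,i

FVI = 0 means no detectable patches; FVI = 1 a fully depigmented face.  The
clinical F-VASI is estimated by counting fingertip units, each covering 0.1%
of body surface area.  Treatment response is the percent decline of an index
between two timepoints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .image_model import PatchMask


@dataclass(frozen=True)
class ViewIndexResult:
    """Vitiligo pixel fraction for a single view."""

    view: str
    vitiligo_pixels: int
    face_pixels: int

    def __post_init__(self) -> None:
        if self.face_pixels < 1:
            raise ValidationError("face mask must contain at least one pixel")
        if not 0 <= self.vitiligo_pixels <= self.face_pixels:
            raise ValidationError(
                f"vitiligo pixels ({self.vitiligo_pixels}) must be within "
                f"[0, face pixels = {self.face_pixels}]"
            )

    @property
    def ratio(self) -> float:
        return self.vitiligo_pixels / self.face_pixels


@dataclass(frozen=True)
class FVIResult:
    """FVI for one patient at one timepoint, with per-view provenance."""

    per_view: tuple[ViewIndexResult, ...]
    fvi_fraction: float

    @property
    def fvi_percent(self) -> float:
        return 100.0 * self.fvi_fraction

    @property
    def n_views(self) -> int:
        return len(self.per_view)


@dataclass(frozen=True)
class FvasiEstimate:
    """F-VASI from a clinician's fingertip-unit count (0.1% BSA per unit)."""

    fingertip_units_depigmented: float

    def __post_init__(self) -> None:
        if self.fingertip_units_depigmented < 0:
            raise ValidationError("fingertip-unit count must be >= 0")

    @property
    def fvasi(self) -> float:
        return 0.1 * self.fingertip_units_depigmented


def view_index(mask: PatchMask | np.ndarray, face_mask: np.ndarray,
               view: str = "frontal") -> ViewIndexResult:
    """Count vitiligo pixels inside the face and normalise by face area."""
    grid = mask.grid if isinstance(mask, PatchMask) else np.asarray(mask, bool)
    face = np.asarray(face_mask, dtype=bool)
    if grid.shape != face.shape:
        raise ValidationError(
            f"mask shape {grid.shape} does not match face {face.shape}"
        )
    face_px = int(face.sum())
    if face_px == 0:
        raise ValidationError("face mask is empty; cannot normalise area")
    return ViewIndexResult(
        view=view,
        vitiligo_pixels=int((grid & face).sum()),
        face_pixels=face_px,
    )


def face_vitiligo_index(per_view: list[ViewIndexResult]) -> FVIResult:
    """Average the per-view fractions into the Face Vitiligo Index.

    With all three views this is the canonical (1/3)-weighted sum; with
    fewer the divisor is the number of views supplied (imputing zeros for a
    missing view would understate disease).
    """
    if not per_view:
        raise ValidationError("at least one view index is required")
    labels = [v.view for v in per_view]
    if len(set(labels)) != len(labels):
        raise ValidationError(f"duplicate view labels: {labels}")
    # fsum keeps the mean exactly permutation-invariant
    fraction = math.fsum(v.ratio for v in per_view) / len(per_view)
    return FVIResult(per_view=tuple(per_view), fvi_fraction=fraction)


def percent_change(before: float, after: float) -> float:
    """Percent decline 100·(before − after)/before; positive = improvement.

    Used both for repigmentation (area index decline) and questionnaire
    score reduction.  Returned unrounded; reports round to one decimal.
    """
    if before <= 0:
        raise ValidationError(
            f"baseline value must be > 0 to compute percent change, got {before}"
        )
    if after < 0:
        raise ValidationError(f"follow-up value must be >= 0, got {after}")
    return 100.0 * (before - after) / before


def fvasi_from_units(units: float) -> FvasiEstimate:
    """Convert a fingertip-unit count to F-VASI (% of body surface area)."""
    return FvasiEstimate(fingertip_units_depigmented=float(units))
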