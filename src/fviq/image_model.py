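"""Core data types and raster/annotation I/O shared by every pipeline stage.

A patient is photographed under Wood's light (long-wave UV-A, 340-365 nm) in
up to three views — frontal, left, right.  Each view carries one operator-drawn
face-outline polygon and zero or more rough polygonal regions of interest
(ROIs) around suspected depigmented patches; segmentation refines the ROIs to
pixel level.

Coordinate convention: origin at the top-left corner, x rightward, y downward,
0-based integer pixel indices.  Polygon vertices live in continuous pixel
coordinates; a pixel (x, y) belongs to a polygon iff its centre (x+0.5, y+0.5)
lies inside the closed polygon under the even-odd rule.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import imageio.v3 as iio
import numpy as np

from .errors import InputError, ValidationError

logger = logging.getLogger(__name__)

VIEW_LABELS = ("frontal", "left", "right")

ViewLabel = Literal["frontal", "left", "right"]


def _check_view(view: str) -> str:
    if view not in VIEW_LABELS:
        raise ValidationError(
            f"view must be one of {VIEW_LABELS}, got {view!r}"
        )
    return view


@dataclass(frozen=True)
class WoodsLightImage:
    """One RGB view of a patient's face under Wood's-light illumination.

    ``pixels`` is an (H, W, 3) uint8 array.  View, patient and timepoint are
    explicit metadata supplied by the caller (sidecar annotation or CLI flag),
    never guessed from filenames or image content.
    """

    pixels: np.ndarray
    view: str
    patient_id: str = ""
    timepoint: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValidationError(
                f"pixels must be an (H, W, 3) array, got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValidationError("image must have width >= 1 and height >= 1")
        if px.dtype != np.uint8:
            raise ValidationError(f"pixels must be uint8, got {px.dtype}")
        _check_view(self.view)
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class PolygonROI:
    """A closed polygon in continuous pixel coordinates.

    ``kind`` distinguishes the single face outline from patch ROIs.  A patch
    ROI may carry a per-patch binarisation threshold override in [0, 1],
    which takes precedence over any global threshold.
    """

    vertices: tuple[tuple[float, float], ...]
    kind: Literal["face_outline", "patch"] = "patch"
    threshold_override: float | None = None

    def __post_init__(self) -> None:
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        if len(verts) < 3:
            raise ValidationError(
                f"polygon needs >= 3 vertices, got {len(verts)}"
            )
        if self.kind not in ("face_outline", "patch"):
            raise ValidationError(f"unknown ROI kind {self.kind!r}")
        if self.threshold_override is not None:
            if self.kind != "patch":
                raise ValidationError(
                    "threshold_override is only valid on patch ROIs"
                )
            t = float(self.threshold_override)
            if not 0.0 <= t <= 1.0:
                raise ValidationError(
                    f"threshold_override must be in [0, 1], got {t}"
                )
            object.__setattr__(self, "threshold_override", t)
        if _is_self_intersecting(verts):
            raise ValidationError("polygon is self-intersecting")
        object.__setattr__(self, "vertices", verts)

    def bounding_box(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the vertex set."""
        xs = [v[0] for v in self.vertices]
        ys = [v[1] for v in self.vertices]
        return min(xs), min(ys), max(xs), max(ys)


def _segments_properly_cross(p1, p2, q1, q2) -> bool:
    """True iff open segments p1-p2 and q1-q2 cross at an interior point."""

    def orient(a, b, c):
        v = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        return 0 if v == 0 else (1 if v > 0 else -1)

    o1, o2 = orient(p1, p2, q1), orient(p1, p2, q2)
    o3, o4 = orient(q1, q2, p1), orient(q1, q2, p2)
    return o1 != o2 and o3 != o4 and 0 not in (o1, o2, o3, o4)


def _is_self_intersecting(verts: Sequence[tuple[float, float]]) -> bool:
    """Check simple-polygon property after closing (proper crossings only)."""
    n = len(verts)
    edges = [(verts[i], verts[(i + 1) % n]) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if j == i + 1 or (i == 0 and j == n - 1):
                continue  # adjacent edges share a vertex
            if _segments_properly_cross(*edges[i], *edges[j]):
                return True
    return False


@dataclass(frozen=True)
class ViewAnnotation:
    """Operator annotation for one view: one face outline plus patch ROIs."""

    view: str
    face: PolygonROI
    patches: tuple[PolygonROI, ...] = ()

    def __post_init__(self) -> None:
        _check_view(self.view)
        if self.face.kind != "face_outline":
            raise ValidationError("face ROI must have kind 'face_outline'")
        patches = tuple(self.patches)
        fx0, fy0, fx1, fy1 = self.face.bounding_box()
        for i, p in enumerate(patches):
            if p.kind != "patch":
                raise ValidationError(f"patch ROI {i} must have kind 'patch'")
            px0, py0, px1, py1 = p.bounding_box()
            if px1 < fx0 or px0 > fx1 or py1 < fy0 or py0 > fy1:
                raise ValidationError(
                    f"patch ROI {i} bounding box does not intersect the face"
                )
        object.__setattr__(self, "patches", patches)


@dataclass(frozen=True)
class PatchMask:
    """Per-view binary vitiligo map: 0 = healthy skin, 1 = depigmented."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.grid)
        if g.ndim != 2:
            raise ValidationError("mask must be 2-D")
        g = g.astype(bool)
        object.__setattr__(self, "grid", g)

    @property
    def pixel_count(self) -> int:
        return int(self.grid.sum())


def read_image(
    path: str | Path,
    *,
    view: str = "frontal",
    patient_id: str = "",
    timepoint: str = "",
) -> WoodsLightImage:
    """Read a PNG/JPEG/TIFF photograph into a :class:`WoodsLightImage`.

    Grayscale inputs are replicated to three identical channels; 16-bit inputs
    are rescaled to 8-bit by integer division (65535 -> 255, 0 -> 0).  Alpha
    channels are dropped.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # imageio raises a zoo of types
        raise InputError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.size == 0:
        raise ValidationError(f"image {path} has zero area")
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.shape[-1] == 1:
        arr = np.repeat(arr, 3, axis=-1)
    if arr.dtype == np.uint16:
        arr = (arr // 257).astype(np.uint8)  # 257 = 65535 / 255
    elif arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return WoodsLightImage(
        pixels=arr, view=view, patient_id=patient_id, timepoint=timepoint
    )


def write_image(path: str | Path, img: WoodsLightImage) -> None:
    iio.imwrite(Path(path), img.pixels)


def write_mask_png(path: str | Path, mask: np.ndarray | PatchMask) -> None:
    """Write a binary mask as an 8-bit PNG with values 0/255."""
    grid = mask.grid if isinstance(mask, PatchMask) else np.asarray(mask)
    iio.imwrite(Path(path), (grid.astype(np.uint8) * 255))


def read_mask_png(path: str | Path) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 127


def _roi_from_json(obj: dict, kind: str, index: int) -> PolygonROI:
    try:
        verts = tuple((float(x), float(y)) for x, y in obj["vertices"])
    except (KeyError, TypeError, ValueError) as exc:
        raise ValidationError(f"ROI {index}: malformed vertex list") from exc
    try:
        return PolygonROI(
            vertices=verts,
            kind=kind,
            threshold_override=obj.get("threshold"),
        )
    except ValidationError as exc:
        raise ValidationError(f"ROI {index}: {exc}") from exc


def read_annotation(path: str | Path) -> ViewAnnotation:
    """Read a per-view JSON annotation document.

    Schema::

        {"view": "frontal|left|right",
         "face": {"vertices": [[x, y], ...]},
         "patches": [{"vertices": [[x, y], ...], "threshold": 0.4}, ...]}
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except FileNotFoundError as exc:
        raise InputError(f"annotation file not found: {path}") from exc
    except json.JSONDecodeError as exc:
        raise InputError(f"annotation {path} is not valid JSON: {exc}") from exc
    if "face" not in doc:
        raise ValidationError(f"annotation {path} is missing the face outline")
    face = _roi_from_json(doc["face"], "face_outline", index=-1)
    patches = tuple(
        _roi_from_json(p, "patch", index=i)
        for i, p in enumerate(doc.get("patches", []))
    )
    return ViewAnnotation(view=doc.get("view", "frontal"), face=face, patches=patches)


def annotation_to_json(ann: ViewAnnotation) -> dict:
    """Annotation as a JSON-ready dict; vertices round-trip bit-exactly."""
    doc: dict = {
        "view": ann.view,
        "face": {"vertices": [[x, y] for x, y in ann.face.vertices]},
        "patches": [],
    }
    for p in ann.patches:
        entry: dict = {"vertices": [[x, y] for x, y in p.vertices]}
        if p.threshold_override is not None:
            entry["threshold"] = p.threshold_override
        doc["patches"].append(entry)
    return doc


def write_annotation(path: str | Path, ann: ViewAnnotation) -> None:
    Path(path).write_text(json.dumps(annotation_to_json(ann), indent=1))


def rasterize_polygon(
    poly: PolygonROI | Sequence[tuple[float, float]],
    width: int,
    height: int,
) -> np.ndarray:
    """Rasterise a polygon to an (height, width) boolean mask.

    A pixel is inside iff its centre (x+0.5, y+0.5) is inside the closed
    polygon under the even-odd rule; geometry outside the image is clipped.
    A degenerate (zero-area) polygon yields an empty mask with a warning.
    """
    if width < 1 or height < 1:
        raise ValidationError("width and height must be >= 1")
    verts = poly.vertices if isinstance(poly, PolygonROI) else tuple(poly)
    vx = np.array([v[0] for v in verts], dtype=float)
    vy = np.array([v[1] for v in verts], dtype=float)
    if _polygon_area(vx, vy) == 0.0:
        logger.warning("degenerate zero-area polygon rasterised to empty mask")
        return np.zeros((height, width), dtype=bool)

    # Even-odd ray cast from each pixel centre toward +x, one edge at a time.
    cx = np.arange(width, dtype=float) + 0.5
    cy = np.arange(height, dtype=float) + 0.5
    px = cx[np.newaxis, :]
    py = cy[:, np.newaxis]
    inside = np.zeros((height, width), dtype=bool)
    n = len(verts)
    for i in range(n):
        x1, y1 = vx[i], vy[i]
        x2, y2 = vx[(i + 1) % n], vy[(i + 1) % n]
        if y1 == y2:
            continue  # horizontal edge never crosses a horizontal ray
        straddles = (y1 > py) != (y2 > py)
        x_at = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
        inside ^= straddles & (px < x_at)
    return inside


def _polygon_area(vx: np.ndarray, vy: np.ndarray) -> float:
    """Shoelace area of the closed polygon (absolute value)."""
    return float(
        abs(np.sum(vx * np.roll(vy, -1) - np.roll(vx, -1) * vy)) / 2.0
    )
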