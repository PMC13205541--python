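"""Synthetic Wood's-light facial images with known ground truth.

No clinical photographs are deposited with this tool, so every pipeline stage
is validated against generated patients: a dark, low-fluorescence facial
skin tone (an ellipse for the frontal view, a half-ellipse for the side
views) carrying bright bluish-white depigmented patches of known geometry.
Patches are unions of random overlapping discs — blob-like, matching the
macroscopic morphology of vitiligo — whose total area is tuned to a requested
coverage fraction of the face.  The generator also emits the operator-style
annotations: the face-outline polygon and deliberately rough, over-covering
ROI polygons (convex hulls of each patch dilated by a margin), so that
segmentation, not annotation, does the pixel-level work.

Everything is reproducible from the spec's integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import MultiPoint, Polygon as ShapelyPolygon

from .errors import GenerationError, ValidationError
from .image_model import (
    PatchMask,
    PolygonROI,
    ViewAnnotation,
    WoodsLightImage,
    rasterize_polygon,
    write_annotation,
    write_image,
    write_mask_png,
)

# Appearance defaults: background facial skin is dark and weakly fluorescent;
# depigmented patches gain patch_contrast*255 on the blue and green channels.
BACKGROUND_SKIN_RGB = (20, 20, 60)
OUTSIDE_FACE_RGB = (5, 5, 15)
ROI_DILATION_PX = 5.0


@dataclass(frozen=True)
class SyntheticPatientSpec:
    """Generation parameters for one synthetic patient.

    ``coverage_per_view`` is the requested fraction of face pixels that are
    depigmented in each view; ``patch_contrast`` the intensity gap between
    patch and background skin on a [0, 1] scale; ``noise_sd`` the Gaussian
    pixel noise standard deviation on the same scale.
    """

    seed: int
    views: tuple[str, ...] = ("frontal", "left", "right")
    image_size: tuple[int, int] = (256, 256)  # (width, height)
    coverage_per_view: float = 0.15
    n_patches_per_view: int = 3
    patch_contrast: float = 0.5
    noise_sd: float = 0.02
    illumination_gradient: bool = False

    def __post_init__(self) -> None:
        if not self.views:
            raise ValidationError("at least one view is required")
        if len(set(self.views)) != len(self.views):
            raise ValidationError(f"duplicate views: {self.views}")
        w, h = self.image_size
        if w < 32 or h < 32:
            raise ValidationError("image_size must be at least 32x32")
        if not 0.0 <= self.coverage_per_view <= 0.8:
            raise ValidationError("coverage_per_view must be in [0, 0.8]")
        if self.n_patches_per_view < 1:
            raise ValidationError("n_patches_per_view must be >= 1")
        if not 0.0 <= self.patch_contrast <= 1.0:
            raise ValidationError("patch_contrast must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SyntheticPatient:
    """Images, ground-truth masks and annotations for one synthetic patient."""

    spec: SyntheticPatientSpec
    images: dict[str, WoodsLightImage]
    truth_masks: dict[str, PatchMask]
    face_masks: dict[str, np.ndarray]
    annotations: dict[str, ViewAnnotation]
    realized_coverage: dict[str, float]
    patient_id: str = "synthetic"
    timepoint: str = "baseline"


def face_polygon(view: str, width: int, height: int) -> PolygonROI:
    """Analytic face outline: full ellipse (frontal) or half-ellipse (sides)."""
    cx, cy = width / 2.0, height / 2.0
    a, b = 0.38 * width, 0.44 * height
    if view == "frontal":
        theta = np.linspace(0, 2 * np.pi, 48, endpoint=False)
    elif view == "left":
        theta = np.linspace(np.pi / 2, 3 * np.pi / 2, 25)
    elif view == "right":
        theta = np.linspace(-np.pi / 2, np.pi / 2, 25)
    else:
        raise ValidationError(f"unknown view {view!r}")
    xs = cx + a * np.cos(theta)
    ys = cy + b * np.sin(theta)
    verts = tuple((float(x), float(y)) for x, y in zip(xs, ys))
    return PolygonROI(vertices=verts, kind="face_outline")


def _signed_distance(mask: np.ndarray) -> np.ndarray:
    """Positive inside the mask, negative outside, in pixel units."""
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    return inside - outside


def _top_k_mask(score: np.ndarray, eligible: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask selecting the k highest-scoring eligible pixels.

    Ties are broken by row-major pixel order, which keeps the selection
    deterministic and makes k = |eligible ∩ positive| reproduce the exact
    source mask when scores are a distance transform.
    """
    out = np.zeros(score.shape, dtype=bool)
    if k <= 0:
        return out
    idx = np.flatnonzero(eligible)
    order = np.argsort(-score.ravel()[idx], kind="stable")
    out.ravel()[idx[order[:k]]] = True
    return out


def _blob_field(
    rng: np.random.Generator,
    face_mask: np.ndarray,
    n_patches: int,
    target_pixels: int,
) -> np.ndarray:
    """Union of n_patches disc-cluster blobs seeded inside the face."""
    h, w = face_mask.shape
    base_r = max(2.0, 0.7 * np.sqrt(target_pixels / n_patches / np.pi))
    depth = ndimage.distance_transform_edt(face_mask)
    candidates = np.flatnonzero(depth > 1.2 * base_r)
    if candidates.size == 0:
        candidates = np.flatnonzero(face_mask)
    if candidates.size == 0:
        raise GenerationError("face mask is empty")
    yy, xx = np.mgrid[0:h, 0:w]
    blob = np.zeros((h, w), dtype=bool)
    centers = rng.choice(candidates, size=n_patches, replace=False
                         if candidates.size >= n_patches else True)
    for c in np.atleast_1d(centers):
        cy, cx = divmod(int(c), w)
        n_discs = int(rng.integers(3, 7))
        px, py = float(cx), float(cy)
        for _ in range(n_discs):
            r = float(rng.uniform(0.5, 1.1) * base_r)
            blob |= (xx - px) ** 2 + (yy - py) ** 2 <= r * r
            px += float(rng.normal(0, 0.8 * base_r))
            py += float(rng.normal(0, 0.8 * base_r))
    return blob & face_mask


def _patch_rois(truth: np.ndarray) -> tuple[PolygonROI, ...]:
    """One rough, over-covering polygon per connected patch component."""
    labels, n = ndimage.label(truth)
    rois = []
    for i in range(1, n + 1):
        ys, xs = np.nonzero(labels == i)
        pts = np.column_stack([xs + 0.5, ys + 0.5]).astype(float)
        try:
            hull = ConvexHull(pts)
            poly = ShapelyPolygon(pts[hull.vertices])
        except QhullError:  # tiny or collinear component
            poly = MultiPoint(pts).buffer(1.0).convex_hull
        dilated = poly.buffer(ROI_DILATION_PX, quad_segs=2)
        verts = tuple(
            (float(x), float(y)) for x, y in dilated.exterior.coords[:-1]
        )
        rois.append(PolygonROI(vertices=verts, kind="patch"))
    return tuple(rois)


def _render_view(
    rng: np.random.Generator,
    face_mask: np.ndarray,
    truth: np.ndarray,
    contrast: float,
    noise_sd: float,
    gradient: bool,
) -> np.ndarray:
    h, w = face_mask.shape
    img = np.empty((h, w, 3), dtype=np.float64)
    img[...] = OUTSIDE_FACE_RGB
    img[face_mask] = BACKGROUND_SKIN_RGB
    boost = contrast * 255.0
    img[truth, 1] += boost  # green
    img[truth, 2] += boost  # blue: Wood's-light fluorescence is bluish-white
    if gradient:
        ramp = np.linspace(0.85, 1.15, w)[np.newaxis, :, np.newaxis]
        img = img * ramp
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd * 255.0, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def _generate_view(
    spec: SyntheticPatientSpec,
    view: str,
    geometry_rng: np.random.Generator,
    noise_rng: np.random.Generator,
) -> tuple[WoodsLightImage, PatchMask, np.ndarray, ViewAnnotation, float]:
    w, h = spec.image_size
    face_poly = face_polygon(view, w, h)
    face_mask = rasterize_polygon(face_poly, w, h)
    face_px = int(face_mask.sum())
    if face_px == 0:
        raise GenerationError(f"face polygon rasterised to nothing for {view}")
    target = int(round(spec.coverage_per_view * face_px))

    if target == 0:
        truth = np.zeros((h, w), dtype=bool)
        rois: tuple[PolygonROI, ...] = ()
    else:
        truth = None
        for _ in range(5):  # bounded retries if the blob field degenerates
            blob = _blob_field(
                geometry_rng, face_mask, spec.n_patches_per_view, target
            )
            if blob.any():
                truth = _top_k_mask(_signed_distance(blob), face_mask, target)
                break
        if truth is None or not truth.any():
            raise GenerationError(
                f"could not reach coverage {spec.coverage_per_view} in view "
                f"{view}"
            )
        rois = _patch_rois(truth)

    ann = ViewAnnotation(view=view, face=face_poly, patches=rois)
    pixels = _render_view(
        noise_rng,
        face_mask,
        truth,
        spec.patch_contrast,
        spec.noise_sd,
        spec.illumination_gradient,
    )
    img = WoodsLightImage(pixels=pixels, view=view, patient_id="synthetic")
    coverage = truth.sum() / face_px
    return img, PatchMask(truth), face_mask, ann, float(coverage)


def _view_rngs(seed: int, view_idx: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), view_idx, stream])
    )


def generate_patient(spec: SyntheticPatientSpec) -> SyntheticPatient:
    """Generate one synthetic patient; bit-identical for identical specs."""
    images, truths, faces, anns, realized = {}, {}, {}, {}, {}
    for i, view in enumerate(spec.views):
        img, truth, face_mask, ann, cov = _generate_view(
            spec, view, _view_rngs(spec.seed, i, 0), _view_rngs(spec.seed, i, 1)
        )
        images[view] = img
        truths[view] = truth
        faces[view] = face_mask
        anns[view] = ann
        realized[view] = cov
    return SyntheticPatient(
        spec=spec,
        images=images,
        truth_masks=truths,
        face_masks=faces,
        annotations=anns,
        realized_coverage=realized,
    )


def generate_longitudinal_pair(
    spec: SyntheticPatientSpec, repigmentation_fraction: float
) -> tuple[SyntheticPatient, SyntheticPatient]:
    """A before/after pair emulating treatment response.

    The after-timepoint reuses the before geometry with every patch shrunk
    (uniform inward erosion via the distance transform) so that total truth
    coverage is (1 − repigmentation_fraction) × the before coverage.
    """
    if not 0.0 <= repigmentation_fraction <= 1.0:
        raise ValidationError("repigmentation_fraction must be in [0, 1]")
    before = generate_patient(spec)
    images, truths, anns, realized = {}, {}, {}, {}
    for i, view in enumerate(spec.views):
        truth_before = before.truth_masks[view].grid
        face_mask = before.face_masks[view]
        n_before = int(truth_before.sum())
        target = int(round((1.0 - repigmentation_fraction) * n_before))
        depth = ndimage.distance_transform_edt(truth_before)
        truth_after = _top_k_mask(depth, truth_before, target)
        pixels = _render_view(
            _view_rngs(spec.seed, i, 2),
            face_mask,
            truth_after,
            spec.patch_contrast,
            spec.noise_sd,
            spec.illumination_gradient,
        )
        images[view] = WoodsLightImage(
            pixels=pixels, view=view, patient_id="synthetic",
            timepoint="followup",
        )
        truths[view] = PatchMask(truth_after)
        # The operator re-circles the patches still visible at follow-up;
        # a fully repigmented patch gets no ROI.
        anns[view] = ViewAnnotation(
            view=view,
            face=before.annotations[view].face,
            patches=_patch_rois(truth_after),
        )
        face_px = int(face_mask.sum())
        realized[view] = float(truth_after.sum() / face_px)
    after = SyntheticPatient(
        spec=spec,
        images=images,
        truth_masks=truths,
        face_masks=before.face_masks,
        annotations=anns,
        realized_coverage=realized,
        timepoint="followup",
    )
    return before, after


def write_patient(patient: SyntheticPatient, out_dir: str | Path) -> Path:
    """Write images (PNG), truth masks (PNG), annotations and manifest (JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": patient.spec.seed,
        "timepoint": patient.timepoint,
        "views": list(patient.spec.views),
        "coverage_requested": patient.spec.coverage_per_view,
        "realized_coverage": patient.realized_coverage,
        "files": {},
    }
    for view in patient.spec.views:
        stem = f"{patient.timepoint}_{view}"
        write_image(out / f"{stem}.png", patient.images[view])
        write_mask_png(out / f"{stem}_truth.png", patient.truth_masks[view])
        write_annotation(out / f"{stem}.json", patient.annotations[view])
        manifest["files"][view] = {
            "image": f"{stem}.png",
            "truth_mask": f"{stem}_truth.png",
            "annotation": f"{stem}.json",
        }
    (out / f"manifest_{patient.timepoint}.json").write_text(
        json.dumps(manifest, indent=1)
    )
    return out
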