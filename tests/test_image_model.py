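import json
import math

import imageio.v3 as iio
import numpy as np
import pytest
import shapely
from hypothesis import assume, given, strategies as st
from shapely.geometry import Polygon as ShapelyPolygon

from fviq.errors import InputError, ValidationError
from fviq.image_model import (
    PolygonROI,
    ViewAnnotation,
    WoodsLightImage,
    annotation_to_json,
    rasterize_polygon,
    read_annotation,
    read_image,
    write_annotation,
)

from conftest import bruteforce_rasterize


class TestReadImage:
    def test_black_png(self, tmp_path):
        iio.imwrite(tmp_path / "z.png", np.zeros((4, 4, 3), dtype=np.uint8))
        img = read_image(tmp_path / "z.png", view="frontal")
        assert (img.width, img.height) == (4, 4)
        assert img.pixels.dtype == np.uint8
        assert np.all(img.pixels == 0)

    def test_16bit_tiff_range_endpoints(self, tmp_path):
        arr = np.array([[0, 65535], [65535, 0]], dtype=np.uint16)
        iio.imwrite(tmp_path / "t.tiff", arr)
        img = read_image(tmp_path / "t.tiff")
        assert img.pixels.max() == 255 and img.pixels.min() == 0
        # grayscale replicated to three identical channels
        assert np.array_equal(img.pixels[..., 0], img.pixels[..., 2])

    def test_synthetic_roundtrip_three_views(self, small_patient, tmp_path):
        from fviq.synthetic import write_patient

        write_patient(small_patient, tmp_path)
        views = {}
        for v in ("frontal", "left", "right"):
            views[v] = read_image(tmp_path / f"baseline_{v}.png", view=v)
        assert {img.view for img in views.values()} == {
            "frontal", "left", "right"
        }
        for v, img in views.items():
            assert np.array_equal(
                img.pixels, small_patient.images[v].pixels
            )

    def test_missing_file_names_path(self, tmp_path):
        with pytest.raises(InputError, match="nope.png"):
            read_image(tmp_path / "nope.png")

    def test_metadata_is_explicit_not_guessed(self, tmp_path):
        iio.imwrite(
            tmp_path / "frontal_p1.png", np.zeros((2, 2, 3), dtype=np.uint8)
        )
        img = read_image(tmp_path / "frontal_p1.png", view="left")
        assert img.view == "left"

    def test_invalid_view_rejected(self):
        with pytest.raises(ValidationError):
            WoodsLightImage(
                pixels=np.zeros((2, 2, 3), dtype=np.uint8), view="back"
            )


class TestAnnotationIO:
    SQUARE = ((0.0, 0.0), (10.0, 0.0), (10.0, 10.0), (0.0, 10.0))
    TRI = ((1.0, 1.0), (5.0, 1.0), (3.0, 4.0))

    def _write(self, tmp_path, doc):
        p = tmp_path / "ann.json"
        p.write_text(json.dumps(doc))
        return p

    def test_minimal_document(self, tmp_path):
        p = self._write(tmp_path, {
            "view": "frontal",
            "face": {"vertices": [list(v) for v in self.SQUARE]},
            "patches": [{"vertices": [list(v) for v in self.TRI]}],
        })
        ann = read_annotation(p)
        assert len(ann.patches) == 1
        assert ann.patches[0].threshold_override is None

    def test_out_of_range_override(self, tmp_path):
        p = self._write(tmp_path, {
            "view": "frontal",
            "face": {"vertices": [list(v) for v in self.SQUARE]},
            "patches": [{"vertices": [list(v) for v in self.TRI],
                         "threshold": 1.5}],
        })
        with pytest.raises(ValidationError):
            read_annotation(p)

    def test_overrides_preserved_per_patch(self, tmp_path):
        p = self._write(tmp_path, {
            "view": "left",
            "face": {"vertices": [list(v) for v in self.SQUARE]},
            "patches": [
                {"vertices": [list(v) for v in self.TRI]},
                {"vertices": [list(v) for v in self.TRI], "threshold": 0.4},
            ],
        })
        ann = read_annotation(p)
        assert [r.threshold_override for r in ann.patches] == [None, 0.4]

    def test_missing_face_outline(self, tmp_path):
        p = self._write(tmp_path, {"view": "frontal", "patches": []})
        with pytest.raises(ValidationError, match="face"):
            read_annotation(p)

    def test_self_intersecting_polygon_names_roi(self, tmp_path):
        bowtie = [[0, 0], [4, 4], [4, 0], [0, 4]]
        p = self._write(tmp_path, {
            "view": "frontal",
            "face": {"vertices": [list(v) for v in self.SQUARE]},
            "patches": [{"vertices": bowtie}],
        })
        with pytest.raises(ValidationError, match="ROI 0"):
            read_annotation(p)

    def test_roundtrip_is_bit_exact(self, tmp_path):
        verts = ((0.125, 0.3), (7.7500001, 0.1), (5.5, 9.999999999))
        ann = ViewAnnotation(
            view="right",
            face=PolygonROI(self.SQUARE, kind="face_outline"),
            patches=(PolygonROI(verts, threshold_override=0.325),),
        )
        write_annotation(tmp_path / "a.json", ann)
        back = read_annotation(tmp_path / "a.json")
        assert back.face.vertices == ann.face.vertices
        assert back.patches[0].vertices == verts
        assert back.patches[0].threshold_override == 0.325
        assert annotation_to_json(back) == annotation_to_json(ann)


def star_polygons(max_coord=63, max_vertices=10):
    """Simple star-shaped polygons: unique lattice points + 0.25 offset,
    sorted by angle around their centroid."""

    @st.composite
    def strat(draw):
        pts = draw(st.lists(
            st.tuples(st.integers(0, max_coord), st.integers(0, max_coord)),
            min_size=3, max_size=max_vertices, unique=True,
        ))
        pts = [(x + 0.25, y + 0.25) for x, y in pts]
        cx = sum(p[0] for p in pts) / len(pts)
        cy = sum(p[1] for p in pts) / len(pts)
        pts.sort(key=lambda p: math.atan2(p[1] - cy, p[0] - cx))
        return tuple(pts)

    return strat()


class TestRasterize:
    @pytest.mark.parametrize("w,h", [(1, 1), (3, 7), (10, 10)])
    def test_axis_aligned_rectangle_area(self, w, h):
        rect = ((0.0, 0.0), (w, 0.0), (w, h), (0.0, h))
        mask = rasterize_polygon(rect, 20, 20)
        assert int(mask.sum()) == w * h

    def test_square_on_grid_derived_count(self):
        # brute-force point-in-polygon over all 400 pixel centres gives 100
        square = ((0.0, 0.0), (10.0, 0.0), (10.0, 10.0), (0.0, 10.0))
        mask = rasterize_polygon(square, 20, 20)
        expected = bruteforce_rasterize(square, 20, 20)
        assert int(expected.sum()) == 100
        assert np.array_equal(mask, expected)

    def test_polygon_outside_image_is_clipped(self):
        far = ((100.0, 100.0), (110.0, 100.0), (105.0, 110.0))
        assert not rasterize_polygon(far, 8, 8).any()

    def test_degenerate_polygon_warns_and_is_empty(self, caplog):
        line = ((0.0, 0.0), (5.0, 5.0), (10.0, 10.0))
        with caplog.at_level("WARNING"):
            mask = rasterize_polygon(line, 8, 8)
        assert not mask.any()
        assert any("degenerate" in r.message for r in caplog.records)

    def test_deterministic(self):
        tri = ((0.2, 0.1), (30.4, 4.4), (12.0, 28.9))
        assert np.array_equal(
            rasterize_polygon(tri, 32, 32), rasterize_polygon(tri, 32, 32)
        )

    @given(poly=star_polygons())
    def test_matches_bruteforce_even_odd_oracle(self, poly):
        vx = [p[0] for p in poly]
        vy = [p[1] for p in poly]
        area = abs(sum(
            vx[i] * vy[(i + 1) % len(poly)] - vx[(i + 1) % len(poly)] * vy[i]
            for i in range(len(poly))
        )) / 2
        assume(area > 0.5)
        mask = rasterize_polygon(poly, 64, 64)
        assert np.array_equal(mask, bruteforce_rasterize(poly, 64, 64))

    def test_matches_shapely_on_convex_polygon(self):
        hexagon = tuple(
            (16 + 10 * math.cos(t) + 0.2, 16 + 8 * math.sin(t) + 0.2)
            for t in np.linspace(0, 2 * math.pi, 6, endpoint=False)
        )
        mask = rasterize_polygon(hexagon, 32, 32)
        shp = ShapelyPolygon(hexagon)
        xs, ys = np.meshgrid(np.arange(32) + 0.5, np.arange(32) + 0.5)
        oracle = shapely.contains_xy(shp, xs.ravel(), ys.ravel()).reshape(
            32, 32
        )
        assert np.array_equal(mask, oracle)
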