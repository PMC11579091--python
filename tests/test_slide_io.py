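"""I/O: images, metadata tables, stacks, annotations."""

import numpy as np
import pytest
import tifffile
from PIL import Image as PILImage

from brainslide.slide_io import (
    MetadataTable,
    TemplateStack,
    mask_from_polygon,
    read_annotations,
    read_image,
    read_metadata,
    read_stack,
    roi_from_mask,
    write_annotations,
    write_image,
    write_metadata,
    write_stack,
)


class TestReadImage:
    def test_white_png_reads_as_ones(self, tmp_path):
        p = tmp_path / "white.png"
        PILImage.fromarray(np.full((8, 8), 255, np.uint8)).save(p)
        img = read_image(p)
        np.testing.assert_allclose(img.pixels, 1.0)

    def test_16bit_tiff_full_scale(self, tmp_path):
        p = tmp_path / "t.tif"
        tifffile.imwrite(p, np.full((8, 8), 65535, np.uint16))
        np.testing.assert_allclose(read_image(p).pixels, 1.0)

    def test_rgb_collapses_to_luminance(self, tmp_path):
        p = tmp_path / "rgb.png"
        arr = np.zeros((4, 4, 3), np.uint8)
        arr[..., 0] = 255  # pure red
        PILImage.fromarray(arr).save(p)
        np.testing.assert_allclose(read_image(p).pixels, 0.299, atol=1e-3)

    def test_truncated_file_errors_with_path(self, tmp_path):
        p = tmp_path / "broken.png"
        p.write_bytes(b"\x89PNG\r\n\x1a\n junk")
        with pytest.raises(IOError, match="broken.png"):
            read_image(p)

    def test_round_trip(self, tmp_path, brain):
        p = tmp_path / "b.png"
        write_image(brain.image, p)
        back = read_image(p)
        assert np.abs(back.pixels - brain.image.pixels).max() <= 1 / 255 + 1e-9


class TestMetadata:
    def _write_csv(self, tmp_path, rows):
        p = tmp_path / "layout.csv"
        p.write_text("\n".join(",".join(r) for r in rows))
        return p

    def test_full_2x3_table(self, tmp_path):
        p = self._write_csv(tmp_path, [["A1", "A2", "A3"], ["A4", "A5", "A6"]])
        t = read_metadata(p)
        assert (t.n_rows, t.n_cols, t.n_filled) == (2, 3, 6)

    def test_blank_cell_is_explicitly_empty(self, tmp_path):
        p = self._write_csv(tmp_path, [["A1", "", "A3"], ["A4", "A5", "A6"]])
        t = read_metadata(p)
        assert t.n_filled == 5 and (0, 1) not in t.cells

    def test_duplicate_label_rejected(self, tmp_path):
        p = self._write_csv(tmp_path, [["A1", "A1"]])
        with pytest.raises(ValueError, match="A1"):
            read_metadata(p)

    def test_empty_table_rejected(self, tmp_path):
        p = self._write_csv(tmp_path, [["", ""], ["", ""]])
        with pytest.raises(ValueError, match="empty"):
            read_metadata(p)

    def test_xlsx_round_trip_with_groups(self, tmp_path):
        t = MetadataTable(
            {(0, 0): ("S1", "ctrl"), (0, 1): ("S2", "trt"), (1, 0): ("S3", "ctrl")},
            n_rows=2,
            n_cols=2,
        )
        p = tmp_path / "layout.xlsx"
        write_metadata(t, p)
        back = read_metadata(p)
        assert back.cells == t.cells

    def test_out_of_bounds_cell_rejected(self):
        with pytest.raises(ValueError):
            MetadataTable({(2, 0): ("S1", "")}, n_rows=2, n_cols=2)


class TestAnnotations:
    def _square_roi(self, name="CP", lo=10, hi=30, shape=(48, 48)):
        mask = np.zeros(shape, bool)
        mask[lo:hi, lo:hi] = True
        return roi_from_mask(name, mask, source_layer=3)

    def test_geojson_round_trip(self, tmp_path):
        rois = [self._square_roi("CP"), self._square_roi("aco", 34, 44)]
        p = tmp_path / "a.geojson"
        write_annotations(rois, p, format="geojson")
        back = read_annotations(p, shape=(48, 48))
        assert [r.name for r in back] == ["CP", "aco"]
        for orig, rec in zip(rois, back):
            assert rec.source_layer == 3
            np.testing.assert_allclose(orig.polygons[0], rec.polygons[0])

    def test_label_mask_round_trip_exact(self, tmp_path):
        rois = [self._square_roi("CP"), self._square_roi("aco", 34, 44)]
        p = tmp_path / "mask.png"
        write_annotations(rois, p, format="label_mask_png")
        back = read_annotations(p)
        for orig, rec in zip(rois, back):
            assert rec.name == orig.name
            assert np.array_equal(rec.mask, orig.mask)

    def test_overlapping_rois_rejected_in_mask_mode(self, tmp_path):
        rois = [self._square_roi("CP"), self._square_roi("CP2", 20, 40)]
        with pytest.raises(ValueError, match="overlap"):
            write_annotations(rois, tmp_path / "m.png", format="label_mask_png")

    def test_polygon_mask_agreement_band(self, brain):
        """Rasterized polygon and stored mask agree within a 1-px boundary."""
        from scipy.ndimage import binary_dilation, binary_erosion

        for roi in brain.rois:
            re_mask = mask_from_polygon(roi.polygons, roi.mask.shape)
            disagreement = re_mask ^ roi.mask
            band = binary_dilation(roi.mask) & ~binary_erosion(roi.mask)
            assert np.all(band[disagreement])

    def test_square_roi_gives_closed_five_point_ring(self):
        roi = self._square_roi()
        assert len(roi.polygons) == 1
        ring = roi.polygons[0]
        assert len(ring) == 5
        np.testing.assert_allclose(ring[0], ring[-1])

    def test_mask_polygon_mask_round_trip_exact(self, brain):
        for roi in brain.rois:
            re_mask = mask_from_polygon(roi.polygons, roi.mask.shape)
            assert np.array_equal(re_mask, roi.mask)

    def test_convex_polygon_area_round_trip(self):
        mask = np.zeros((64, 64), bool)
        yy, xx = np.mgrid[0:64, 0:64]
        mask[(xx - 32) ** 2 / 169 + (yy - 32) ** 2 / 100 < 1] = True  # 26x20 ellipse
        roi = roi_from_mask("e", mask)
        re_mask = mask_from_polygon(roi.polygons, mask.shape)
        assert abs(re_mask.sum() - mask.sum()) / mask.sum() < 0.02


class TestStack:
    def test_round_trip(self, tmp_path, stack_and_brains):
        stack, _ = stack_and_brains
        d = tmp_path / "stack"
        write_stack(stack, d)
        back = read_stack(d)
        assert back.layer_ids == stack.layer_ids
        for (_, img_a, masks_a), (_, img_b, masks_b) in zip(stack.layers, back.layers):
            assert np.abs(img_a.pixels - img_b.pixels).max() <= 1 / 255 + 1e-9
            for name in masks_a:
                assert np.array_equal(masks_a[name], masks_b[name])

    def test_non_increasing_ids_rejected(self, stack_and_brains):
        stack, _ = stack_and_brains
        layers = [stack.layers[1], stack.layers[0]]
        with pytest.raises(ValueError, match="increasing"):
            TemplateStack(layers)

    def test_empty_directory_rejected(self, tmp_path):
        with pytest.raises(IOError):
            read_stack(tmp_path)
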