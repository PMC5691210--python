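"""Image reading, channel grouping, summary writing, overlay rendering."""

import numpy as np
import pandas as pd
import pytest
import tifffile

from histopipes.imgio import (
    ChannelSet,
    StackError,
    group_channels,
    list_images,
    read_image,
    render_overlay,
    write_image,
    write_summary,
)


class TestReadImage:
    def test_white_png_identity(self, tmp_path):
        path = tmp_path / "white.png"
        write_image(path, np.full((2, 2, 3), 255, np.uint8))
        out = read_image(path)
        assert out.shape == (2, 2, 3) and (out == 255).all()

    def test_8bit_roundtrip_pixel_exact(self, tmp_path, rng):
        img = rng.integers(0, 256, (13, 17), dtype=np.uint8)
        for ext in ("png", "tif"):
            path = tmp_path / f"img.{ext}"
            write_image(path, img)
            assert np.array_equal(read_image(path), img)

    def test_16bit_tiff_rescaled_to_dtype_max(self, tmp_path):
        img16 = np.array([[0, 32768], [49152, 65535]], dtype=np.uint16)
        path = tmp_path / "deep.tif"
        tifffile.imwrite(path, img16)
        out = read_image(path)
        assert out.dtype == np.uint8
        assert out[1, 1] == 255 and out[0, 0] == 0  # min -> 0, dtype max -> 255

    def test_multipage_tiff_refused(self, tmp_path, rng):
        stack = rng.integers(0, 255, (3, 8, 8), dtype=np.uint8)
        path = tmp_path / "stack.tif"
        tifffile.imwrite(path, stack)
        with pytest.raises(StackError, match="split stacks"):
            read_image(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_image(tmp_path / "nope.png")

    def test_corrupt_file_is_io_error(self, tmp_path):
        path = tmp_path / "bad.png"
        path.write_bytes(b"this is not an image")
        with pytest.raises(OSError, match="bad.png"):
            read_image(path)


class TestGroupChannels:
    MAP = {"foci": "Ch00", "nuclei": "Ch01", "cytoplasm": "Ch02"}

    def _write(self, folder, name):
        write_image(folder / name, np.zeros((4, 4), np.uint8))

    def test_complete_triple_grouped(self, tmp_path):
        for s in ("Ch00", "Ch01", "Ch02"):
            self._write(tmp_path, f"a_{s}.tif")
        sets = group_channels(tmp_path, self.MAP)
        assert len(sets) == 1
        assert sets[0].base_name == "a_"
        assert sets[0].cytoplasm is not None

    def test_incomplete_group_skipped_with_warning(self, tmp_path, caplog):
        self._write(tmp_path, "a_Ch00.tif")
        with caplog.at_level("WARNING"):
            sets = group_channels(tmp_path, self.MAP)
        assert sets == []
        assert any("a_" in rec.message for rec in caplog.records)

    def test_partition_and_sorted_order(self, tmp_path):
        for base in ("c", "a", "b"):
            for s in ("Ch00", "Ch01", "Ch02"):
                self._write(tmp_path, f"{base}_{s}.tif")
        self._write(tmp_path, "d_Ch00.tif")  # incomplete
        sets = group_channels(tmp_path, self.MAP)
        assert [s.base_name for s in sets] == ["a_", "b_", "c_"]
        paths = [p for s in sets for p in s.paths.values()]
        assert len(paths) == len(set(paths))  # no file in two sets

    def test_cytoplasm_optional(self, tmp_path):
        self._write(tmp_path, "x_Ch00.tif")
        self._write(tmp_path, "x_Ch01.tif")
        sets = group_channels(tmp_path, {"foci": "Ch00", "nuclei": "Ch01"})
        assert len(sets) == 1 and sets[0].cytoplasm is None

    def test_missing_required_role_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            group_channels(tmp_path, {"foci": "Ch00"})


class TestChannelSet:
    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ChannelSet("x", foci=np.zeros((4, 4)), nuclei=np.zeros((5, 5)))

    def test_empty_base_name_rejected(self):
        with pytest.raises(ValueError):
            ChannelSet("", foci=np.zeros((4, 4)), nuclei=np.zeros((4, 4)))


class TestWriteSummary:
    def test_header_plus_one_row_per_image(self, tmp_path):
        df = pd.DataFrame([{"image": "a.png", "count": 3}])
        out = tmp_path / "summary.csv"
        write_summary(df, out)
        lines = out.read_text().strip().splitlines()
        assert len(lines) == 2 and lines[0] == "image,count"

    def test_overwrite_is_byte_identical_not_appending(self, tmp_path):
        df = pd.DataFrame({"image": [f"i{k}.png" for k in range(5)], "v": range(5)})
        out = tmp_path / "summary.csv"
        write_summary(df, out)
        first = out.read_bytes()
        write_summary(df, out)
        assert out.read_bytes() == first

    def test_empty_table_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_summary(pd.DataFrame(), tmp_path / "s.csv")


class TestRenderOverlay:
    def test_empty_mask_identity(self, rng):
        img = rng.integers(0, 256, (10, 10, 3)).astype(np.uint8)
        out = render_overlay(img, [(np.zeros((10, 10), bool), (255, 0, 0))])
        assert np.array_equal(out, img)
        assert out is not img

    def test_five_square_contour_pixel_count(self):
        img = np.zeros((11, 11, 3), np.uint8)
        mask = np.zeros((11, 11), bool)
        mask[3:8, 3:8] = True
        out = render_overlay(img, [(mask, (255, 0, 0))])
        red = (out[:, :, 0] == 255) & (out[:, :, 1] == 0)
        assert int(red.sum()) == 16  # 5x5 square has a 16-px perimeter ring

    def test_full_mask_recolors_only_border_ring(self):
        img = np.full((8, 8, 3), 90, np.uint8)
        out = render_overlay(img, [(np.ones((8, 8), bool), (0, 255, 0))])
        green = (out == np.array([0, 255, 0])).all(axis=2)
        assert green[0].all() and green[-1].all()
        assert green[:, 0].all() and green[:, -1].all()
        assert not green[1:-1, 1:-1].any()

    def test_points_drawn_as_crosses(self):
        img = np.zeros((9, 9, 3), np.uint8)
        out = render_overlay(img, [([(4.0, 4.0)], (0, 0, 255))])
        blue = (out[:, :, 2] == 255)
        assert int(blue.sum()) == 5
        assert blue[4, 4] and blue[3, 4] and blue[4, 3]

    def test_pixels_outside_layers_untouched(self, rng):
        img = rng.integers(0, 200, (12, 12, 3)).astype(np.uint8)
        mask = np.zeros((12, 12), bool)
        mask[2:5, 2:5] = True
        out = render_overlay(img, [(mask, (255, 255, 0))])
        from histopipes.imgio import _contour

        untouched = ~_contour(mask)
        assert np.array_equal(out[untouched], img[untouched])

    def test_dimension_mismatch_rejected(self, rng):
        img = rng.integers(0, 255, (10, 10, 3)).astype(np.uint8)
        with pytest.raises(ValueError):
            render_overlay(img, [(np.zeros((5, 5), bool), (255, 0, 0))])


def test_list_images_nonrecursive_case_insensitive(tmp_path):
    write_image(tmp_path / "a.PNG".lower(), np.zeros((2, 2), np.uint8))
    (tmp_path / "b.TIF").write_bytes((tmp_path / "a.png").read_bytes())  # wrong bytes, right ext
    (tmp_path / "notes.txt").write_text("ignored")
    sub = tmp_path / "sub"
    sub.mkdir()
    write_image(sub / "c.png", np.zeros((2, 2), np.uint8))
    names = [p.name for p in list_images(tmp_path)]
    assert names == ["a.png", "b.TIF"]
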