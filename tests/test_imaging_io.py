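"""Image/mask loading, registries, subtraction, and table round trips."""

import numpy as np
import pandas as pd
import pytest
from PIL import Image

import fishrad as fr
from fishrad.errors import (
    AlignmentError,
    EmptyMaskError,
    FormatError,
    LoadError,
    MergeError,
)
from fishrad.study import (
    FeatureTable,
    export_feature_table,
    import_feature_table,
)


def _write(tmp_path, name, arr, mode=None):
    path = tmp_path / name
    Image.fromarray(arr, mode=mode).save(path)
    return path


class TestLoadImage:
    def test_constant_png_preserves_values_and_unit_spacing(self, tmp_path):
        path = _write(tmp_path, "c.png", np.full((5, 7), 100, dtype=np.uint8))
        vol = fr.load_image(path)
        assert vol.pixels.shape == (5, 7)
        assert np.all(vol.pixels == 100.0)
        assert vol.spacing == (1.0, 1.0, 1.0)

    def test_rgb_converted_with_bt601_luma(self, tmp_path):
        rgb = np.zeros((2, 2, 3), dtype=np.uint8)
        rgb[..., 0] = 255  # pure red
        path = _write(tmp_path, "red.png", rgb)
        vol = fr.load_image(path)
        assert vol.pixels == pytest.approx(np.full((2, 2), 0.299 * 255))

    def test_gray_conversion_is_idempotent(self, tmp_path):
        arr = (np.arange(64).reshape(8, 8) * 3).astype(np.uint8)
        path = _write(tmp_path, "g.png", arr)
        once = fr.load_image(path).pixels
        assert np.array_equal(once, arr.astype(float))

    def test_explicit_spacing_respected(self, tmp_path):
        path = _write(tmp_path, "s.png", np.full((3, 3), 9, dtype=np.uint8))
        vol = fr.load_image(path, spacing=(2.5, 2.5, 1.0))
        assert vol.spacing == (2.5, 2.5, 1.0)

    def test_unsupported_extension_raises_format_error(self, tmp_path):
        bad = tmp_path / "img.bmp"
        bad.write_bytes(b"BM")
        with pytest.raises(FormatError):
            fr.load_image(bad)

    def test_unreadable_file_names_the_path(self, tmp_path):
        bad = tmp_path / "broken.png"
        bad.write_bytes(b"not a png")
        with pytest.raises(LoadError, match="broken.png"):
            fr.load_image(bad)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(LoadError):
            fr.load_image(tmp_path / "absent.png")


class TestLoadMask:
    def test_white_rectangle_binarizes_exactly(self, tmp_path):
        arr = np.zeros((20, 20), dtype=np.uint8)
        arr[5:10, 3:12] = 255
        parent = fr.ImageVolume(np.zeros((20, 20)))
        mask = fr.load_mask(_write(tmp_path, "m.png", arr), "roi", parent)
        expected = arr > 0
        assert np.array_equal(mask.pixels, expected)
        assert mask.name == "roi"

    def test_compression_speckle_thresholded_at_half_dtype_max(self, tmp_path):
        # values 3 (dark speckle) and 250 (bright speckle) at threshold 127.5
        arr = np.array([[3, 250]], dtype=np.uint8)
        parent = fr.ImageVolume(np.zeros((1, 2)))
        mask = fr.load_mask(_write(tmp_path, "s.png", arr), "roi", parent)
        assert mask.pixels.tolist() == [[False, True]]

    def test_binarization_invariant_to_lossless_reencode(self, tmp_path):
        rng = np.random.default_rng(0)
        arr = (rng.random((16, 16)) > 0.5).astype(np.uint8) * 255
        parent = fr.ImageVolume(np.zeros((16, 16)))
        p1 = _write(tmp_path, "a.png", arr)
        with Image.open(p1) as im:
            im.save(tmp_path / "b.png")  # re-encode losslessly
        m1 = fr.load_mask(p1, "roi", parent)
        m2 = fr.load_mask(tmp_path / "b.png", "roi", parent)
        assert np.array_equal(m1.pixels, m2.pixels)

    def test_dimension_mismatch_raises_alignment_error(self, tmp_path):
        arr = np.full((100, 100), 255, dtype=np.uint8)
        parent = fr.ImageVolume(np.zeros((200, 200)))
        with pytest.raises(AlignmentError):
            fr.load_mask(_write(tmp_path, "m.png", arr), "roi", parent)

    def test_all_black_mask_rejected(self, tmp_path):
        arr = np.zeros((8, 8), dtype=np.uint8)
        parent = fr.ImageVolume(np.zeros((8, 8)))
        with pytest.raises(EmptyMaskError):
            fr.load_mask(_write(tmp_path, "m.png", arr), "roi", parent)


class TestSubtractMasks:
    def _mask(self, arr, name="m"):
        return fr.NamedMask(arr, name, arr.shape)

    def test_whole_minus_organ(self):
        whole = np.zeros((10, 10), dtype=bool)
        whole[2:8, 2:8] = True
        organ = np.zeros((10, 10), dtype=bool)
        organ[4:6, 4:6] = True
        out = fr.subtract_masks(self._mask(whole, "fish"), self._mask(organ, "heart"),
                                "fish_minus_heart")
        assert np.array_equal(out.pixels, whole & ~organ)
        assert out.name == "fish_minus_heart"

    def test_self_subtraction_is_empty_error(self):
        m = np.ones((4, 4), dtype=bool)
        with pytest.raises(EmptyMaskError):
            fr.subtract_masks(self._mask(m), self._mask(m), "zero")

    def test_disjoint_subtraction_is_identity(self):
        a = np.zeros((6, 6), dtype=bool)
        a[:2] = True
        b = np.zeros((6, 6), dtype=bool)
        b[4:] = True
        out = fr.subtract_masks(self._mask(a, "a"), self._mask(b, "b"), "diff")
        assert np.array_equal(out.pixels, a)


class TestMaskRegistry:
    def test_register_is_idempotent_and_order_stable(self):
        reg = fr.MaskRegistry()
        for name in ["all_fish", "eye", "heart", "eye"]:
            fr.register_mask_name(reg, name)
        assert fr.list_mask_names(reg) == ["all_fish", "eye", "heart"]

    def test_case_study_registry_has_six_names_whole_animal_first(self):
        reg = fr.MaskRegistry(list(fr.REGION_NAMES))
        names = fr.list_mask_names(reg)
        assert len(names) == 6
        assert names[0] == "all_fish"
        assert set(names) == {"all_fish", "eye", "heart", "yolk", "head", "length"}

    def test_empty_registry_lists_nothing(self):
        assert fr.list_mask_names(fr.MaskRegistry()) == []

    def test_empty_name_rejected(self):
        with pytest.raises(ValueError):
            fr.register_mask_name(fr.MaskRegistry(), "")


def _toy_table(n_spec=2, regions=("all_fish", "eye"), n_feats=4, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    feats = [f"original_shape_F{i}" for i in range(n_feats)]
    for s in range(n_spec):
        for r in regions:
            rows.append({"specimen": f"s{s}", "region": r,
                         "label": "high" if s % 2 else "low",
                         **{f: rng.random() * 10.0 ** int(rng.integers(-8, 8)) for f in feats}})
    return FeatureTable(pd.DataFrame(rows), {"bin_count": 64, "mode": "none"})


class TestFeatureTableIO:
    def test_row_and_column_counts(self, tmp_path, tiny_cohort_table):
        _, table = tiny_cohort_table
        # 4 specimens x 6 regions, 3 key columns + 107 features
        assert table.n_rows == 24
        assert table.data.shape[1] == 3 + 107

    @pytest.mark.parametrize("fmt", ["csv", "xlsx"])
    def test_round_trip_is_identity(self, tmp_path, fmt):
        table = _toy_table()
        path = export_feature_table(table, tmp_path / f"t.{fmt}")
        back = import_feature_table(path, table.settings)
        assert list(back.data.columns) == list(table.data.columns)
        pd.testing.assert_frame_equal(back.data, table.data)

    def test_empty_table_export_rejected(self, tmp_path):
        empty = FeatureTable(pd.DataFrame(columns=["specimen", "region", "label"]))
        with pytest.raises(ValueError):
            export_feature_table(empty, tmp_path / "t.csv")


class TestImportStudy:
    def _manifest(self, tmp_path, study_id, names, settings):
        return fr.StudyManifest(
            study_id=study_id, registry=fr.MaskRegistry(list(names)),
            settings=dict(settings), specimens=[], root=tmp_path,
        )

    def test_matching_settings_merge(self, tmp_path):
        cur = self._manifest(tmp_path, "a", ["all_fish", "eye"], {"bin_count": 1, "mode": "none"})
        inc = self._manifest(tmp_path, "b", ["eye", "heart"], {"bin_count": 1, "mode": "none"})
        merged = fr.import_study(inc, cur)
        assert fr.list_mask_names(merged.registry) == ["all_fish", "eye", "heart"]

    def test_bin_count_mismatch_refused_with_key_names(self, tmp_path):
        cur = self._manifest(tmp_path, "a", ["eye"], {"bin_count": 1, "mode": "none"})
        inc = self._manifest(tmp_path, "b", ["eye"], {"bin_count": 64, "mode": "none"})
        with pytest.raises(MergeError, match="bin_count"):
            fr.import_study(inc, cur)

    def test_mode_mismatch_refused(self, tmp_path):
        cur = self._manifest(tmp_path, "a", ["eye"], {"bin_count": 64, "mode": "none"})
        inc = self._manifest(tmp_path, "b", ["eye"], {"bin_count": 64, "mode": "resample"})
        with pytest.raises(MergeError, match="mode"):
            fr.import_study(inc, cur)

    def test_manifest_json_round_trip(self, tmp_path):
        cur = self._manifest(tmp_path, "rt", ["all_fish", "eye"], {"bin_count": 64})
        path = cur.save(tmp_path / "manifest.json")
        back = fr.StudyManifest.load(path)
        assert back.study_id == "rt"
        assert fr.list_mask_names(back.registry) == ["all_fish", "eye"]
        assert back.settings == {"bin_count": 64}
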