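"""Patch tiling, GAP feature extraction and the merging/indexing law."""

import numpy as np
import pytest

from brainnext.errors import GeometryError
from brainnext.patch_features import (FeatureMatrix, divide_patches,
                                      exemplar_features,
                                      extract_gap_features, merge_features,
                                      reassemble, unmerge_features)


class TestPatchDivision:
    def test_224_yields_49_rowmajor_patches(self, rng):
        img = rng.random((224, 224, 3), dtype=np.float32)
        grid = divide_patches(img, 32)
        assert len(grid.patches) == 49
        assert grid.grid_shape == (7, 7)
        # 1-based origins follow the arithmetic i,j in {1, 33, ..., 193}
        assert grid.origins[0] == (1, 1)
        assert grid.origins[1] == (1, 33)
        assert grid.origins[7] == (33, 1)
        assert grid.origins[48] == (193, 193)
        # pixel-exact copies
        assert np.array_equal(grid.patches[8], img[32:64, 32:64])

    def test_patch_equal_to_image_is_identity(self, rng):
        img = rng.random((64, 64, 3), dtype=np.float32)
        grid = divide_patches(img, 64)
        assert len(grid.patches) == 1
        assert np.array_equal(grid.patches[0], img)

    @pytest.mark.parametrize("side,patch", [(64, 32), (96, 32), (224, 32)])
    def test_tiling_is_lossless_and_disjoint(self, side, patch, rng):
        img = rng.random((side, side, 3), dtype=np.float32)
        grid = divide_patches(img, patch)
        assert len(grid.patches) == (side // patch) ** 2
        assert np.array_equal(reassemble(grid), img)

    def test_non_divisible_geometry_rejected(self, rng):
        with pytest.raises(GeometryError, match="100.*32|32.*100"):
            divide_patches(rng.random((100, 100, 3)), 32)


class TestGapFeatures:
    def test_length_equals_final_stage_width(self, small_net, rng):
        img = rng.random((224, 224, 3), dtype=np.float32)
        fv = extract_gap_features(small_net, img)
        assert fv.shape == (small_net.feature_length(),)

    def test_matches_bruteforce_spatial_mean(self, small_net, rng):
        """GAP output equals the per-channel mean over all spatial
        positions of the final stage map, computed by explicit loop."""
        img = rng.random((224, 224, 3), dtype=np.float32)
        fv = extract_gap_features(small_net, img)
        fmap = small_net._last_feature_map[0]     # C x h x w
        c, h, w = fmap.shape
        brute = np.zeros(c)
        for ch in range(c):
            acc = 0.0
            for i in range(h):
                for j in range(w):
                    acc += float(fmap[ch, i, j])
            brute[ch] = acc / (h * w)
        assert np.allclose(fv, brute, rtol=1e-5)

    def test_zero_input_finite(self, small_net):
        fv = extract_gap_features(small_net, np.zeros((224, 224, 3),
                                                      np.float32))
        assert np.all(np.isfinite(fv))


class TestExemplar:
    def test_shape_is_50_by_width(self, small_net, rng):
        ef = exemplar_features(small_net, rng.random((224, 224, 3),
                                                     dtype=np.float32))
        assert ef.shape == (50, small_net.feature_length())

    def test_constant_image_patch_rows_identical(self, small_net):
        ef = exemplar_features(small_net,
                               np.full((224, 224, 3), 0.3, np.float32))
        assert np.allclose(ef[1:], ef[1], atol=1e-5)

    def test_row1_is_raw_image_features(self, small_net, rng):
        img = rng.random((224, 224, 3), dtype=np.float32)
        ef = exemplar_features(small_net, img)
        assert np.allclose(ef[0], extract_gap_features(small_net, img))


class TestMerge:
    def test_width_and_provenance(self, rng):
        per = [rng.random((50, 64)) for _ in range(3)]
        fm = merge_features(per)
        assert fm.width == 50 * 64
        # merging law: column q + C*(t-1) holds fv_t[q] (1-based t, q)
        for col in rng.integers(0, fm.width, 40):
            t, q = fm.column_provenance(int(col))
            assert fm.values[0, col] == per[0][t - 1, q - 1]

    def test_ordering_law_tiny(self):
        fm = merge_features([np.array([[1.0, 2.0], [3.0, 4.0]])])
        assert fm.values.tolist() == [[1.0, 2.0, 3.0, 4.0]]

    def test_unmerge_round_trip(self, rng):
        per = [rng.random((5, 7)) for _ in range(4)]
        fm = merge_features(per)
        back = unmerge_features(fm)
        for a, b in zip(per, back):
            assert np.array_equal(a, b)

    def test_ragged_inputs_rejected(self, rng):
        with pytest.raises(GeometryError):
            merge_features([rng.random((50, 64)), rng.random((49, 64))])

    def test_csv_round_trip(self, tmp_path, rng):
        fm = merge_features([rng.random((3, 4)) for _ in range(2)],
                            labels=np.array([0, 1]))
        fm.to_csv(tmp_path / "f.csv")
        back = FeatureMatrix.from_csv(tmp_path / "f.csv")
        assert back.feature_len == 4 and back.n_vectors == 3
        assert np.allclose(back.values, fm.values)
        assert np.array_equal(back.labels, fm.labels)


def test_extraction_deterministic_in_eval_mode(small_net, rng):
    img = rng.random((224, 224, 3), dtype=np.float32)
    a = exemplar_features(small_net, img)
    b = exemplar_features(small_net, img)
    assert np.array_equal(a, b)
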