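import numpy as np
import pytest

import imageio.v3 as iio

from obstruseg import images as im
from obstruseg.util import ValidationError


class TestLoadSave:
    def test_constant_8bit_png_maps_to_zero(self, tmp_path):
        p = tmp_path / "c.png"
        iio.imwrite(p, np.full((8, 8), 255, dtype=np.uint8))
        img = im.load_image(p)
        assert np.all(img.pixels == 0.0)  # documented max==min convention

    def test_16bit_tiff_endpoints(self, tmp_path):
        p = tmp_path / "e.tif"
        arr = np.zeros((4, 4), dtype=np.uint16)
        arr[2:, :] = 65535
        iio.imwrite(p, arr)
        img = im.load_image(p)
        assert set(np.unique(img.pixels)) == {0.0, 1.0}

    def test_image_roundtrip_16bit(self, tmp_path, rng):
        arr = rng.random((12, 17))
        arr[0, 0], arr[0, 1] = 0.0, 1.0  # pin endpoints so normalization is identity
        img = im.GrayImage(arr)
        p = tmp_path / "r.png"
        im.save_image(img, p)
        back = im.load_image(p)
        assert np.allclose(back.pixels, img.pixels, atol=1.0 / 65535)

    def test_mask_roundtrip(self, tmp_path, rng):
        mask = im.LabelMask(rng.integers(0, 3, (10, 14)))
        p = tmp_path / "m.png"
        im.save_mask(mask, p)
        assert np.array_equal(im.load_mask(p).labels, mask.labels)

    def test_color_rejected(self, tmp_path):
        p = tmp_path / "rgb.png"
        iio.imwrite(p, np.zeros((4, 4, 3), dtype=np.uint8))
        with pytest.raises(ValidationError, match="multi-channel"):
            im.load_image(p)

    def test_nifti_roundtrip_and_multislice_error(self, tmp_path, rng):
        arr = rng.random((6, 7))
        arr[0, 0], arr[0, 1] = 0.0, 1.0
        p = tmp_path / "one.nii.gz"
        im.save_nifti(im.GrayImage(arr), p)
        assert np.allclose(im.load_image(p).pixels, arr, atol=1e-6)

        import nibabel as nib

        p3 = tmp_path / "vol.nii.gz"
        nib.save(nib.Nifti1Image(np.zeros((4, 4, 3)), np.eye(4)), p3)
        with pytest.raises(ValidationError, match="--slice"):
            im.load_image(p3)
        assert im.load_image(p3, slice_index=1).shape == (4, 4)

    def test_missing_file(self):
        with pytest.raises(ValidationError):
            im.load_image("/nonexistent/x.png")


class TestExtractBlocks:
    def test_64_b32_s16_nine_blocks(self, rng):
        img = im.GrayImage(rng.random((64, 64)))
        grid = im.extract_blocks(img, 32, 16)
        # oracle: brute-force stride enumeration
        expected = [(r, c) for r in (0, 16, 32) for c in (0, 16, 32)]
        assert grid.n_blocks == 9
        assert grid.origins.tolist() == [list(o) for o in expected]

    def test_block_equals_image(self, rng):
        img = im.GrayImage(rng.random((32, 32)))
        grid = im.extract_blocks(img, 32, 16)
        assert grid.n_blocks == 1
        assert grid.origins.tolist() == [[0, 0]]
        assert np.array_equal(grid.blocks[0], img.pixels)

    def test_70_edge_flush(self, rng):
        img = im.GrayImage(rng.random((70, 70)))
        grid = im.extract_blocks(img, 32, 16)
        axis = sorted(set(grid.origins[:, 0].tolist()))
        assert axis == [0, 16, 32, 38]
        assert grid.n_blocks == 16
        # brute-force coverage oracle
        cover = np.zeros((70, 70), dtype=int)
        for r, c in grid.origins:
            cover[r : r + 32, c : c + 32] += 1
        assert cover.min() >= 1

    def test_block_content_matches_origin(self, rng):
        img = im.GrayImage(rng.random((40, 50)))
        grid = im.extract_blocks(img, 16, 8)
        for (r, c), blk in zip(grid.origins, grid.blocks):
            assert np.array_equal(blk, img.pixels[r : r + 16, c : c + 16])

    def test_validation(self, rng):
        img = im.GrayImage(rng.random((16, 16)))
        with pytest.raises(ValidationError):
            im.extract_blocks(img, 32, 16)
        with pytest.raises(ValidationError):
            im.extract_blocks(img, 8, 0)
        with pytest.raises(ValidationError):
            im.extract_blocks(img, 8, 9)

    @pytest.mark.parametrize("shape", [(33, 47), (64, 80), (41, 41)])
    @pytest.mark.parametrize("b,s", [(8, 4), (16, 8), (32, 16)])
    def test_coverage_sampled(self, rng, shape, b, s):
        if b > min(shape):
            pytest.skip("block larger than image")
        img = im.GrayImage(rng.random(shape))
        grid = im.extract_blocks(img, b, s)
        cover = np.zeros(shape, dtype=int)
        for r, c in grid.origins:
            cover[r : r + b, c : c + b] += 1
        assert cover.min() >= 1


def pixel_average_oracle(grid, scores):
    """Brute-force per-pixel loop: average covering blocks then argmax."""
    h, w = grid.source_shape
    k = scores.shape[1]
    out = np.zeros((h, w), dtype=np.int64)
    b = grid.block_size
    for i in range(h):
        for j in range(w):
            acc = np.zeros(k)
            n = 0
            for (r, c), s in zip(grid.origins, scores):
                if r <= i < r + b and c <= j < c + b:
                    acc += s
                    n += 1
            mean = acc / n
            out[i, j] = int(np.argmax(mean))
    return out


class TestReassemble:
    def test_unanimous_onehot(self, rng):
        img = im.GrayImage(rng.random((48, 48)))
        grid = im.extract_blocks(img, 16, 8)
        scores = np.tile([0.0, 1.0, 0.0], (grid.n_blocks, 1))
        mask = im.reassemble_mask(grid, scores)
        assert np.all(mask.labels == 1)

    def test_nonoverlapping_single_cover(self, rng):
        img = im.GrayImage(rng.random((32, 32)))
        grid = im.extract_blocks(img, 16, 16)
        scores = rng.random((grid.n_blocks, 3))
        mask = im.reassemble_mask(grid, scores)
        for (r, c), s in zip(grid.origins, scores):
            assert np.all(mask.labels[r : r + 16, c : c + 16] == np.argmax(s))

    def test_matches_pixel_oracle(self, rng):
        img = im.GrayImage(rng.random((64, 64)))
        grid = im.extract_blocks(img, 32, 16)
        scores = rng.random((grid.n_blocks, 4))
        mask = im.reassemble_mask(grid, scores)
        assert np.array_equal(mask.labels, pixel_average_oracle(grid, scores))

    def test_tie_breaks_low_index(self, rng):
        img = im.GrayImage(rng.random((16, 16)))
        grid = im.extract_blocks(img, 16, 16)
        mask = im.reassemble_mask(grid, np.array([[0.5, 0.5]]))
        assert np.all(mask.labels == 0)

    def test_score_count_validation(self, rng):
        img = im.GrayImage(rng.random((32, 32)))
        grid = im.extract_blocks(img, 16, 16)
        with pytest.raises(ValidationError):
            im.reassemble_mask(grid, np.zeros((grid.n_blocks + 1, 2)))

    def test_majority_vote_mode(self, rng):
        img = im.GrayImage(rng.random((32, 32)))
        grid = im.extract_blocks(img, 16, 16)
        scores = rng.random((grid.n_blocks, 3))
        mask = im.reassemble_mask(grid, scores, vote="majority")
        for (r, c), s in zip(grid.origins, scores):
            assert np.all(mask.labels[r : r + 16, c : c + 16] == np.argmax(s))
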