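"""Image I/O, canonicalisation and paired augmentation."""

import numpy as np
import pytest

from coralseg import preprocess as pp


# ---------------------------------------------------------------------------
# loading / saving
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("value,expected", [(255, 1.0), (0, 0.0)])
def test_load_gray_image_scales_8bit_extremes(tmp_path, value, expected):
    import imageio.v3 as iio
    path = tmp_path / "img.png"
    iio.imwrite(path, np.full((5, 7), value, dtype=np.uint8))
    img = pp.load_gray_image(path)
    assert img.shape == (5, 7)
    np.testing.assert_array_equal(img, expected)


def test_load_gray_image_rejects_color(tmp_path):
    import imageio.v3 as iio
    path = tmp_path / "rgb.png"
    iio.imwrite(path, np.zeros((4, 4, 3), dtype=np.uint8))
    with pytest.raises(pp.ChannelCountError):
        pp.load_gray_image(path)


def test_load_gray_image_missing_file(tmp_path):
    with pytest.raises((FileNotFoundError, OSError)):
        pp.load_gray_image(tmp_path / "missing.png")


def test_save_load_round_trip_within_one_gray_level(tmp_path, rng):
    img = rng.random((16, 16))
    pp.save_gray_image(tmp_path / "r.png", img)
    back = pp.load_gray_image(tmp_path / "r.png")
    assert np.abs(back - img).max() <= 1 / 255 + 1e-12


def test_split_rgb_channels_basis_and_restack(rng):
    red = np.zeros((3, 3, 3), dtype=np.uint8)
    red[..., 0] = 255
    r, g, b = pp.split_rgb_channels(red)
    np.testing.assert_array_equal(r, 1.0)
    np.testing.assert_array_equal(g, 0.0)
    np.testing.assert_array_equal(b, 0.0)
    gray = np.full((4, 5, 3), 77, dtype=np.uint8)
    r, g, b = pp.split_rgb_channels(gray)
    np.testing.assert_array_equal(r, g)
    np.testing.assert_array_equal(g, b)
    # restacking reconstructs any uint8 raster bit-exactly
    raster = rng.integers(0, 256, (6, 7, 3)).astype(np.uint8)
    channels = pp.split_rgb_channels(raster)
    restacked = np.round(np.stack(channels, axis=2) * 255).astype(np.uint8)
    np.testing.assert_array_equal(restacked, raster)
    with pytest.raises(pp.ChannelCountError):
        pp.split_rgb_channels(np.zeros((4, 4, 4)))


# ---------------------------------------------------------------------------
# canonical geometry
# ---------------------------------------------------------------------------

def test_pad_to_square_landscape_adds_top_bottom_bands(rng):
    img = rng.random((400, 512))
    out = pp.pad_to_square(img)
    assert out.shape == (512, 512)
    np.testing.assert_array_equal(out[:56], 0.0)
    np.testing.assert_array_equal(out[-56:], 0.0)
    np.testing.assert_array_equal(out[56:456], img)


def test_pad_to_square_portrait_and_identity(rng):
    img = rng.random((512, 400)) + 0.01
    out = pp.pad_to_square(img)
    assert out.shape == (512, 512)
    # padded pixels are black: their sum is zero
    assert out[:, :56].sum() == 0 and out[:, 456:].sum() == 0
    square = rng.random((64, 64))
    assert pp.pad_to_square(square) is square


def test_resize_constant_preserved_and_canonical_side(rng):
    const = np.full((128, 128), 0.4)
    out = pp.resize_to_canonical(const, 64)
    assert out.shape == (64, 64)
    np.testing.assert_allclose(out, 0.4, atol=1e-12)
    assert pp.canonicalize(rng.random((100, 60)), 512).shape == (512, 512)


def test_resize_mask_nearest_neighbour_index_map():
    mask = np.array([[0, 1], [0, 1]], dtype=np.uint8)
    out = pp.resize_to_canonical(mask, 4, is_mask=True)
    np.testing.assert_array_equal(out[:, :2], 0)
    np.testing.assert_array_equal(out[:, 2:], 1)
    assert set(np.unique(out)) <= {0, 1}


def test_resize_rejects_non_square(rng):
    with pytest.raises(ValueError, match="square"):
        pp.resize_to_canonical(rng.random((4, 8)), 16)


@pytest.mark.parametrize("value,expected", [(1.0, 1), (0.0, 0),
                                            (0.49, 0), (0.51, 1)])
def test_binarize_mask_threshold(value, expected):
    np.testing.assert_array_equal(pp.binarize_mask(np.full((3, 3), value)),
                                  expected)


def test_canonicalize_keeps_masks_binary(rng):
    mask = (rng.random((30, 50)) > 0.5).astype(np.uint8)
    out = pp.canonicalize(mask, 64, is_mask=True)
    assert set(np.unique(out)) <= {0, 1}


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

class _ForcedRng:
    """Deterministic stand-in driving augment_pair down a chosen branch."""

    def __init__(self, draws, angle=90.0):
        self.draws = list(draws)
        self.angle = angle

    def random(self):
        return self.draws.pop(0)

    def uniform(self, lo, hi):
        return self.angle


def test_augment_identity_branch(rng):
    img = rng.random((8, 8))
    mask = (img > 0.5).astype(np.uint8)
    out_img, out_mask = pp.augment_pair(img, mask, _ForcedRng([0.9, 0.9, 0.9]))
    np.testing.assert_array_equal(out_img, img)
    np.testing.assert_array_equal(out_mask, mask)


def test_augment_horizontal_flip_is_involution(rng):
    img = rng.random((8, 8))
    mask = (img > 0.5).astype(np.uint8)
    once = pp.augment_pair(img, mask, _ForcedRng([0.9, 0.1, 0.9]))
    np.testing.assert_array_equal(once[0], img[:, ::-1])
    np.testing.assert_array_equal(once[1], mask[:, ::-1])
    twice = pp.augment_pair(once[0], once[1], _ForcedRng([0.9, 0.1, 0.9]))
    np.testing.assert_array_equal(twice[0], img)
    np.testing.assert_array_equal(twice[1], mask)


def test_augment_flips_preserve_foreground_count_exactly(rng):
    mask = (rng.random((16, 16)) > 0.7).astype(np.uint8)
    img = mask.astype(float)
    for draws in ([0.9, 0.1, 0.1], [0.9, 0.1, 0.9], [0.9, 0.9, 0.1]):
        _, out = pp.augment_pair(img, mask, _ForcedRng(list(draws)))
        assert out.sum() == mask.sum()


def test_augment_rotation_keeps_mask_binary_and_blob_area_stable():
    # centred disc occupying well over 5% of the frame
    yy, xx = np.mgrid[0:64, 0:64]
    mask = (((yy - 32) ** 2 + (xx - 32) ** 2) < 14 ** 2).astype(np.uint8)
    img = mask.astype(float)
    for angle in (17.0, 45.0, 90.0, 133.0):
        _, out = pp.augment_pair(img, mask,
                                 _ForcedRng([0.1, 0.9, 0.9], angle=angle))
        assert set(np.unique(out)) <= {0, 1}
        delta = abs(int(out.sum()) - int(mask.sum())) / mask.sum()
        assert delta <= 0.10


def test_augment_shape_mismatch_raises(rng):
    with pytest.raises(ValueError, match="mismatch"):
        pp.augment_pair(rng.random((8, 8)), np.zeros((4, 4), dtype=np.uint8),
                        np.random.default_rng(0))


def test_augment_transforms_fire_with_half_probability():
    rng = np.random.default_rng(99)
    img = np.zeros((4, 4))
    counts = {"rotate": 0, "hflip": 0, "vflip": 0}
    n = 10_000
    for _ in range(n):
        _, _, params = pp.augment_pair(img, None, rng, return_params=True)
        for key in counts:
            counts[key] += params[key]
    # binomial(10000, 0.5): 3 sigma = 150
    for key, c in counts.items():
        assert abs(c - n / 2) <= 3 * np.sqrt(n * 0.25), (key, c)


def test_augment_replay_with_same_seed_is_identical(rng):
    img = rng.random((16, 16))
    mask = (img > 0.6).astype(np.uint8)
    a = pp.augment_pair(img, mask, np.random.default_rng(5))
    b = pp.augment_pair(img, mask, np.random.default_rng(5))
    np.testing.assert_array_equal(a[0], b[0])
    np.testing.assert_array_equal(a[1], b[1])


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def test_manifest_round_trip_resolves_relative_paths(tmp_path):
    records = [
        pp.SampleRecord("images/a.png", "masks/a.png", 1, "train"),
        pp.SampleRecord("images/b.png", None, 0, "val"),
    ]
    pp.write_manifest(tmp_path / "m.csv", records)
    back = pp.read_manifest(tmp_path / "m.csv")
    assert back[0].image_path == str(tmp_path / "images/a.png")
    assert back[0].mask_path == str(tmp_path / "masks/a.png")
    assert back[0].image_label == 1 and back[0].split == "train"
    assert back[1].mask_path is None and back[1].split == "val"
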