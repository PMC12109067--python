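"""Dataset generator: connectivity, motion consistency, noise, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hcdm import (ColorRegime, MotionDirection, NoiseSpec, add_gaussian,
                  add_salt_pepper, build_group, build_mixed, generate_object,
                  render_pair, save_pairs, load_pairs)
from hcdm.dataset import GROUPS, _OFFSETS


def flood_fill_components(cells):
    """Independent connectivity oracle: count 4-connected components."""
    cells = set(map(tuple, cells))
    n_comp = 0
    while cells:
        n_comp += 1
        stack = [cells.pop()]
        while stack:
            r, c = stack.pop()
            for nb in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                if nb in cells:
                    cells.remove(nb)
                    stack.append(nb)
    return n_comp


class TestMotionDirection:
    def test_eight_unique_offsets_cover_nonzero_grid(self):
        offsets = {d.offset for d in MotionDirection}
        expected = {(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                    if (dy, dx) != (0, 0)}
        assert offsets == expected
        assert len(MotionDirection) == 8

    def test_code_offset_bijection_is_stable(self):
        assert {int(d): d.offset for d in MotionDirection} == _OFFSETS


class TestGenerateObject:
    @pytest.mark.parametrize("size", [1, 2, 4, 8, 16, 32, 64, 128])
    def test_exact_size_and_single_component(self, size, rng):
        mask = generate_object(size, rng)
        assert len(mask) == size
        assert len({tuple(c) for c in mask}) == size
        assert flood_fill_components(mask) == 1

    def test_many_draws_stay_connected(self, rng):
        for _ in range(1000):
            mask = generate_object(8, rng)
            assert len(mask) == 8
            assert flood_fill_components(mask) == 1

    def test_normalized_to_bounding_box_origin(self, rng):
        mask = generate_object(16, rng)
        assert mask.min(axis=0).tolist() == [0, 0]

    def test_oversized_object_rejected(self, rng):
        with pytest.raises(ValueError):
            generate_object(32 * 32 + 1, rng)


class TestRenderPair:
    def test_single_pixel_object_moves_east(self, rng):
        mask = np.array([[0, 0]])
        pair = render_pair(mask, MotionDirection.E, ColorRegime("dark"),
                           ColorRegime("constant", 200), rng)
        on_t = np.argwhere(pair.frame_t[:, :, 0] == 200)
        on_t1 = np.argwhere(pair.frame_t1[:, :, 0] == 200)
        assert len(on_t) == 1 and len(on_t1) == 1
        assert (on_t1[0] - on_t[0]).tolist() == [0, 1]
        assert pair.frame_t.sum() == 3 * 200  # rest dark

    @pytest.mark.parametrize("direction", list(MotionDirection))
    @pytest.mark.parametrize("bg,obj", [("dark", "random"),
                                        ("random", "random"),
                                        ("constant", "constant")])
    def test_motion_consistency_on_noiseless_pairs(self, direction, bg, obj, rng):
        background = ColorRegime.sample(bg, rng)
        objreg = ColorRegime.sample(obj, rng)
        mask = generate_object(12, rng)
        pair = render_pair(mask, direction, background, objreg, rng)
        placed = pair.meta["object_mask_t"]
        dy, dx = direction.offset
        moved = placed + np.array([dy, dx])
        assert (moved >= 0).all() and (moved < 32).all()
        np.testing.assert_array_equal(
            pair.frame_t[placed[:, 0], placed[:, 1]],
            pair.frame_t1[moved[:, 0], moved[:, 1]])

    def test_constant_constant_has_two_distinct_values(self, rng):
        for _ in range(20):
            bg = ColorRegime.sample("constant", rng)
            obj = ColorRegime.sample("constant", rng)
            if obj.value == bg.value:
                continue
            mask = generate_object(8, rng)
            pair = render_pair(mask, MotionDirection.N, bg, obj, rng)
            assert set(np.unique(pair.frame_t)) == {bg.value, obj.value}
            assert set(np.unique(pair.frame_t1)) == {bg.value, obj.value}

    def test_dark_on_dark_rejected(self, rng):
        with pytest.raises(ValueError):
            render_pair(np.array([[0, 0]]), MotionDirection.E,
                        ColorRegime("dark"), ColorRegime("dark"), rng)


class TestNoise:
    def test_salt_pepper_zero_rate_identity(self, rng):
        img = rng.integers(0, 256, (32, 32, 3), dtype=np.uint8)
        np.testing.assert_array_equal(add_salt_pepper(img, 0.0, rng), img)

    def test_salt_pepper_full_rate_binarizes(self, rng):
        img = rng.integers(1, 255, (32, 32, 3), dtype=np.uint8)
        out = add_salt_pepper(img, 1.0, rng)
        assert set(np.unique(out)) <= {0, 255}

    @pytest.mark.parametrize("rate,expected", [(0.05, 51), (0.10, 102),
                                               (0.01, 10), (0.02, 20)])
    def test_exact_corruption_count(self, rate, expected, rng):
        # mid-gray image: every corrupted pixel is visibly changed
        img = np.full((32, 32, 3), 100, dtype=np.uint8)
        out = add_salt_pepper(img, rate, rng)
        changed = np.any(out != img, axis=2).sum()
        assert changed == expected == round(rate * 32 * 32)

    def test_salt_pepper_corrupts_all_channels_together(self, rng):
        img = np.full((32, 32, 3), 100, dtype=np.uint8)
        out = add_salt_pepper(img, 0.3, rng)
        changed = out != img
        # a corrupted position is corrupted in every channel
        assert np.array_equal(changed.any(axis=2), changed.all(axis=2))

    def test_gaussian_zero_std_identity(self, rng):
        img = rng.integers(0, 256, (32, 32, 3), dtype=np.uint8)
        np.testing.assert_array_equal(add_gaussian(img, 0.0, rng), img)

    def test_gaussian_moments_on_midrange_pixels(self, rng):
        img = np.full((200, 200, 3), 128, dtype=np.uint8)
        out = add_gaussian(img, 5.0, rng)
        dev = out.astype(np.float64) - 128.0
        assert abs(dev.mean()) < 0.1
        assert abs(dev.std() - 5.0) < 0.15

    def test_gaussian_clips_at_zero(self, rng):
        img = np.zeros((32, 32, 3), dtype=np.uint8)
        out = add_gaussian(img, 5.0, rng)
        assert out.min() >= 0 and out.mean() > 0

    def test_invalid_parameters_rejected(self, rng):
        img = np.zeros((4, 4, 3), dtype=np.uint8)
        with pytest.raises(ValueError):
            add_salt_pepper(img, 1.5, rng)
        with pytest.raises(ValueError):
            add_gaussian(img, -1.0, rng)


class TestBuildGroup:
    def test_direction_balance(self):
        pairs = build_group("dark-constant", 80, seed=1)
        counts = np.bincount([int(p.label) for p in pairs], minlength=9)[1:]
        assert (counts == 10).all()

    def test_same_seed_identical_datasets(self):
        a = build_group("random-random", 24, seed=5)
        b = build_group("random-random", 24, seed=5)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.frame_t, pb.frame_t)
            np.testing.assert_array_equal(pa.frame_t1, pb.frame_t1)
            assert pa.label == pb.label

    def test_invalid_group_rejected(self):
        with pytest.raises(ValueError):
            build_group("dark-dark", 8, seed=0)
        with pytest.raises(ValueError):
            build_group("blue-green", 8, seed=0)

    def test_mixed_covers_all_groups(self):
        pairs = build_mixed(80, seed=2)
        groups = {p.meta["group"] for p in pairs}
        assert groups == {f"{b}-{o}" for b, o in GROUPS}

    @pytest.mark.parametrize("fmt", ["npz", "png"])
    def test_save_load_round_trip(self, fmt, tmp_path):
        pairs = build_group("constant-random", 16, seed=9)
        save_pairs(pairs, tmp_path / fmt, fmt=fmt)
        loaded = load_pairs(tmp_path / fmt)
        assert len(loaded) == 16
        for orig, back in zip(pairs, loaded):
            np.testing.assert_array_equal(orig.frame_t, back.frame_t)
            np.testing.assert_array_equal(orig.frame_t1, back.frame_t1)
            assert orig.label == back.label


@settings(max_examples=25, deadline=None, derandomize=True)
@given(size=st.integers(1, 64), seed=st.integers(0, 2**31 - 1))
def test_object_connectivity_property(size, seed):
    mask = generate_object(size, np.random.default_rng(seed))
    assert len(mask) == size
    assert flood_fill_components(mask) == 1
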