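import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirfuse.pyramid import (
    BURT_ADELSON_KERNEL,
    Pyramid,
    build_gaussian,
    build_laplacian,
    collapse,
    default_depth,
    max_feasible_depth,
    smooth_downsample,
    upsample_to,
)


def oracle_smooth_downsample(img):
    """Independent reduce: explicit mirror padding + direct separable convolution."""
    k = np.array([1, 4, 6, 4, 1], dtype=float) / 16
    out = img.astype(float)
    for axis in (0, 1):
        if out.shape[axis] > 1:
            moved = np.moveaxis(out, axis, 0)
            padded = np.pad(moved, [(2, 2)] + [(0, 0)] * (moved.ndim - 1), mode="reflect")
            conv = sum(k[j] * padded[j : j + moved.shape[0]] for j in range(5))
            out = np.moveaxis(conv, 0, axis)
    return out[::2, ::2]


class TestSmoothDownsample:
    def test_constant_preserved_at_half_size(self):
        out = smooth_downsample(np.full((6, 9), 0.42))
        assert out.shape == (3, 5)
        np.testing.assert_allclose(out, 0.42, atol=1e-14)

    @pytest.mark.parametrize(
        "shape,expected",
        [((4, 4), (2, 2)), ((5, 5), (3, 3)), ((1, 1), (1, 1)), ((7, 2), (4, 1))],
    )
    def test_ceil_division_size_contract(self, shape, expected):
        assert smooth_downsample(np.zeros(shape)).shape == expected

    def test_impulse_matches_hand_convolution(self):
        # 1-D analogue [0,0,1,0,0]: mirror-pad, 5-tap convolve, decimate
        # gives [2, 6, 2] / 16 (hand-derived; border taps pick up the
        # reflected impulse).
        sig = np.zeros((1, 5))
        sig[0, 2] = 1.0
        out = smooth_downsample(sig)
        np.testing.assert_allclose(out, [[0.125, 0.375, 0.125]], atol=1e-14)

    def test_matches_brute_force_oracle_on_random_image(self, rng):
        x = rng.random((23, 17))
        np.testing.assert_allclose(smooth_downsample(x), oracle_smooth_downsample(x), atol=1e-12)

    def test_kernel_is_normalized(self):
        assert BURT_ADELSON_KERNEL.sum() == pytest.approx(1.0, abs=1e-15)


class TestUpsampleTo:
    def test_constant_preserved(self):
        out = upsample_to(np.full((3, 4), 0.7), 5, 7)
        assert out.shape == (5, 7)
        np.testing.assert_allclose(out, 0.7, atol=1e-14)

    @pytest.mark.parametrize("src,target", [((2, 2), (4, 4)), ((3, 3), (5, 5)), ((1, 1), (2, 2))])
    def test_valid_size_contract(self, src, target):
        assert upsample_to(np.zeros(src), *target).shape == target

    def test_inconsistent_target_rejected(self):
        with pytest.raises(ValueError, match="cannot upsample"):
            upsample_to(np.zeros((2, 2)), 5, 5)

    def test_residual_definition(self, rng):
        x = rng.random((9, 9))
        down = smooth_downsample(x)
        residual = x - upsample_to(down, 9, 9)
        lp = build_laplacian(x, 2)
        np.testing.assert_allclose(lp[0], residual, atol=1e-14)


class TestGaussianPyramid:
    def test_depth_one_is_identity(self, rng):
        x = rng.random((8, 8))
        p = build_gaussian(x, 1)
        assert p.depth == 1 and p.variant == "gaussian"
        np.testing.assert_array_equal(p[0], x)

    def test_constant_image_all_levels_constant(self):
        p = build_gaussian(np.full((16, 16), 0.3), 5)
        assert [lvl.shape[0] for lvl in p.levels] == [16, 8, 4, 2, 1]
        for lvl in p.levels:
            np.testing.assert_allclose(lvl, 0.3, atol=1e-13)

    def test_levels_match_oracle(self, rng):
        x = rng.random((32, 32))
        p = build_gaussian(x, 4)
        cur = x
        for l in range(1, 4):
            cur = oracle_smooth_downsample(cur)
            assert p[l].shape == cur.shape
            np.testing.assert_allclose(p[l], cur, atol=1e-11)

    def test_infeasible_depth_error_names_maximum(self):
        with pytest.raises(ValueError, match="maximum feasible depth is 4"):
            build_gaussian(np.zeros((8, 8)), 9)

    def test_max_feasible_depth_iterative_ceil(self):
        assert max_feasible_depth(5, 5) == 4  # 5 -> 3 -> 2 -> 1
        assert max_feasible_depth(16, 16) == 5
        assert max_feasible_depth(1, 1) == 1

    def test_default_depth(self):
        assert default_depth(256, 256) == 8
        assert default_depth(2, 2) == 1
        assert default_depth(1, 1) == 1


class TestLaplacianPyramid:
    def test_depth_one_collapse_is_identity(self, rng):
        x = rng.random((6, 11))
        lp = build_laplacian(x, 1)
        np.testing.assert_array_equal(collapse(lp), x)

    def test_constant_image_residuals_are_zero(self):
        lp = build_laplacian(np.full((16, 16), 0.55), 4)
        for lvl in lp.levels[:-1]:
            np.testing.assert_allclose(lvl, 0.0, atol=1e-13)
        np.testing.assert_allclose(lp.levels[-1], 0.55, atol=1e-13)

    def test_collapse_rejects_gaussian_variant(self):
        p = build_gaussian(np.zeros((4, 4)), 2)
        with pytest.raises(ValueError, match="Laplacian"):
            collapse(p)

    def test_zeroed_residuals_collapse_to_pure_lowpass(self, rng):
        x = rng.random((16, 16))
        lp = build_laplacian(x, 3)
        zeroed = Pyramid("laplacian", [np.zeros_like(lp[0]), np.zeros_like(lp[1]), lp[2]])
        expected = upsample_to(upsample_to(lp[2], 8, 8), 16, 16)
        np.testing.assert_allclose(collapse(zeroed), expected, atol=1e-13)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        h=st.integers(min_value=1, max_value=257),
        w=st.integers(min_value=1, max_value=257),
        data=st.data(),
    )
    def test_reconstruction_identity_fuzzed(self, h, w, data):
        depth = data.draw(st.integers(min_value=1, max_value=max_feasible_depth(h, w)))
        rng = np.random.default_rng(h * 1000 + w)
        x = rng.random((h, w))
        err = np.abs(collapse(build_laplacian(x, depth)) - x).max()
        assert err < 1e-10

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(h=st.integers(min_value=1, max_value=100), w=st.integers(min_value=1, max_value=100))
    def test_size_law_iterated_ceil(self, h, w):
        p = build_gaussian(np.zeros((h, w)), max_feasible_depth(h, w))
        ch, cw = h, w
        for lvl in p.levels:
            assert lvl.shape == (ch, cw)
            ch, cw = -(-ch // 2), -(-cw // 2)
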