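"""Unit and property tests for the flat-morphology / reconstruction algebra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from conftest import (
    FAMILIES,
    naive_dilate,
    naive_erode,
    naive_reconstruct_dilation,
    naive_reconstruct_erosion,
    random_images,
)
from msthgr import morphology as mm

CROSS = mm.cross_se()

small_images = hnp.arrays(
    dtype=np.float64,
    shape=st.tuples(st.integers(3, 10), st.integers(3, 10)),
    elements=st.integers(0, 255).map(float),
)


class TestStructuringElements:
    def test_disk_radius_one_is_the_cross(self):
        se = mm.disk_se(1)
        assert se.size == 5
        assert np.array_equal(
            se.mask, np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
        )

    def test_disk_radius_two_has_thirteen_members(self):
        assert mm.disk_se(2).size == 13

    @pytest.mark.parametrize("family", FAMILIES.values(), ids=list(FAMILIES))
    def test_scale_family_is_nested_and_rejects_scale_zero(self, family):
        with pytest.raises(ValueError):
            family(0)
        for i in range(1, 6):
            small, big = family(i).mask, family(i + 1).mask
            pad = (big.shape[0] - small.shape[0]) // 2
            embedded = np.pad(small, pad)
            assert np.all(big[embedded]), f"{family.__name__}({i}) not nested"

    def test_iterated_dilation_family_gives_diamonds(self):
        # cross (+) cross ... = the L1 ball, e.g. radius 3 has 25 members
        se = mm.iterated_dilation_se(3)
        y, x = np.ogrid[-3:4, -3:4]
        assert np.array_equal(se.mask, np.abs(x) + np.abs(y) <= 3)

    def test_invalid_masks_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mm.StructuringElement(np.zeros((3, 3), dtype=bool))
        asym = np.zeros((3, 3), dtype=bool)
        asym[1, 1] = asym[0, 0] = True
        with pytest.raises(ValueError, match="symmetric"):
            mm.StructuringElement(asym)
        no_origin = np.ones((3, 3), dtype=bool)
        no_origin[1, 1] = False
        with pytest.raises(ValueError, match="origin"):
            mm.StructuringElement(no_origin)


class TestBasicOperators:
    def test_dilate_erode_open_wth_on_ramp(self, ramp3):
        assert np.array_equal(
            mm.dilate(ramp3, CROSS), [[4, 5, 6], [7, 8, 9], [8, 9, 9]]
        )
        assert np.array_equal(
            mm.erode(ramp3, CROSS), [[1, 1, 2], [1, 2, 3], [4, 5, 6]]
        )
        assert np.array_equal(
            mm.open_(ramp3, CROSS), [[1, 2, 3], [4, 5, 6], [5, 6, 6]]
        )
        assert np.array_equal(
            mm.wth(ramp3, CROSS), [[0, 0, 0], [0, 0, 0], [2, 2, 3]]
        )

    def test_constant_image_is_fixed_by_everything(self):
        c = np.full((6, 7), 42.0)
        for op in (mm.dilate, mm.erode, mm.open_, mm.close_):
            assert np.array_equal(op(c, mm.disk_se(2)), c)
        assert np.array_equal(mm.wth(c, CROSS), np.zeros_like(c))
        assert np.array_equal(mm.bth(c, CROSS), np.zeros_like(c))

    def test_singleton_se_is_the_identity(self, rng):
        se = mm.StructuringElement(np.ones((1, 1), dtype=bool))
        img = rng.integers(0, 256, (5, 8)).astype(float)
        assert np.array_equal(mm.dilate(img, se), img)
        assert np.array_equal(mm.erode(img, se), img)

    def test_single_bright_pixel_white_tophat_is_the_image(self):
        img = np.zeros((5, 5))
        img[2, 2] = 7.0
        assert np.array_equal(mm.wth(img, CROSS), img)

    @given(img=small_images)
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_duality_and_extensivity(self, img):
        se = mm.disk_se(1)
        ceiling = img.max() + 1.0
        assert np.array_equal(
            mm.erode(img, se), ceiling - mm.dilate(ceiling - img, se)
        )
        assert np.all(mm.open_(img, se) <= img)
        assert np.all(img <= mm.close_(img, se))

    @given(img=small_images)
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_open_close_idempotent(self, img):
        se = mm.disk_se(2)
        opened = mm.open_(img, se)
        closed = mm.close_(img, se)
        assert np.array_equal(mm.open_(opened, se), opened)
        assert np.array_equal(mm.close_(closed, se), closed)

    def test_matches_naive_operators(self, rng):
        for img in random_images(rng, 20):
            for i in (1, 2, 3):
                se = mm.disk_se(i)
                assert np.array_equal(mm.dilate(img, se), naive_dilate(img, se))
                assert np.array_equal(mm.erode(img, se), naive_erode(img, se))


class TestGeodesicAndReconstruction:
    MARKER = np.array([[5.0, 0, 0], [0, 0, 0], [0, 0, 0]])
    MASK = np.array([[5.0, 5, 0], [0, 0, 0], [0, 0, 4]])

    def test_single_geodesic_step_spreads_and_clamps(self):
        out = mm.geodesic_dilate(self.MARKER, self.MASK)
        assert np.array_equal(out, [[5, 5, 0], [0, 0, 0], [0, 0, 0]])

    def test_geodesic_identities(self):
        assert np.array_equal(mm.geodesic_dilate(self.MASK, self.MASK), self.MASK)
        zero = np.zeros((3, 3))
        assert np.array_equal(mm.geodesic_dilate(zero, self.MASK), zero)

    def test_ordering_violation_names_the_pixel(self):
        with pytest.raises(ValueError, match=r"\(0, 1\)"):
            mm.geodesic_dilate(np.full((3, 3), 1.0), np.eye(3) * 9)
        with pytest.raises(ValueError, match="marker <= mask"):
            mm.reconstruct_by_dilation(self.MASK, self.MARKER)

    def test_reconstruction_skips_unseeded_components(self):
        out = mm.reconstruct_by_dilation(self.MARKER, self.MASK)
        assert np.array_equal(out, [[5, 5, 0], [0, 0, 0], [0, 0, 0]])
        assert np.array_equal(
            mm.reconstruct_by_dilation(self.MASK, self.MASK), self.MASK
        )

    def test_reconstruction_equals_iterate_to_stability_oracle(self, rng):
        """Fast reconstruction is bit-exact against the naive fixed point."""
        for k, mask in enumerate(random_images(rng, 120)):
            drop = rng.integers(0, 128, size=mask.shape)
            marker = np.maximum(mask - drop, 0.0)
            se = mm.disk_se(1) if k % 2 == 0 else mm.disk_se(2)
            fast = mm.reconstruct_by_dilation(marker, mask, se=se)
            assert np.array_equal(fast, naive_reconstruct_dilation(marker, mask, se))
            up = mask + drop
            fast = mm.reconstruct_by_erosion(up, mask, se=se)
            assert np.array_equal(fast, naive_reconstruct_erosion(up, mask, se))

    def test_open_close_by_reconstruction_bracket_the_image(self, rng):
        for img in random_images(rng, 12):
            for m in (1, 2, 3):
                g = mm.open_by_reconstruction(img, m)
                p = mm.close_by_reconstruction(img, m)
                assert np.all(g <= img) and np.all(img <= p)
                # reconstruction recovers at least the plain opening
                assert np.all(mm.open_(img, mm.disk_se(m)) <= g)

    def test_reconstruction_openings_ordered_across_scales(self, rng):
        for img in random_images(rng, 10):
            for fam in FAMILIES.values():
                prev_g, prev_p = None, None
                for m in (1, 2, 3):
                    g = mm.open_by_reconstruction(img, m, fam)
                    p = mm.close_by_reconstruction(img, m, fam)
                    if prev_g is not None:
                        assert np.all(g <= prev_g)
                        assert np.all(p >= prev_p)
                    prev_g, prev_p = g, p

    def test_large_square_is_reconstructed_exactly(self):
        img = np.zeros((9, 9))
        img[2:8, 2:8] = 50.0  # 6x6 square, larger than disk_se(2)
        assert np.array_equal(mm.open_by_reconstruction(img, 2), img)

    def test_open_by_reconstruction_matches_composition_oracle(self, rng):
        img = rng.integers(0, 256, (8, 8)).astype(float)
        marker = naive_erode(img, mm.disk_se(2))
        expected = naive_reconstruct_dilation(marker, img)
        assert np.array_equal(mm.open_by_reconstruction(img, 2), expected)


class TestReconstructionTopHats:
    def test_constant_image_vanishes(self):
        c = np.full((5, 5), 9.0)
        assert np.array_equal(mm.rwth(c, 2), np.zeros_like(c))
        assert np.array_equal(mm.rbth(c, 2), np.zeros_like(c))

    def test_single_bright_pixel_not_reconstructable(self):
        img = np.zeros((5, 5))
        img[2, 2] = 7.0
        assert np.array_equal(mm.rwth(img, 1), img)

    def test_bounded_by_classic_tophats(self, rng):
        for img in random_images(rng, 15):
            for m in (1, 2, 3):
                se = mm.disk_se(m)
                r_w, w = mm.rwth(img, m), mm.wth(img, se)
                r_b, b = mm.rbth(img, m), mm.bth(img, se)
                assert np.all(r_w >= 0) and np.all(r_b >= 0)
                assert np.all(r_w <= w)
                assert np.all(r_b <= b)
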