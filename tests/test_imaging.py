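"""Bernsen thresholding, particle analysis, and overlap assignment."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_channel
from _oracles import bernsen_oracle, flood_fill_components, overlap_oracle

from phaquant.imaging import (
    BernsenParams,
    BinaryMask,
    ChannelImage,
    ParticleFilter,
    ParticleSet,
    bernsen_threshold,
    circular_footprint,
    label_particles,
    overlap_assign,
)

DEFAULTS = BernsenParams(radius=15, contrast_threshold=15, low_contrast_cut=128)


class TestBernsenThreshold:
    @pytest.mark.parametrize(
        "value,expect_object",
        [(100, False), (200, True)],  # low-contrast routing by midgray vs cut
    )
    def test_uniform_image_routed_by_low_contrast_cut(self, value, expect_object):
        img = make_channel(np.full((20, 20), value))
        mask = bernsen_threshold(img, DEFAULTS)
        assert mask.pixels.all() == expect_object
        assert mask.pixels.any() == expect_object

    def test_single_bright_pixel_is_the_only_object(self):
        px = np.zeros((5, 5), dtype=int)
        px[2, 2] = 255
        mask = bernsen_threshold(make_channel(px), BernsenParams(radius=2, contrast_threshold=15))
        expected = np.zeros((5, 5), dtype=bool)
        expected[2, 2] = True
        np.testing.assert_array_equal(mask.pixels, expected)

    def test_matches_brute_force_oracle_on_random_images(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            shape = tuple(rng.integers(1, 33, size=2))
            px = rng.integers(0, 256, size=shape)
            radius = int(rng.integers(1, 8))
            contrast = int(rng.integers(0, 60))
            cut = int(rng.integers(0, 256))
            params = BernsenParams(radius=radius, contrast_threshold=contrast, low_contrast_cut=cut)
            got = bernsen_threshold(make_channel(px), params).pixels
            want = bernsen_oracle(px, radius, contrast, cut)
            np.testing.assert_array_equal(got, want)

    @given(
        data=st.data(),
        nrows=st.integers(2, 12),
        ncols=st.integers(2, 12),
        radius=st.integers(1, 5),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_zero_contrast_threshold_uses_midgray_branch_everywhere(
        self, data, nrows, ncols, radius
    ):
        px = np.array(
            data.draw(
                st.lists(
                    st.lists(st.integers(0, 255), min_size=ncols, max_size=ncols),
                    min_size=nrows,
                    max_size=nrows,
                )
            )
        )
        params = BernsenParams(radius=radius, contrast_threshold=0, low_contrast_cut=128)
        mask = bernsen_threshold(make_channel(px), params).pixels
        want = bernsen_oracle(px, radius, 0, 128)
        np.testing.assert_array_equal(mask, want)

    def test_huge_contrast_threshold_makes_low_contrast_rule_global(self):
        rng = np.random.default_rng(3)
        px = rng.integers(0, 256, size=(12, 12))
        params = BernsenParams(radius=20, contrast_threshold=1000, low_contrast_cut=128)
        # radius exceeds both dimensions: window = whole image everywhere
        mask = bernsen_threshold(make_channel(px), params).pixels
        expected = (int(px.max()) + int(px.min())) >= 2 * 128
        assert mask.all() == expected or (not mask.any()) == (not expected)
        assert len(np.unique(mask)) == 1

    def test_16bit_input_is_rescaled_to_8bit_range(self):
        px16 = np.full((10, 10), 4000, dtype=int)
        px16[5, 5] = 60000
        img = ChannelImage(pixels=px16, bit_depth=16, role="PHA")
        mask = bernsen_threshold(img, BernsenParams(radius=3, contrast_threshold=15))
        assert mask.pixels[5, 5]
        assert mask.pixels.sum() == 1

    def test_deterministic(self):
        rng = np.random.default_rng(11)
        px = rng.integers(0, 256, size=(24, 24))
        a = bernsen_threshold(make_channel(px), DEFAULTS).pixels
        b = bernsen_threshold(make_channel(px), DEFAULTS).pixels
        np.testing.assert_array_equal(a, b)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            ChannelImage(pixels=np.zeros((0, 5), dtype=int), bit_depth=8, role="DNA")

    def test_footprint_is_euclidean_disk(self):
        foot = circular_footprint(2)
        assert foot.shape == (5, 5)
        assert foot.sum() == 13  # 3x3 block plus the four axis tips


def _mask(arr) -> BinaryMask:
    return BinaryMask(pixels=np.asarray(arr, dtype=bool))


class TestLabelParticles:
    def test_size_filter_keeps_only_large_blob(self):
        px = np.zeros((10, 10), dtype=bool)
        px[1:3, 1:6] = True  # 10 px
        px[7, 2:5] = True  # 3 px
        ps = label_particles(_mask(px), ParticleFilter(min_area_px=5))
        assert len(ps) == 1
        assert ps.particles[0].area_px == 10
        assert ps.particles[0].label == 1

    def test_all_background_gives_empty_set(self):
        ps = label_particles(_mask(np.zeros((8, 8))))
        assert len(ps) == 0
        assert not ps.label_image.any()

    def test_matches_flood_fill_oracle_on_random_masks(self):
        rng = np.random.default_rng(19)
        for _ in range(50):
            shape = tuple(rng.integers(3, 33, size=2))
            px = rng.random(shape) < 0.25
            ps = label_particles(_mask(px))
            comps = flood_fill_components(px)
            assert len(ps) == len(comps)
            for particle, comp in zip(ps.particles, comps):
                assert particle.area_px == len(comp)
                got_pixels = set(zip(*np.nonzero(ps.label_image == particle.label)))
                assert got_pixels == comp

    def test_object_pixel_conservation(self):
        rng = np.random.default_rng(23)
        px = rng.random((40, 40)) < 0.3
        unfiltered = label_particles(_mask(px))
        assert sum(p.area_px for p in unfiltered.particles) == int(px.sum())
        filtered = label_particles(_mask(px), ParticleFilter(min_area_px=4))
        dropped = int(px.sum()) - sum(p.area_px for p in filtered.particles)
        small = [p.area_px for p in unfiltered.particles if p.area_px < 4]
        assert dropped == sum(small)

    @given(min_area=st.integers(0, 20))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_raising_min_area_never_increases_count(self, min_area):
        rng = np.random.default_rng(5)
        px = rng.random((30, 30)) < 0.3
        n_lo = len(label_particles(_mask(px), ParticleFilter(min_area_px=min_area)))
        n_hi = len(label_particles(_mask(px), ParticleFilter(min_area_px=min_area + 1)))
        assert n_hi <= n_lo

    def test_exclude_border_drops_edge_touching_components(self):
        px = np.zeros((10, 10), dtype=bool)
        px[0, 0:3] = True  # touches border
        px[4:7, 4:7] = True  # interior
        ps = label_particles(_mask(px), ParticleFilter(exclude_border=True))
        assert len(ps) == 1
        assert not ps.particles[0].touches_border
        ps_all = label_particles(_mask(px))
        assert {p.touches_border for p in ps_all.particles} == {True, False}

    def test_relabeling_is_raster_order_and_metadata_consistent(self):
        px = np.zeros((10, 10), dtype=bool)
        px[6:9, 1:4] = True
        px[1:3, 6:9] = True
        ps = label_particles(_mask(px))
        # first pixel of label 1 precedes label 2 in raster order
        firsts = [
            np.flatnonzero((ps.label_image == p.label).ravel())[0] for p in ps.particles
        ]
        assert firsts == sorted(firsts)
        for p in ps.particles:
            minr, minc, maxr, maxc = p.bbox
            assert minr <= p.centroid[0] < maxr
            assert minc <= p.centroid[1] < maxc


def _particle_set_from_labels(labels: np.ndarray) -> ParticleSet:
    return label_particles(_mask(labels > 0))


class TestOverlapAssign:
    def test_child_centroid_inside_parent(self):
        parents = np.zeros((20, 20), dtype=int)
        parents[2:9, 2:9] = 1
        parents[12:19, 12:19] = 2
        children = np.zeros((20, 20), dtype=int)
        children[13:16, 13:16] = 1
        got = overlap_assign(_particle_set_from_labels(children), _particle_set_from_labels(parents))
        assert got == {1: 2}

    def test_zero_overlap_is_unassigned(self):
        parents = np.zeros((10, 10), dtype=int)
        parents[0:3, 0:3] = 1
        children = np.zeros((10, 10), dtype=int)
        children[7:9, 7:9] = 1
        got = overlap_assign(_particle_set_from_labels(children), _particle_set_from_labels(parents))
        assert got == {1: None}

    def test_matches_exhaustive_overlap_oracle_on_nested_masks(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            parents = np.zeros((40, 40), dtype=bool)
            children = np.zeros((40, 40), dtype=bool)
            for _ in range(4):
                r, c = rng.integers(4, 32, size=2)
                h, w = rng.integers(5, 9, size=2)
                parents[r : r + h, c : c + w] = True
                children[r + 1 : r + 1 + h // 2, c + 1 : c + 1 + w // 2] = True
            pset = label_particles(_mask(parents))
            cset = label_particles(_mask(children))
            got = overlap_assign(cset, pset)
            want = overlap_oracle(cset.label_image, pset.label_image)
            assert got == want

    def test_dimension_mismatch_rejected(self):
        a = _particle_set_from_labels(np.zeros((5, 5), dtype=int))
        b = _particle_set_from_labels(np.zeros((6, 6), dtype=int))
        with pytest.raises(ValueError):
            overlap_assign(a, b)
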