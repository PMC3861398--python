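"""Segmentation stages: stain channel, Otsu, morphology, boundaries, labeling."""

import numpy as np
import pytest
from helpers import boundary_scan_oracle, otsu_bruteforce
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage as ndi

from nestmorph import (CoreImage, SegmentationParams, StainChannel,
                       apply_overrides, binarize_otsu, extract_boundaries,
                       fill_holes, label_nests, morphological_open, preprocess,
                       segment_core)
from nestmorph.segmentation import contour_chain_length, trace_moore_contour
from nestmorph.synthetic import DEFAULT_BG_RGB, DEFAULT_FG_RGB


def _rgb(shape, color):
    img = np.empty(shape + (3,), np.uint8)
    img[:] = color
    return img


class TestPreprocess:
    def test_uniform_image_is_degenerate(self):
        ch = preprocess(CoreImage(_rgb((64, 64), DEFAULT_BG_RGB)))
        assert ch.degenerate
        with pytest.raises(ValueError, match="degenerate"):
            binarize_otsu(ch)

    def test_two_tone_image_gives_two_values(self):
        img = _rgb((64, 64), DEFAULT_BG_RGB)
        img[20:40, 20:40] = DEFAULT_FG_RGB
        ch = preprocess(CoreImage(img), denoise_radius=0)
        vals = np.unique(ch.values)
        assert vals.size == 2
        assert vals[0] == 0.0 and vals[-1] == 1.0  # stretched to [0, 1]

    def test_salt_pixel_removed_by_median(self):
        img = _rgb((64, 64), DEFAULT_BG_RGB)
        img[30, 30] = DEFAULT_FG_RGB
        ch = preprocess(CoreImage(img), denoise_radius=1)
        # the lone stained pixel has no stained neighbours: filtered away
        assert np.unique(ch.values).size == 1

    def test_dab_brown_scores_above_background(self):
        img = _rgb((64, 64), DEFAULT_BG_RGB)
        img[10:30, 10:30] = DEFAULT_FG_RGB
        ch = preprocess(CoreImage(img), denoise_radius=0)
        assert ch.values[15, 15] > ch.values[50, 50]


class TestOtsu:
    def test_bimodal_two_value_channel(self):
        v = np.full((100, 100), 0.1)
        v.ravel()[:1000] = 0.9
        mask, thr = binarize_otsu(StainChannel(values=v))
        assert 0.1 < thr < 0.9
        assert mask.sum() == 1000
        assert (v[mask] == 0.9).all()

    def test_idempotent_on_binary_channel(self):
        rng = np.random.default_rng(3)
        m = rng.random((50, 50)) < 0.3
        mask, _ = binarize_otsu(StainChannel(values=m.astype(float)))
        assert (mask == m).all()

    def test_matches_bruteforce_between_class_variance_scan(self, rng):
        """Gaussian-mixture channel: Otsu equals the exhaustive 256-bin scan."""
        v = np.concatenate([rng.normal(0.25, 0.05, 4000),
                            rng.normal(0.75, 0.08, 2000)]).reshape(100, 60)
        _, thr = binarize_otsu(StainChannel(values=v))
        oracle = otsu_bruteforce(v, nbins=256)
        # same histogram bin: centers differ from edges by half a bin width
        bin_w = (v.max() - v.min()) / 256
        assert abs(thr - oracle) <= bin_w


class TestMorphology:
    def test_opening_removes_isolated_pixel(self):
        m = np.zeros((20, 20), bool)
        m[10, 10] = True
        assert not morphological_open(m, radius=1).any()

    def test_opening_preserves_large_disk(self):
        yy, xx = np.mgrid[:60, :60]
        m = (yy - 30) ** 2 + (xx - 30) ** 2 <= 20**2
        out = morphological_open(m, radius=2)
        # anti-extensive, and changes at most a thin boundary layer
        assert (out <= m).all()
        assert (m & ~out).sum() <= np.count_nonzero(m ^ ndi.binary_erosion(m))

    def test_opening_cuts_one_pixel_bridge(self):
        m = np.zeros((30, 50), bool)
        m[5:25, 5:20] = True
        m[5:25, 30:45] = True
        m[14, 20:30] = True  # 1-px bridge
        assert ndi.label(m)[1] == 1
        out = morphological_open(m, radius=2)
        assert ndi.label(out)[1] == 2

    def test_opening_idempotent(self):
        rng = np.random.default_rng(11)
        m = ndi.binary_dilation(rng.random((80, 80)) < 0.08, iterations=2)
        once = morphological_open(m, radius=2)
        assert (morphological_open(once, radius=2) == once).all()

    def test_fill_holes_annulus_and_nested_rings(self):
        yy, xx = np.mgrid[:60, :60]
        d2 = (yy - 30) ** 2 + (xx - 30) ** 2
        annulus = (d2 <= 25**2) & (d2 >= 15**2)
        disk_full = d2 <= 25**2
        assert (fill_holes(annulus) == disk_full).all()
        nested = annulus | ((d2 <= 10**2) & (d2 >= 5**2))
        assert (fill_holes(nested) == disk_full).all()

    def test_fill_holes_idempotent_and_identity_without_holes(self):
        yy, xx = np.mgrid[:40, :40]
        solid = (yy - 20) ** 2 + (xx - 20) ** 2 <= 10**2
        assert (fill_holes(solid) == solid).all()
        rng = np.random.default_rng(2)
        m = rng.random((60, 60)) < 0.4
        once = fill_holes(m)
        assert (fill_holes(once) == once).all()


class TestBoundaries:
    def test_square_boundary_is_36_border_pixels(self):
        m = np.zeros((20, 20), bool)
        m[5:15, 5:15] = True
        bmap, contours = extract_boundaries(m)
        assert bmap.sum() == 36
        assert (bmap == boundary_scan_oracle(m)).all()
        assert len(contours) == 1
        c = contours[1]
        assert (c[0] == c[-1]).all()  # closed
        assert contour_chain_length(c) == pytest.approx(36.0)

    def test_empty_and_full_masks(self):
        empty = np.zeros((16, 16), bool)
        bmap, contours = extract_boundaries(empty)
        assert not bmap.any() and contours == {}
        full = np.ones((16, 16), bool)
        bmap, _ = extract_boundaries(full)
        rim = np.zeros((16, 16), bool)
        rim[0], rim[-1], rim[:, 0], rim[:, -1] = True, True, True, True
        assert (bmap == rim).all()

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_boundary_map_equals_neighbor_scan_oracle(self, seed):
        """Inner 4-neighbour boundary on arbitrary random masks."""
        rng = np.random.default_rng(seed)
        m = ndi.binary_dilation(rng.random((40, 40)) < 0.1,
                                iterations=rng.integers(0, 3))
        bmap, _ = extract_boundaries(m)
        assert (bmap == boundary_scan_oracle(m)).all()

    def test_one_pixel_line_out_and_back_trace(self):
        m = np.zeros((3, 7), bool)
        m[1, 1:6] = True
        c = trace_moore_contour(m)
        assert contour_chain_length(c) == pytest.approx(8.0)

    def test_moore_trace_passes_through_cut_vertex_twice(self):
        # two lobes joined only through the topmost pixel
        m = np.zeros((3, 3), bool)
        m[0, 1] = m[1, 0] = m[1, 2] = True
        c = trace_moore_contour(m)
        visited = {tuple(p) for p in c}
        assert visited == {(0, 1), (1, 0), (1, 2)}


class TestOverridesAndLabeling:
    def test_override_keep_is_identity(self):
        rng = np.random.default_rng(5)
        m = rng.random((30, 30)) < 0.3
        assert (apply_overrides(m, np.zeros_like(m, np.uint8)) == m).all()

    def test_override_remove_and_add_change_nest_count(self):
        m = np.zeros((60, 60), bool)
        m[5:20, 5:20] = True
        m[35:50, 35:50] = True
        ov = np.zeros_like(m, np.uint8)
        ov[30:55, 30:55] = 2  # remove second component
        seg = label_nests(apply_overrides(m, ov), min_size=10)
        assert seg.n_nests == 1
        ov2 = np.zeros_like(m, np.uint8)
        ov2[40:55, 5:20] = 1  # add a new block
        seg2 = label_nests(apply_overrides(m, ov2), min_size=10)
        assert seg2.n_nests == 3

    def test_override_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            apply_overrides(np.zeros((10, 10), bool), np.zeros((5, 5), np.uint8))

    def test_min_size_filter_and_connectivity(self):
        m = np.zeros((40, 40), bool)
        m[2:8, 2:8] = True  # 36 px
        m[20:30, 20:30] = True  # 100 px
        assert label_nests(m, min_size=10).n_nests == 2
        assert label_nests(m, min_size=50).n_nests == 1
        diag = np.zeros((10, 10), bool)
        diag[3, 3] = diag[4, 4] = True
        assert label_nests(diag, min_size=1).n_nests == 1  # 8-connectivity

    def test_labels_consecutive_in_raster_order(self):
        m = np.zeros((50, 50), bool)
        m[30:40, 2:12] = True
        m[2:12, 30:40] = True
        seg = label_nests(m, min_size=10)
        assert sorted(np.unique(seg.label_mask)) == [0, 1, 2]
        # first label is the component whose first pixel comes first in scan
        assert seg.label_mask[2, 30] == 1
        assert seg.label_mask[30, 2] == 2


class TestFullPipeline:
    def test_recovers_ground_truth_on_clean_core(self, clean_core):
        image, truth = clean_core
        seg = segment_core(image)
        assert seg.n_nests == truth.n_nests
        # match each true nest to the segmented label under its centroid
        for k in range(1, truth.n_nests + 1):
            true_px = truth.label_mask == k
            labels, counts = np.unique(seg.label_mask[true_px], return_counts=True)
            lab = labels[np.argmax(counts)]
            assert lab > 0
            seg_area = (seg.label_mask == lab).sum()
            assert seg_area == pytest.approx(truth.areas[k - 1], rel=0.05)

    def test_pipeline_deterministic(self, clean_core):
        image, _ = clean_core
        a = segment_core(image)
        b = segment_core(image)
        assert (a.label_mask == b.label_mask).all()
        assert a.params_used == b.params_used

    def test_params_recorded(self, clean_core):
        image, _ = clean_core
        seg = segment_core(image, SegmentationParams(1, 2, 40))
        assert seg.params_used["min_size"] == 40
        assert seg.params_used["denoise_radius"] == 1
        assert "otsu_threshold" in seg.params_used
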