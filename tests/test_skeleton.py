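"""Skeleton pixel classification, junction clustering, branch tracing."""

import numpy as np
import pytest

from phenorosette import imaging, skeleton, synthetic
from phenorosette.skeleton import (
    classify_pixels,
    cluster_junctions,
    skeletonize,
    summarize_skeleton,
    trace_branches,
)

from conftest import (
    draw_line,
    draw_x,
    draw_y,
    oracle_classify,
    oracle_components,
    oracle_junction_clusters,
    oracle_stub_count,
)


class TestSkeletonize:
    def test_thick_bar_thins_to_single_line(self):
        mask = np.zeros((20, 120), dtype=bool)
        mask[8:13, 10:110] = True
        sk = skeletonize(mask)
        assert len(oracle_components(sk)) == 1
        classes = oracle_classify(sk)
        assert len(classes["junction"]) == 0

    def test_annulus_keeps_its_loop(self):
        yy, xx = np.mgrid[:80, :80]
        d2 = (yy - 40) ** 2 + (xx - 40) ** 2
        mask = (d2 <= 30**2) & (d2 >= 20**2)
        sk = skeletonize(mask)
        classes = oracle_classify(sk)
        assert len(oracle_components(sk)) == 1
        assert len(classes["end"]) == 0  # closed loop: no end pixels
        assert len(classes["junction"]) == 0

    def test_empty_mask_gives_empty_skeleton(self):
        assert not skeletonize(np.zeros((10, 10), dtype=bool)).any()


class TestClassifyPixels:
    def test_straight_line_counts(self):
        sk = draw_line(100)
        classes = classify_pixels(sk)
        assert int((classes == skeleton.END).sum()) == 2
        assert int((classes == skeleton.SLAB).sum()) == 98
        assert int((classes == skeleton.JUNCTION).sum()) == 0

    @pytest.mark.parametrize(
        "shape_fn", [draw_line, lambda: draw_y(), lambda: draw_x()]
    )
    def test_matches_neighbor_count_oracle(self, shape_fn):
        sk = shape_fn() if shape_fn is not draw_line else draw_line(50)
        classes = classify_pixels(sk)
        oracle = oracle_classify(sk)
        got = {
            "end": {tuple(p) for p in np.argwhere(classes == skeleton.END)},
            "slab": {tuple(p) for p in np.argwhere(classes == skeleton.SLAB)},
            "junction": {
                tuple(p) for p in np.argwhere(classes == skeleton.JUNCTION)
            },
        }
        assert got == oracle

    def test_closed_ring_is_all_slab(self, shape_ring):
        classes = classify_pixels(shape_ring)
        assert int((classes == skeleton.END).sum()) == 0
        assert int((classes == skeleton.JUNCTION).sum()) == 0
        assert int((classes == skeleton.SLAB).sum()) == int(shape_ring.sum())


class TestJunctionClusters:
    def test_y_is_one_triple_point(self, shape_y):
        clusters = cluster_junctions(shape_y)
        assert len(clusters) == len(oracle_junction_clusters(shape_y)) == 1
        assert clusters[0].degree == oracle_stub_count(
            shape_y, set(clusters[0].pixels)
        ) == 3

    def test_x_is_one_quadruple_point(self, shape_x):
        clusters = cluster_junctions(shape_x)
        assert len(clusters) == 1
        assert clusters[0].degree == oracle_stub_count(
            shape_x, set(clusters[0].pixels)
        ) == 4

    def test_two_ys_bridged_are_two_clusters(self):
        # two Ys joined tip-to-tip through their down-arms
        a = draw_y(arm=10)
        h, w = a.shape
        c = w // 2
        big = np.zeros((2 * h, w), dtype=bool)
        big[:h] = a
        big[h:] = a[::-1]  # mirrored: the two vertical arms line up
        tip = c + 10  # row of the top Y's down-arm tip
        big[tip + 1 : 2 * h - 1 - tip, c] = True  # bridge between the tips
        assert len(oracle_components(big)) == 1
        clusters = cluster_junctions(big)
        assert len(clusters) == 2
        assert all(cl.degree == 3 for cl in clusters)


class TestBranches:
    def test_straight_line_length(self):
        branches = trace_branches(draw_line(100))
        assert len(branches) == 1
        assert branches[0].length == pytest.approx(99.0)

    def test_diagonal_line_length(self):
        branches = trace_branches(draw_line(50, diagonal=True))
        assert len(branches) == 1
        assert branches[0].length == pytest.approx(49 * np.sqrt(2))

    def test_y_branch_lengths(self):
        sk = draw_y(arm=20)
        branches = trace_branches(sk)
        assert len(branches) == 3
        lengths = sorted(b.length for b in branches)
        # two diagonal arms of 20 steps, one vertical arm of 20 steps
        assert lengths[0] == pytest.approx(20.0)
        assert lengths[1] == lengths[2] == pytest.approx(20 * np.sqrt(2))

    def test_isolated_cycle_is_one_branch(self, shape_ring):
        branches = trace_branches(shape_ring)
        assert len(branches) == 1
        assert branches[0].is_cycle
        n = int(shape_ring.sum())
        # circumference: n steps, at least n and at most n*sqrt(2)
        assert n <= branches[0].length <= n * np.sqrt(2) + 1e-9


class TestSummary:
    def test_single_line_summary(self):
        s = summarize_skeleton(draw_line(100))
        assert (
            s.n_branches,
            s.n_actual_junctions,
            s.n_end_pixels,
            s.n_junction_pixels,
            s.n_slab_pixels,
            s.n_triple_points,
            s.n_quadruple_points,
        ) == (1, 0, 2, 0, 98, 0, 0)
        assert s.avg_branch_length == s.max_branch_length == 99.0

    def test_y_summary(self, shape_y):
        s = summarize_skeleton(shape_y)
        assert s.n_triple_points == 1
        assert s.n_branches == 3

    def test_two_disjoint_lines_additive(self):
        a = draw_line(40)
        b = draw_line(60)
        joint = np.zeros((12, 70), dtype=bool)
        joint[:5, :44] = a
        joint[7:12, :64] = b
        sa, sb, sj = (summarize_skeleton(m) for m in (a, b, joint))
        assert sj.n_branches == sa.n_branches + sb.n_branches == 2
        assert sj.n_end_pixels == 4
        assert sj.n_slab_pixels == sa.n_slab_pixels + sb.n_slab_pixels
        assert sj.max_branch_length == max(
            sa.max_branch_length, sb.max_branch_length
        )
        total = (
            sa.avg_branch_length * sa.n_branches
            + sb.avg_branch_length * sb.n_branches
        )
        assert sj.avg_branch_length == pytest.approx(total / 2)

    def test_isolated_pixel_is_end_with_zero_length_branch(self):
        sk = np.zeros((9, 9), dtype=bool)
        sk[4, 4] = True
        s = summarize_skeleton(sk)
        assert s.n_end_pixels == 1
        assert s.n_branches == 1
        assert s.max_branch_length == 0.0

    def test_empty_skeleton_is_all_zero_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, "phenorosette.skeleton"):
            s = summarize_skeleton(np.zeros((5, 5), dtype=bool))
        assert s.n_branches == 0 and s.n_end_pixels == 0
        assert caplog.records

    def test_rotation_by_90_degrees_invariant(self, shape_y):
        s0 = summarize_skeleton(shape_y)
        s90 = summarize_skeleton(np.rot90(shape_y))
        assert s0 == s90

    def test_endpoint_lower_bound_for_loop_free_components(self):
        img, truth = synthetic.gen_inflorescence_image(12, 1, seed=9)
        sk = skeletonize(truth["mask"])
        s = summarize_skeleton(sk)
        n_components = len(oracle_components(sk))
        assert s.n_end_pixels >= 2 * n_components


class TestGeneratorIdentity:
    @pytest.mark.parametrize(
        "n_fruits,n_branches,seed",
        [(0, 0, 0), (10, 0, 1), (25, 3, 2), (40, 2, 5)],
    )
    def test_fruit_count_equals_triple_points(self, n_fruits, n_branches, seed):
        """Each lateral fruit stub (and each side-branch attachment)
        contributes exactly one triple point on the rendered skeleton."""
        img, truth = synthetic.gen_inflorescence_image(
            n_fruits, n_branches, seed=seed
        )
        sk = skeletonize(truth["mask"])
        s = summarize_skeleton(sk)
        assert s.n_triple_points == truth["expected_triple_points"]
        assert s.n_quadruple_points == 0
        assert s.n_actual_junctions == s.n_triple_points

    def test_fruit_model_predictors_track_truth_through_segmentation(self):
        """Going through the full image route (render, segment, thin) the
        triple-point count stays within the junction-artifact tolerance."""
        img, truth = synthetic.gen_inflorescence_image(30, 2, seed=11)
        mask = imaging.segment_plants(img, imaging.SegmentationConfig())
        s = summarize_skeleton(skeletonize(mask))
        assert abs(s.n_triple_points - truth["expected_triple_points"]) <= 3
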