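"""Per-object ellipsoid-fit segmentation: scores, selection, watershed."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tunel3d.io_stacks import LabelVolume, SegConfig
from tunel3d.oracles import poe_sweep_oracle
from tunel3d.poe3d import (
    ComponentTree,
    _erode_objects,
    _sym3_eigvalsh,
    ellipsoid_fit_score,
    iterative_poe_segment,
    poe_segment,
    watershed_split,
)
from tunel3d.synthetic_data import make_touching_fixture

from conftest import smooth_quantized_image


def _ball(shape, center, r2):
    g = np.mgrid[: shape[0], : shape[1], : shape[2]]
    return ((g[0] - center[0]) ** 2 + (g[1] - center[1]) ** 2 + (g[2] - center[2]) ** 2) <= r2


class TestEllipsoidFit:
    def test_digitized_ball_scores_high(self):
        # regression constant computed by direct voxelization of the
        # equal-moment ellipsoid for a radius-5 digitized ball
        ball = _ball((16, 16, 16), (8, 8, 8), 25)
        fit = ellipsoid_fit_score(ball, (1.0, 1.0, 1.0))
        assert fit.fit_score == pytest.approx(0.941747572815534, abs=1e-9)
        assert fit.fit_score >= 0.90
        assert np.allclose(fit.diameters_um, fit.diameters_um[0])  # isotropic

    def test_single_voxel_is_perfect_by_convention(self):
        reg = np.zeros((5, 5, 5), bool)
        reg[2, 2, 2] = True
        assert ellipsoid_fit_score(reg, (1, 1, 1)).fit_score == 1.0

    def test_l_shape_scores_below_ball(self):
        L = np.zeros((8, 8, 8), bool)
        L[2:4, 1:6, 2:4] = True
        L[2:4, 1:3, 2:7] = True
        score = ellipsoid_fit_score(L, (1, 1, 1)).fit_score
        assert score == pytest.approx(0.6521739130434783, abs=1e-9)
        assert score < 0.941747572815534

    def test_empty_region_raises(self):
        with pytest.raises(ValueError):
            ellipsoid_fit_score(np.zeros((4, 4, 4), bool), (1, 1, 1))

    def test_diameters_sorted_descending_and_moments_psd(self):
        rng = np.random.default_rng(0)
        reg = _ball((12, 12, 12), (6, 6, 6), 16) & (rng.random((12, 12, 12)) < 0.9)
        fit = ellipsoid_fit_score(reg, (2.0, 0.5, 0.5))
        assert np.all(np.diff(fit.diameters_um) <= 1e-12)
        assert np.allclose(fit.moments, fit.moments.T)
        assert np.linalg.eigvalsh(fit.moments).min() >= -1e-9

    def test_closed_form_eigenvalues_match_lapack(self):
        rng = np.random.default_rng(1)
        m = rng.normal(size=(200, 3, 3))
        cov = m @ m.transpose(0, 2, 1)
        assert np.allclose(_sym3_eigvalsh(cov), np.linalg.eigvalsh(cov), atol=1e-8)


class TestComponentTree:
    def test_node_supports_are_level_set_components(self):
        from scipy import ndimage

        rng = np.random.default_rng(5)
        img = rng.integers(0, 6, size=(6, 9, 9)).astype(np.uint8)
        tree = ComponentTree(img, 6, (1, 1, 1))
        struct = ndimage.generate_binary_structure(3, 1)
        for node in tree.pre_order:
            coords = tree.node_coords(node)
            lab, _ = ndimage.label(img >= tree.level[node], structure=struct)
            c = np.unravel_index(tree.canon_pixels[node], img.shape)
            want = np.argwhere(lab == lab[c])
            assert {tuple(x) for x in coords} == {tuple(x) for x in want}

    def test_subtree_sizes_consistent_between_modes(self):
        rng = np.random.default_rng(6)
        img = rng.integers(0, 8, size=(5, 8, 8)).astype(np.uint8)
        full = ComponentTree(img, 6, (1, 1, 1), need_moments=True)
        light = ComponentTree(img, 6, (1, 1, 1), need_moments=False)
        assert np.array_equal(full.node_sizes(), light.node_sizes())
        assert np.array_equal(full.end - full.start, full.node_sizes())


class TestPoeSegment:
    def test_two_blobs_match_brute_force_oracle(self, iso_config):
        img = np.zeros((24, 40, 24))
        g = np.mgrid[:24, :40, :24]
        for c, peak in (((12, 10, 12), 200), ((12, 30, 12), 120)):
            d2 = (g[0] - c[0]) ** 2 + (g[1] - c[1]) ** 2 + (g[2] - c[2]) ** 2
            img = np.maximum(img, peak * (d2 <= 16))
        from scipy import ndimage

        img = ndimage.gaussian_filter(img, 1.0).round().astype(np.uint8)
        res = poe_segment(img, iso_config, (1, 1, 1))
        assert res.n_objects == 2
        # each object contains its blob's peak voxel
        assert res.objects.labels[12, 10, 12] > 0
        assert res.objects.labels[12, 30, 12] > 0
        assert res.objects.labels[12, 10, 12] != res.objects.labels[12, 30, 12]
        got = {
            (frozenset(map(tuple, np.argwhere(res.objects.labels == r.label))), int(r.threshold))
            for r in res.records.itertuples()
        }
        assert got == poe_sweep_oracle(img, iso_config, (1, 1, 1))

    def test_uniform_image_yields_no_objects(self, iso_config):
        res = poe_segment(np.full((8, 8, 8), 7, np.uint8), iso_config, (1, 1, 1))
        assert res.n_objects == 0

    def test_oversized_blob_rejected_by_diameter(self):
        cfg = SegConfig(min_diameter_um=1.0, max_diameter_um=3.0, min_fit_score=0.3,
                        voxel_size=(1, 1, 1))
        img = (200 * _ball((20, 20, 20), (10, 10, 10), 49)).astype(np.uint8)
        res = poe_segment(img, cfg, (1, 1, 1))
        assert res.n_objects == 0

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_monotone_intensity_invariance(self, seed):
        """A strictly increasing grey-level map leaves object supports unchanged."""
        iso_config = SegConfig(
            min_diameter_um=2.0, max_diameter_um=20.0, min_fit_score=0.3,
            voxel_size=(1.0, 1.0, 1.0),
        )
        rng = np.random.default_rng(seed)
        img = smooth_quantized_image(rng, (12, 14, 14), 10)
        res = poe_segment(img, iso_config, (1, 1, 1))
        lut = np.cumsum(rng.integers(1, 5, size=16)).astype(np.int32)
        res2 = poe_segment(lut[img], iso_config, (1, 1, 1))
        sup1 = {frozenset(map(tuple, np.argwhere(res.objects.labels == r.label))): r.threshold
                for r in res.records.itertuples()}
        sup2 = {frozenset(map(tuple, np.argwhere(res2.objects.labels == r.label))): r.threshold
                for r in res2.records.itertuples()}
        assert set(sup1) == set(sup2)
        for sup, t in sup1.items():
            assert sup2[sup] == lut[t]  # thresholds map through the LUT

    def test_seeds_lie_inside_their_objects(self, iso_config):
        img = (180 * _ball((14, 14, 14), (7, 7, 7), 16)).astype(np.uint8)
        res = poe_segment(img, iso_config, (1, 1, 1))
        assert res.n_objects == 1
        inside = res.objects.labels[res.seeds.labels > 0]
        assert np.all(inside == res.seeds.labels[res.seeds.labels > 0])

    def test_erosion_to_nothing_keeps_brightest_voxel(self):
        labels = np.zeros((5, 5, 5), np.int32)
        labels[2, 2, 2:4] = 1  # two voxels: two erosions empty it
        img = np.zeros((5, 5, 5), np.uint8)
        img[2, 2, 2], img[2, 2, 3] = 50, 90
        seeds = _erode_objects(LabelVolume(labels, (1, 1, 1)), img, 2, 6)
        assert seeds.labels.sum() == 1
        assert seeds.labels[2, 2, 3] == 1


class TestIterativePoe:
    def test_touching_fixture_rescued_on_second_pass(self):
        stack, truth = make_touching_fixture(seed=0)
        cfg = SegConfig(voxel_size=stack.voxel_size)
        img = stack.channel("TUNEL")
        single = poe_segment(img, cfg, stack.voxel_size)
        assert single.n_objects == 1
        res = iterative_poe_segment(img, cfg, stack.voxel_size)
        assert res.n_objects == 2
        assert res.records["iteration_found"].tolist() == [1, 2]
        # each found object overlaps a distinct truth nucleus
        hit = set()
        for r in res.records.itertuples():
            obj = res.objects.labels == r.label
            overlaps = [np.logical_and(obj, truth.labels.labels == t).sum() for t in (1, 2)]
            hit.add(int(np.argmax(overlaps)))
        assert hit == {0, 1}

    def test_empty_image_stops_after_first_iteration(self, iso_config):
        res = iterative_poe_segment(np.zeros((6, 6, 6), np.uint8), iso_config, (1, 1, 1))
        assert res.n_objects == 0
        assert res.iterations_used == 1

    def test_fixed_point_equals_single_pass(self, iso_config):
        img = (150 * _ball((14, 14, 14), (7, 7, 7), 16)).astype(np.uint8)
        single = poe_segment(img, iso_config, (1, 1, 1))
        res = iterative_poe_segment(img, iso_config, (1, 1, 1))
        assert res.iterations_used == 2  # second pass finds nothing and stops
        assert np.array_equal(res.objects.labels, single.objects.labels)

    def test_earlier_objects_persist_unchanged(self):
        stack, _ = make_touching_fixture(seed=1)
        cfg = SegConfig(voxel_size=stack.voxel_size)
        img = stack.channel("TUNEL")
        first = poe_segment(img, cfg, stack.voxel_size)
        final = iterative_poe_segment(img, cfg, stack.voxel_size)
        for lab in range(1, first.n_objects + 1):
            assert np.array_equal(first.objects.labels == lab, final.objects.labels == lab)

    def test_max_iterations_records_warning(self):
        stack, _ = make_touching_fixture(seed=2)
        cfg = SegConfig(voxel_size=stack.voxel_size, max_iterations=1)
        res = iterative_poe_segment(stack.channel("TUNEL"), cfg, stack.voxel_size)
        assert res.iterations_used == 1
        assert res.warnings


class TestWatershedSplit:
    def test_single_seed_takes_whole_ball(self):
        mask = _ball((16, 16, 16), (8, 8, 8), 30)
        seeds = np.zeros(mask.shape, np.int32)
        seeds[8, 8, 8] = 1
        out = watershed_split(mask, seeds, (1, 1, 1))
        assert np.array_equal(out.labels > 0, mask)
        assert out.n_labels == 1

    def test_symmetric_dumbbell_splits_at_neck(self):
        shape = (20, 34, 20)
        g = np.mgrid[: shape[0], : shape[1], : shape[2]]
        b1 = ((g[0] - 10) ** 2 + (g[1] - 9) ** 2 + (g[2] - 10) ** 2) <= 36
        b2 = ((g[0] - 10) ** 2 + (g[1] - 24) ** 2 + (g[2] - 10) ** 2) <= 36
        neck = (np.abs(g[0] - 10) <= 1) & (np.abs(g[2] - 10) <= 1) & (g[1] >= 9) & (g[1] <= 24)
        mask = b1 | b2 | neck
        seeds = np.zeros(shape, np.int32)
        seeds[10, 9, 10], seeds[10, 24, 10] = 1, 2
        out = watershed_split(mask, seeds, (1, 1, 1))
        v1 = int((out.labels == 1).sum())
        v2 = int((out.labels == 2).sum())
        assert (v1, v2) == (942, 942)  # frozen by symmetry
        assert abs(v1 - v2) <= 0.01 * max(v1, v2)

    def test_seed_outside_mask_is_discarded(self):
        mask = _ball((12, 12, 12), (6, 6, 6), 16)
        seeds = np.zeros(mask.shape, np.int32)
        seeds[6, 6, 6] = 1
        seeds[0, 0, 0] = 2  # outside
        out = watershed_split(mask, seeds, (1, 1, 1))
        assert out.n_labels == 1
        assert np.array_equal(out.labels > 0, mask)

    def test_no_seeds_returns_whole_mask_as_one_object(self):
        mask = _ball((10, 10, 10), (5, 5, 5), 9)
        out = watershed_split(mask, np.zeros(mask.shape, np.int32), (1, 1, 1))
        assert out.n_labels == 1
        assert np.array_equal(out.labels > 0, mask)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            watershed_split(np.ones((4, 4, 4), bool), np.zeros((5, 4, 4), np.int32), (1, 1, 1))
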