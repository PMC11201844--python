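"""Similarity measures, CPD point-set registration, and two-phase tree matching."""

import numpy as np
import pytest

from conftest import paint_tube, tube_tree_scene
from resectmargin.errors import EmptyInputError, GridMismatchError
from resectmargin.imaging import BinaryMask
from resectmargin.matching import (
    MatchResult,
    build_feature_points,
    dice,
    dice_penalized,
    match_trees,
    nonrigid_cpd,
    phase1_match,
    phase2_match,
    rigid_cpd,
    skeletonize,
    skeletonize_mask,
)
from resectmargin.segmentation import extract_subvascular_trees


def _mask(arr):
    return BinaryMask(arr, (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))


def _skeleton_cloud(n=200, seed=0):
    """A bent branching curve resembling a vessel centerline."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 1, n)
    pts = np.stack(
        [
            40 * t + 5 * np.sin(3 * np.pi * t),
            30 * t + 8 * np.cos(2 * np.pi * t),
            20 * np.sin(np.pi * t),
        ],
        axis=1,
    )
    return pts + rng.normal(0, 0.3, size=pts.shape)


class TestSkeletonize:
    def test_thin_line_unchanged(self):
        arr = np.zeros((20, 7, 7), dtype=bool)
        arr[3:17, 3, 3] = True
        idx = skeletonize_mask(_mask(arr))
        np.testing.assert_array_equal(idx, np.argwhere(arr))

    def test_solid_tube_reduces_to_spanning_curve(self):
        arr = np.zeros((50, 20, 20), dtype=bool)
        paint_tube(arr, (5, 10, 10), (1, 0, 0), 40, radius=4.0)
        idx = skeletonize_mask(_mask(arr))
        assert len(idx) <= 60
        assert idx[:, 0].min() <= 9 and idx[:, 0].max() >= 40  # spans the ends
        from scipy import ndimage as ndi

        skel = np.zeros_like(arr)
        skel[tuple(idx.T)] = True
        _, n = ndi.label(skel, np.ones((3, 3, 3)))
        assert n == 1

    def test_component_count_preserved(self):
        arr = np.zeros((40, 30, 30), dtype=bool)
        paint_tube(arr, (5, 10, 10), (1, 0, 0), 12, radius=3.0)
        paint_tube(arr, (24, 18, 18), (1, 0.3, 0), 12, radius=3.0)
        idx = skeletonize_mask(_mask(arr))
        from scipy import ndimage as ndi

        skel = np.zeros_like(arr)
        skel[tuple(idx.T)] = True
        _, n = ndi.label(skel, np.ones((3, 3, 3)))
        assert n == 2


class TestDice:
    def test_identical_masks(self):
        rng = np.random.default_rng(0)
        a = _mask(rng.random((10, 10, 10)) > 0.5)
        assert dice(a, a) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((8, 8, 8), bool)
        b = np.zeros((8, 8, 8), bool)
        a[:2], b[6:] = True, True
        assert dice(_mask(a), _mask(b)) == 0.0

    def test_half_overlap(self):
        a = np.zeros((10, 10, 10), bool)
        b = np.zeros((10, 10, 10), bool)
        a.ravel()[:100] = True
        b.ravel()[50:150] = True
        assert dice(_mask(a), _mask(b)) == pytest.approx(0.5)

    def test_grid_mismatch_rejected(self):
        a = _mask(np.ones((4, 4, 4), bool))
        b = BinaryMask(np.ones((4, 4, 4), bool), (2, 2, 2), (0, 0, 0))
        with pytest.raises(GridMismatchError):
            dice(a, b)

    def test_penalized_equals_dice_for_equal_volumes(self):
        rng = np.random.default_rng(1)
        a = _mask(rng.random((10, 10, 10)) > 0.5)
        b_arr = np.roll(a.data, 1, axis=0)
        b = _mask(b_arr)
        if a.count() == b.count():
            assert dice_penalized(a, b) == pytest.approx(dice(a, b))

    def test_penalized_quarters_known_example(self):
        # |a| = 400, |b| = 100, |a&b| = 80 -> dice 0.32, r = 4, DSCP = 0.02
        a = np.zeros((10, 10, 10), bool)
        b = np.zeros((10, 10, 10), bool)
        a.ravel()[:400] = True
        b.ravel()[320:420] = True
        assert dice(_mask(a), _mask(b)) == pytest.approx(0.32)
        assert dice_penalized(_mask(a), _mask(b)) == pytest.approx(0.02)

    def test_penalized_never_exceeds_dice(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = _mask(rng.random((8, 8, 8)) > rng.uniform(0.3, 0.7))
            b = _mask(rng.random((8, 8, 8)) > rng.uniform(0.3, 0.7))
            if a.count() and b.count():
                assert dice_penalized(a, b) <= dice(a, b) + 1e-12

    def test_empty_mask_rejected_for_penalized(self):
        a = _mask(np.ones((4, 4, 4), bool))
        b = _mask(np.zeros((4, 4, 4), bool))
        with pytest.raises(EmptyInputError):
            dice_penalized(a, b)


def _rot_z(deg):
    th = np.deg2rad(deg)
    return np.array(
        [[1, 0, 0], [0, np.cos(th), -np.sin(th)], [0, np.sin(th), np.cos(th)]]
    )


class TestRigidCPD:
    def test_identity_pair(self):
        pts = _skeleton_cloud()
        res = rigid_cpd(pts, pts)
        assert np.abs(res.rotation - np.eye(3)).max() < 1e-3
        assert np.linalg.norm(res.translation) < 1e-2
        assert res.scale == pytest.approx(1.0, abs=1e-3)

    def test_known_rotation_translation_recovery(self):
        pts = _skeleton_cloud()
        R = _rot_z(10.0)
        t = np.array([4.0, 2.0, -3.0])
        fixed = pts @ R.T + t
        res = rigid_cpd(pts, fixed)
        angle = np.rad2deg(
            np.arccos(np.clip((np.trace(res.rotation @ R.T) - 1) / 2, -1, 1))
        )
        assert angle < 0.5
        assert np.linalg.norm(res.translation - t) < 0.5

    def test_outlier_contamination(self):
        rng = np.random.default_rng(3)
        pts = _skeleton_cloud()
        t = np.array([4.0, 2.0, -3.0])
        fixed = pts + t
        moving = np.vstack([pts, rng.uniform(-20, 60, size=(20, 3))])
        res = rigid_cpd(moving, fixed, w=0.1)
        assert np.linalg.norm(res.translation - t) < 1.0

    def test_collinear_degeneracy_warns(self):
        line = np.stack([np.linspace(0, 10, 30)] * 3, axis=1)
        with pytest.warns(UserWarning, match="collinear"):
            rigid_cpd(line, line + 1.0)


class TestNonRigidCPD:
    def test_identity_correspondence(self):
        pts = _skeleton_cloud(80)
        res = nonrigid_cpd(pts, pts)
        np.testing.assert_array_equal(res.correspondence, np.arange(len(pts)))
        assert np.linalg.norm(res.displaced - pts, axis=1).max() < 0.2

    def test_smooth_warp_recovery(self):
        pts = _skeleton_cloud(150)
        warp = 3.0 * np.sin(2 * np.pi * pts[:, [1, 2, 0]] / 80.0)
        fixed = pts + warp
        res = nonrigid_cpd(pts, fixed)
        err = np.linalg.norm(res.displaced - fixed, axis=1)
        assert err.mean() < 1.0

    def test_extra_moving_points_do_not_break_correspondence(self):
        rng = np.random.default_rng(4)
        pts = _skeleton_cloud(100)
        moving = np.vstack([pts, rng.uniform(0, 40, size=(20, 3))])
        res = nonrigid_cpd(moving, pts)
        correct = (res.correspondence[:100] == np.arange(100)).mean()
        assert correct >= 0.9


class TestPhaseMatching:
    def test_self_match_is_complete_and_perfect(self):
        vessels, trees = tube_tree_scene()
        result = phase1_match(trees, trees, vessels, vessels)
        assert len(result.pairs) == len(trees)
        assert all(c.dsc_target == pytest.approx(1.0) for c in result.pairs)
        assert all(c.post_tree_id == c.pre_tree_id for c in result.pairs)

    def test_orphan_post_tree_stays_unmatched(self):
        pre_vessels, pre_trees = tube_tree_scene()
        post_vessels, post_trees = tube_tree_scene(orphan=True)
        result = match_trees(pre_trees, post_trees, pre_vessels, post_vessels)
        assert len(post_trees) == len(pre_trees) + 1
        assert len(result.unmatched_post) == 1
        orphan_id = result.unmatched_post[0]
        orphan = next(t for t in post_trees if t.id == orphan_id)
        # the orphan is the fabricated extra tube (x ~ 80), not a real tree
        assert orphan.centroid[2] > 70

    def test_global_translation_absorbed_by_rigid_cpd(self):
        pre_vessels, pre_trees = tube_tree_scene()
        post_vessels, post_trees = tube_tree_scene(translate=(2.0, 3.0, 3.0))
        result = phase1_match(pre_trees, post_trees, pre_vessels, post_vessels)
        assert len(result.pairs) >= 0.8 * len(pre_trees)

    def test_one_to_one_invariant(self):
        pre_vessels, pre_trees = tube_tree_scene()
        post_vessels, post_trees = tube_tree_scene(translate=(1.0, 1.0, 2.0))
        result = match_trees(pre_trees, post_trees, pre_vessels, post_vessels)
        posts = [c.post_tree_id for c in result.pairs]
        pres = [c.pre_tree_id for c in result.pairs]
        assert len(posts) == len(set(posts)) and len(pres) == len(set(pres))
        for c in result.pairs:
            if c.phase == "I":
                assert c.dsc_target >= 0.5 and c.dsc_surround >= 0.2
            else:
                assert c.dscp >= 0.3

    def test_matching_is_deterministic(self):
        pre_vessels, pre_trees = tube_tree_scene()
        post_vessels, post_trees = tube_tree_scene(translate=(1.0, 2.0, 1.0))
        r1 = match_trees(pre_trees, post_trees, pre_vessels, post_vessels)
        r2 = match_trees(pre_trees, post_trees, pre_vessels, post_vessels)
        assert [(c.post_tree_id, c.pre_tree_id, c.dsc_target) for c in r1.pairs] == [
            (c.post_tree_id, c.pre_tree_id, c.dsc_target) for c in r2.pairs
        ]


class TestPhase2:
    def test_displaced_tree_recovered(self):
        pre_vessels, pre_trees = tube_tree_scene()
        # displace one tree by 4 mm; the rest are identical
        arr = np.zeros(pre_vessels.shape, dtype=bool)
        for t in pre_trees:
            vox = t.voxels.copy()
            if t.id == 2:
                vox = vox + np.array([0, 0, 4])
            arr[vox[:, 0], vox[:, 1], vox[:, 2]] = True
        post_vessels = BinaryMask(arr, (1, 1, 1), (0, 0, 0))
        post_trees = extract_subvascular_trees(post_vessels)
        # ids are volume-ordered, so find the displaced post tree by centroid
        moved = min(
            post_trees,
            key=lambda t: min(
                np.linalg.norm(t.centroid - (p.centroid + [0, 0, 4]))
                for p in pre_trees
                if p.id == 2
            ),
        )
        result = self._seed_phase1_by_centroid(pre_trees, post_trees, moved.id)
        result = phase2_match(result, pre_trees, post_trees, pre_vessels)
        pair = next((c for c in result.pairs if c.post_tree_id == moved.id), None)
        assert pair is not None and pair.phase == "II"
        assert pair.dscp >= 0.3

    def _seed_phase1_by_centroid(self, pre_trees, post_trees, skip_id):
        from resectmargin.matching import MatchCandidate

        result = MatchResult()
        for t in post_trees:
            if t.id == skip_id:
                continue
            pre = min(pre_trees, key=lambda p: np.linalg.norm(p.centroid - t.centroid))
            result.pairs.append(
                MatchCandidate(t.id, pre.id, 1.0, 1.0, 1.0, 1.0, "I")
            )
        result.unmatched_post = [skip_id]
        used = {c.pre_tree_id for c in result.pairs}
        result.unmatched_pre = [p.id for p in pre_trees if p.id not in used]
        return result

    def test_orphan_tree_yields_null_result(self):
        pre_vessels, pre_trees = tube_tree_scene()
        post_vessels, post_trees = tube_tree_scene(orphan=True)
        orphan_id = max(
            post_trees, key=lambda t: t.centroid[2]
        ).id  # fabricated tube at x ~ 80
        result = self._seed_phase1_by_centroid(pre_trees, post_trees, orphan_id)
        result = phase2_match(result, pre_trees, post_trees, pre_vessels)
        assert orphan_id in result.unmatched_post

    def test_severely_bent_tree_falls_below_threshold(self):
        # post tree with two 45-degree kinks vs a straight pre counterpart
        shape = (72, 96, 96)
        pre_arr = np.zeros(shape, dtype=bool)
        paint_tube(pre_arr, (36, 20, 48), (0, 1, 0), 45, radius=3.0)
        post_arr = np.zeros(shape, dtype=bool)
        paint_tube(post_arr, (36, 20, 48), (0, 1, 0), 15, radius=3.0)
        paint_tube(post_arr, (36, 35, 48), (0, 0.7071, 0.7071), 15, radius=3.0)
        paint_tube(post_arr, (36, 45.6, 58.6), (0, 0.7071, -0.7071), 15, radius=3.0)
        scaffold_pre = np.zeros(shape, dtype=bool)
        scaffold_post = np.zeros(shape, dtype=bool)
        for x in (14, 30, 78):
            paint_tube(scaffold_pre, (20, 20, x), (0, 1, 0), 40, radius=3.0, bend=2.0)
            paint_tube(scaffold_post, (20, 20, x), (0, 1, 0), 40, radius=3.0, bend=2.0)
        pre_vessels = BinaryMask(pre_arr | scaffold_pre, (1, 1, 1), (0, 0, 0))
        post_vessels = BinaryMask(post_arr | scaffold_post, (1, 1, 1), (0, 0, 0))
        pre_trees = extract_subvascular_trees(pre_vessels)
        post_trees = extract_subvascular_trees(post_vessels)
        bent_id = min(post_trees, key=lambda t: abs(t.centroid[1] - 38)).id
        result = self._seed_phase1_by_centroid(pre_trees, post_trees, bent_id)
        result = phase2_match(result, pre_trees, post_trees, pre_vessels)
        assert bent_id in result.unmatched_post


class TestFeaturePoints:
    def test_identical_trees_give_coincident_pairs(self):
        vessels, trees = tube_tree_scene(n_trees=3)
        result = phase1_match(trees, trees, vessels, vessels)
        fps = build_feature_points(result, trees, trees)
        offsets = np.linalg.norm(fps.displacements, axis=1)
        assert offsets.mean() < 0.5

    def test_known_warp_recovery(self):
        pre_vessels, pre_trees = tube_tree_scene(n_trees=3)
        # post trees: the same tubes shifted by a smooth, position-dependent warp
        shift = np.array([0.0, 0.0, 3.0])
        arr = np.zeros(pre_vessels.shape, dtype=bool)
        for t in pre_trees:
            vox = t.voxels + np.round(shift).astype(int)
            arr[vox[:, 0], vox[:, 1], vox[:, 2]] = True
        post_vessels = BinaryMask(arr, (1, 1, 1), (0, 0, 0))
        post_trees = extract_subvascular_trees(post_vessels)
        result = match_trees(pre_trees, post_trees, pre_vessels, post_vessels)
        fps = build_feature_points(result, pre_trees, post_trees)
        # every kept post point should map within 1.5 mm of its true position
        err = np.linalg.norm(fps.displacements - (-shift), axis=1)
        assert err.mean() < 1.5

    def test_feature_point_count_on_phantom(self, full_run):
        assert len(full_run.feature_points) >= 250

    def test_points_lie_near_source_skeletons(self, full_run):
        fps = full_run.feature_points
        by_id = {t.id: t for t in full_run.post_trees}
        rng = np.random.default_rng(0)
        take = rng.choice(len(fps), size=min(100, len(fps)), replace=False)
        for i in take:
            skel = by_id[int(fps.source_tree[i])].skeleton
            d = np.linalg.norm(skel - fps.post_points[i], axis=1).min()
            assert d < 2.0
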