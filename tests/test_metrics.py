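"""Matched-region accounting and the four comparison criteria."""

import numpy as np
import pytest

from cytodetect.detection import Detection, DetectionSet, oracle_detect
from cytodetect.metrics import (MatchResult, combine_matches, compare_backends,
                                compute_metrics, match_detections)
from conftest import make_scene_from_masks


def brute_force_match(detections, scene, min_fraction=0.25):
    """Independent all-pairs enumeration of the permissive matching rule."""
    blue = [i for i in scene.instances if i.lineage == "blue"]
    n_background = 0
    per_nucleus = {i.id: [] for i in blue}
    for d_idx, det in enumerate(detections.detections):
        hit = False
        for inst in blue:
            inter = int(np.sum(det.mask & inst.mask))
            frac_ok = det.mask.sum() > 0 and inter / det.mask.sum() >= min_fraction
            rows, cols = np.nonzero(inst.mask)
            cr, cc = int(round(rows.mean())), int(round(cols.mean()))
            if frac_ok or det.mask[cr, cc]:
                per_nucleus[inst.id].append(d_idx)
                hit = True
        if not hit:
            n_background += 1
    return n_background, per_nucleus


def random_instance_problem(rng, shape=(64, 64)):
    """Random rectangular nuclei and detections on a small canvas."""
    def rect():
        r = rng.integers(0, shape[0] - 10)
        c = rng.integers(0, shape[1] - 10)
        h = rng.integers(4, 10)
        w = rng.integers(4, 10)
        m = np.zeros(shape, dtype=bool)
        m[r:r + h, c:c + w] = True
        return m

    n_nuc = rng.integers(1, 6)
    scene = make_scene_from_masks([rect() for _ in range(n_nuc)],
                                  ["blue"] * n_nuc, shape=shape)
    dets = [Detection(box=_bbox(m), mask=m, score=float(rng.random()))
            for m in (rect() for _ in range(rng.integers(0, 8)))]
    return scene, DetectionSet(detections=dets, source_id="rand",
                               backend="test")


def _bbox(mask):
    rows, cols = np.nonzero(mask)
    return int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1


def _mr(D, B, N, U, M, **kw):
    return MatchResult(n_detections=D, n_background_detections=B,
                       n_gt_nuclei=N, n_undetected_regions_total=U,
                       n_matched_regions_total=M, **kw)


class TestComputeMetrics:
    def test_reference_count_arithmetic(self):
        """The protocol's reference counts reproduce their ratios exactly."""
        swm = compute_metrics(_mr(320, 97, 36, 67, 223))
        assert swm.background_fraction == 0.3031
        assert swm.avg_undetected_per_nucleus == 1.8611
        assert swm.avg_regions_per_nucleus == 6.1944
        inst = compute_metrics(_mr(37, 1, 36, 0, 36), decimals=3)
        assert inst.background_fraction == 0.027
        assert inst.avg_undetected_per_nucleus == 0.0
        assert inst.avg_regions_per_nucleus == 1.0

    def test_zero_detection_convention(self):
        m = compute_metrics(_mr(0, 0, 5, 5, 0))
        assert m.background_fraction == 0.0

    def test_no_nuclei_errors(self):
        with pytest.raises(ValueError):
            compute_metrics(_mr(3, 3, 0, 0, 0))

    def test_rounding_is_half_up(self):
        m = compute_metrics(_mr(16, 1, 1, 0, 15))  # 1/16 = 0.0625
        assert m.background_fraction == 0.0625
        assert compute_metrics(_mr(16, 1, 1, 0, 15),
                               decimals=3).background_fraction == 0.063


class TestMatchDetections:
    def test_perfect_oracle_fixed_point(self, small_scene):
        match = match_detections(oracle_detect(small_scene.image), small_scene)
        m = compute_metrics(match)
        assert match.n_background_detections == 0
        assert m.avg_undetected_per_nucleus == 0.0
        assert m.avg_regions_per_nucleus == 1.0
        assert all(len(v) == 1 for v in match.per_nucleus_regions.values())

    def test_empty_detection_set(self, small_scene):
        empty = DetectionSet(detections=[], source_id="e", backend="test")
        match = match_detections(empty, small_scene)
        assert match.n_detections == 0
        assert match.n_background_detections == 0
        assert match.n_undetected_regions_total == len(
            small_scene.blue_instances())

    def test_stray_detection_is_background(self):
        masks = [np.zeros((128, 128), dtype=bool) for _ in range(3)]
        masks[0][10:20, 10:20] = True
        masks[1][40:50, 40:50] = True
        masks[2][80:90, 80:90] = True
        scene = make_scene_from_masks(masks, ["blue"] * 3, shape=(128, 128))
        stray = np.zeros((128, 128), dtype=bool)
        stray[100:110, 10:20] = True
        dets = [Detection(box=_bbox(m), mask=m, score=1.0)
                for m in masks + [stray]]
        dset = DetectionSet(detections=dets, source_id="toy", backend="test")
        match = match_detections(dset, scene)
        B_bf, per_bf = brute_force_match(dset, scene)
        assert match.n_background_detections == B_bf == 1
        assert match.per_nucleus_regions == per_bf

    def test_adding_stray_increments_B_and_D_only(self, small_scene):
        base = oracle_detect(small_scene.image)
        m0 = match_detections(base, small_scene)
        stray = np.zeros(small_scene.shape, dtype=bool)
        stray[0:6, 0:6] = True  # far corner, background by construction
        with_stray = DetectionSet(
            detections=base.detections + [Detection(box=(0, 0, 6, 6),
                                                    mask=stray, score=0.9)],
            source_id=base.source_id, backend="test")
        m1 = match_detections(with_stray, small_scene)
        assert m1.n_detections == m0.n_detections + 1
        assert m1.n_background_detections == m0.n_background_detections + 1
        assert m1.n_undetected_regions_total == m0.n_undetected_regions_total

    def test_conservation_and_bruteforce_equivalence_random(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            scene, dset = random_instance_problem(rng)
            match = match_detections(dset, scene)
            B_bf, per_bf = brute_force_match(dset, scene)
            assert match.n_background_detections == B_bf
            assert match.per_nucleus_regions == per_bf
            assert (match.n_background_detections
                    + match.n_matched_regions_total) == match.n_detections

    def test_coordinate_frame_mismatch_errors(self, small_scene):
        bad = Detection(box=(0, 0, 5, 5),
                        mask=np.zeros((10, 10), dtype=bool), score=1.0)
        dset = DetectionSet(detections=[bad], source_id="b", backend="test")
        with pytest.raises(ValueError, match="coordinate"):
            match_detections(dset, small_scene)

    def test_iou_criterion_is_stricter(self, small_scene):
        dset = oracle_detect(small_scene.image)
        perm = match_detections(dset, small_scene, "permissive")
        iou = match_detections(dset, small_scene, "iou")
        assert iou.n_background_detections >= perm.n_background_detections
        with pytest.raises(ValueError):
            match_detections(dset, small_scene, "nope")


class TestSwmMode:
    def test_window_accounting(self):
        """Expected regions are the positively-labelled windows; a missing
        window counts as one undetected region for its nucleus."""
        from cytodetect.detection import windows_to_detections
        from cytodetect.patch_cnn import ProbabilityMap

        masks = [np.zeros((96, 288), dtype=bool) for _ in range(2)]
        masks[0][40:60, 20:40] = True  # fully inside window (0, 0)
        masks[1][40:60, 120:140] = True  # fully inside window (0, 96)
        scene = make_scene_from_masks(masks, ["blue", "blue"],
                                      shape=(96, 288))
        # classifier fires on window (0, 0) and the empty window (0, 192),
        # misses (0, 96) entirely
        pmap = ProbabilityMap(probs={(0, 0): 0.8, (0, 96): 0.2,
                                     (0, 192): 0.7}, source_id="handmade")
        dset = windows_to_detections(pmap, scene.shape)
        assert len(dset) == 2
        match = match_detections(dset, scene)
        assert match.mode == "swm"
        assert match.n_background_detections == 1  # the empty window
        assert match.per_nucleus_undetected == {1: 0, 2: 1}
        assert match.n_undetected_regions_total == 1
        assert match.n_matched_regions_total == 1


class TestCompareBackends:
    def test_reference_counts_format(self):
        swm = _mr(320, 97, 36, 67, 223, image_ids=("a",))
        rcnn = _mr(37, 1, 36, 0, 36, image_ids=("a",))
        table = compare_backends(swm, rcnn)
        assert table.shape == (4, 2)
        col = table.iloc[:, 0]
        assert col.iloc[0] == "320"
        assert col.iloc[1] == "0.3031 (97/320)"
        assert col.iloc[2] == "1.8611 (67/36)"
        assert col.iloc[3] == "6.1944 (223/36)"
        right = table.iloc[:, 1]
        assert right.iloc[1] == "0.027 (1/37)"
        assert right.iloc[2] == "0 (0/36)"
        assert right.iloc[3] == "1 (36/36)"

    def test_identical_inputs_and_swap_symmetry(self):
        a = _mr(10, 2, 5, 1, 8, image_ids=("x",))
        b = _mr(6, 0, 5, 0, 6, image_ids=("x",))
        t1 = compare_backends(a, b)
        t2 = compare_backends(b, a)
        assert list(t1.iloc[:, 0]) == list(t2.iloc[:, 1])
        same = compare_backends(a, a)
        assert list(same.iloc[:, 0]) == list(same.iloc[:, 1])

    def test_mismatched_image_sets_error(self):
        a = _mr(1, 0, 1, 0, 1, image_ids=("x",))
        b = _mr(1, 0, 1, 0, 1, image_ids=("y",))
        with pytest.raises(ValueError):
            compare_backends(a, b)


def test_combine_matches_pools_counts():
    parts = [_mr(3, 1, 2, 1, 2, image_ids=("a",)),
             _mr(4, 0, 3, 0, 4, image_ids=("b",))]
    pooled = combine_matches(parts)
    assert pooled.n_detections == 7
    assert pooled.n_background_detections == 1
    assert pooled.n_gt_nuclei == 5
    assert pooled.image_ids == ("a", "b")
    with pytest.raises(ValueError):
        combine_matches([])
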