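"""Lesion-wise metric tests against brute-force and published-count oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctnodes import (LesionLabelMap, SizeThresholds, classify_size,
                     detection_metrics, dsc, evaluate_volume, extract_nodes,
                     hd95, label_components, match_detections, measure_sad)
from ctnodes.reference import ELIGIBLE_NODES, detection_counts

import oracles
from conftest import random_blob_mask

# published percentages for each detection-count row, in table order
PRINTED = {
    ("nih", 1.00, "no_augmentation"): (70.7, 83.8, 76.8),
    ("nih", 1.00, "augmentation"): (67.3, 84.6, 74.9),
    ("nih", 0.75, "no_augmentation"): (71.4, 83.5, 77.0),
    ("nih", 0.75, "augmentation"): (67.6, 84.5, 75.1),
    ("nih", 0.50, "no_augmentation"): (72.7, 82.6, 77.3),
    ("nih", 0.50, "augmentation"): (68.5, 84.3, 75.6),
    ("nih", 0.25, "no_augmentation"): (74.8, 79.1, 76.9),
    ("nih", 0.25, "augmentation"): (69.6, 83.1, 75.8),
    ("nih", 0.10, "no_augmentation"): (77.8, 70.4, 73.9),
    ("nih", 0.10, "augmentation"): (71.9, 79.0, 75.3),
    ("nih", 0.05, "no_augmentation"): (79.3, 60.0, 68.3),
    ("nih", 0.05, "augmentation"): (75.0, 73.8, 74.4),
    ("lnq", 1.00, "no_augmentation"): (54.4, 80.4, 64.9),
    ("lnq", 1.00, "augmentation"): (53.2, 81.6, 64.4),
}


class TestLabelComponents:
    def test_empty_mask_has_no_components(self):
        out = label_components(np.zeros((5, 5, 5), dtype=int))
        assert out.data.max() == 0

    def test_two_disjoint_cubes(self):
        m = np.zeros((10, 10, 10), dtype=int)
        m[1:3, 1:3, 1:3] = 1
        m[6:8, 6:8, 6:8] = 1
        assert label_components(m).data.max() == 2

    def test_vertex_touch_merges_under_26_connectivity(self):
        m = np.zeros((6, 6, 6), dtype=int)
        m[1:3, 1:3, 1:3] = 1
        m[3:5, 3:5, 3:5] = 1  # touches only at the (3,3,3) vertex
        assert label_components(m).data.max() == 1
        assert oracles.flood_fill_components(m > 0) == 1

    def test_component_count_matches_flood_fill_oracle(self, rng):
        for _ in range(10):
            m = rng.random((10, 10, 10)) < 0.15
            assert label_components(m.astype(int)).data.max() == \
                oracles.flood_fill_components(m)

    def test_label_order_is_first_voxel_order(self):
        m = np.zeros((6, 6, 6), dtype=int)
        m[4, 4, 4] = 7   # later in C order
        m[1, 1, 1] = 3   # earlier
        out = label_components(m)
        assert out.data[1, 1, 1] == 1 and out.data[4, 4, 4] == 2


class TestMeasureSad:
    def test_digital_sphere_diameter_recovered(self):
        zz, yy, xx = np.mgrid[-8:9, -8:9, -8:9]
        sphere = (zz ** 2 + yy ** 2 + xx ** 2) <= 6 ** 2
        assert measure_sad(sphere, (1, 1, 1)) == pytest.approx(12.0, abs=2.0)

    def test_single_voxel_convention(self):
        m = np.zeros((3, 3, 3), dtype=bool)
        m[1, 1, 1] = True
        assert measure_sad(m, (5.0, 0.8, 0.8)) == pytest.approx(0.8)

    def test_sad_is_axial_in_plane_not_thickness(self):
        # a 3-slice 30x30 slab: the inscribed circle lives in the axial face
        m = np.zeros((10, 40, 40), dtype=bool)
        m[4:7, 5:35, 5:35] = True
        assert measure_sad(m, (1, 1, 1)) == pytest.approx(30.0, abs=1.0)

    def test_empty_component_raises(self):
        with pytest.raises(ValueError):
            measure_sad(np.zeros((3, 3, 3), dtype=bool), (1, 1, 1))


class TestClassifySize:
    @pytest.mark.parametrize("sad,expected", [
        (8.0, "large"), (3.0, "small"), (2.99, "ignored"), (0.0, "ignored"),
        (7.99, "small"), (25.0, "large"),
    ])
    def test_boundaries_closed_on_left(self, sad, expected):
        assert classify_size(sad) == expected

    def test_negative_sad_rejected(self):
        with pytest.raises(ValueError):
            classify_size(-1.0)


class TestDetectionMetrics:
    def test_published_counts_reproduce_published_percentages(self):
        """Every published precision/sensitivity/F1 follows from its TP/FP/FN
        to within 0.1 percentage points (one known rounding discrepancy:
        the full-dose no-augmentation sensitivity prints 83.8 where the
        counts give 83.89)."""
        for row in detection_counts().itertuples():
            m = detection_metrics(row.tp, row.fp, row.fn)
            printed = PRINTED[(row.dataset, row.dose, row.model)]
            for value, target in zip((m.precision, m.sensitivity, m.f1), printed):
                assert value == pytest.approx(target, abs=0.1)

    def test_count_conservation_against_dataset_totals(self):
        for row in detection_counts().itertuples():
            assert row.tp + row.fn == ELIGIBLE_NODES[row.dataset]

    def test_headline_full_dose_row(self):
        m = detection_metrics(4092, 1692, 786)
        assert round(m.precision, 1) == 70.7
        assert round(m.f1, 1) == 76.8
        assert round(m.sensitivity, 1) == 83.9  # prints 83.8 in the source

    def test_zero_counts_are_undefined_not_zero(self):
        m = detection_metrics(0, 0, 0)
        assert m.precision is None and m.sensitivity is None and m.f1 is None

    def test_f1_is_harmonic_mean(self):
        m = detection_metrics(30, 10, 20)
        p, s = m.precision, m.sensitivity
        assert m.f1 == pytest.approx(2 * p * s / (p + s))


class TestDsc:
    def test_identity_and_disjoint(self, rng):
        a = random_blob_mask(rng)
        assert dsc(a, a) == 1.0
        b = np.zeros_like(a)
        b[0, 0, 0] = True
        assert dsc(a & ~a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros((4, 4, 4), dtype=bool)
        b = np.zeros_like(a)
        a[0, 0, :2], a[1, 0, :2], a[2, 0, :2], a[3, 0, :2] = True, True, True, True
        b[:2, 0, :2] = True
        b[0, 1, :2] = True
        b[1, 1, :2] = True
        assert a.sum() == b.sum() == 8
        assert dsc(a, b) == pytest.approx(2 * (a & b).sum() / 16)

    def test_both_empty_defined_as_one(self):
        z = np.zeros((3, 3, 3), dtype=bool)
        assert dsc(z, z) == 1.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_matches_bruteforce_and_symmetric(self, seed):
        r = np.random.default_rng(seed)
        a, b = random_blob_mask(r), random_blob_mask(r)
        assert dsc(a, b) == pytest.approx(oracles.dsc_bruteforce(a, b))
        assert dsc(a, b) == dsc(b, a)


class TestHd95:
    def test_identical_masks_distance_zero(self, rng):
        a = random_blob_mask(rng)
        assert hd95(a, a, (1, 1, 1)) == 0.0

    def test_unit_cubes_offset_five(self):
        a = np.zeros((3, 12, 3), dtype=bool)
        b = np.zeros_like(a)
        a[1, 2, 1] = True
        b[1, 7, 1] = True
        assert hd95(a, b, (1, 1, 1)) == pytest.approx(5.0)

    def test_symmetric_in_arguments(self, rng):
        a, b = random_blob_mask(rng), random_blob_mask(rng)
        assert hd95(a, b, (1, 2, 0.7)) == hd95(b, a, (1, 2, 0.7))

    def test_empty_mask_raises(self):
        a = np.zeros((3, 3, 3), dtype=bool)
        b = a.copy()
        b[1, 1, 1] = True
        with pytest.raises(ValueError):
            hd95(a, b, (1, 1, 1))

    @pytest.mark.parametrize("spacing", [(1, 1, 1), (2.0, 0.7, 0.7)])
    def test_matches_bruteforce_oracle(self, spacing, rng):
        for _ in range(10):
            a, b = random_blob_mask(rng), random_blob_mask(rng)
            assert hd95(a, b, spacing) == pytest.approx(
                oracles.hd95_bruteforce(a, b, spacing), abs=1e-9)


def _labels(arr, spacing=(1.0, 1.0, 1.0)):
    return LesionLabelMap(np.asarray(arr, dtype=np.int32), spacing)


def _ball_at(shape, center, radius):
    zz, yy, xx = np.ogrid[:shape[0], :shape[1], :shape[2]]
    return ((zz - center[0]) ** 2 + (yy - center[1]) ** 2 +
            (xx - center[2]) ** 2) <= radius ** 2


class TestMatchDetections:
    def make_ref(self):
        data = np.zeros((24, 48, 48), dtype=np.int32)
        data[_ball_at(data.shape, (8, 12, 12), 5)] = 1    # large (SAD ~10)
        data[_ball_at(data.shape, (8, 30, 30), 2.5)] = 2  # small (SAD ~5)
        data[16, 40, 40] = 3                              # ignored (<3 mm)
        return _labels(data)

    def test_identity_prediction(self):
        ref = self.make_ref()
        res = match_detections(ref, ref)
        assert res.counts["all"].tp == 2
        assert res.counts["all"].fp == 0
        assert res.counts["all"].fn == 0

    def test_empty_prediction_all_missed(self):
        ref = self.make_ref()
        res = match_detections(ref, _labels(np.zeros(ref.shape)))
        assert res.counts["all"].tp == 0
        assert res.counts["all"].fn == 2

    def test_fp_touching_only_ignored_node_excluded(self):
        ref = self.make_ref()
        pred = np.zeros(ref.shape, dtype=np.int32)
        pred[16, 40, 40] = 1   # on the ignored node only
        pred[16, 40, 41] = 1
        pred[2, 2, 2] = 2      # genuine false positive
        res = match_detections(ref, _labels(pred))
        assert res.counts["all"].fp == 1
        assert len(res.excluded_fp_labels) == 1  # the ignored-node component

    def test_conservation_tp_plus_fn(self, rng):
        ref = self.make_ref()
        for _ in range(5):
            pred = (rng.random(ref.shape) < 0.02).astype(np.int32)
            res = match_detections(ref, _labels(pred))
            assert res.counts["all"].tp + res.counts["all"].fn == res.eligible

    def test_prediction_label_permutation_invariant(self):
        ref = self.make_ref()
        pred = ref.data.copy()
        permuted = np.zeros_like(pred)
        for old, new in [(1, 3), (2, 1), (3, 2)]:
            permuted[pred == old] = new
        a = match_detections(ref, _labels(pred))
        b = match_detections(ref, _labels(permuted))
        assert a.counts["all"].as_dict() == b.counts["all"].as_dict()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            match_detections(_labels(np.zeros((4, 4, 4))),
                             _labels(np.zeros((4, 4, 5))))

    def test_size_strata_sum_to_overall(self):
        ref = self.make_ref()
        res = match_detections(ref, ref)
        assert res.counts["small"].tp + res.counts["large"].tp == \
            res.counts["all"].tp


class TestEvaluateVolume:
    def test_perfect_prediction(self):
        ref = TestMatchDetections().make_ref()
        ev = evaluate_volume(ref, ref)
        assert ev.volume_dsc == 1.0
        assert ev.volume_hd95 == 0.0
        assert (ev.per_node.dsc == 1.0).all()
        assert (ev.per_node.hd95 == 0.0).all()

    def test_erosion_hurts_small_nodes_more(self):
        from scipy import ndimage
        data = np.zeros((24, 64, 64), dtype=np.int32)
        data[_ball_at(data.shape, (10, 16, 16), 8)] = 1   # SAD ~16
        data[_ball_at(data.shape, (10, 45, 45), 3.5)] = 2  # SAD ~7
        ref = _labels(data)
        eroded = np.zeros_like(data)
        for lab in (1, 2):
            m = ndimage.binary_erosion(data == lab)
            eroded[m] = lab
        ev = evaluate_volume(ref, _labels(eroded))
        by_node = ev.per_node.set_index("node_id")
        assert (by_node.dsc < 1.0).all()
        assert by_node.loc[2, "dsc"] < by_node.loc[1, "dsc"]

    def test_unmatched_node_scores_zero_dsc_nan_hd(self):
        ref = TestMatchDetections().make_ref()
        pred = np.zeros(ref.shape, dtype=np.int32)
        pred[ref.data == 1] = 1  # only the large node predicted
        ev = evaluate_volume(ref, _labels(pred))
        small = ev.per_node[ev.per_node.size_class == "small"].iloc[0]
        assert small.dsc == 0.0 and np.isnan(small.hd95)
        assert ev.n_undefined_hd >= 1

    def test_aggregation_identity(self):
        ref = TestMatchDetections().make_ref()
        ev = evaluate_volume(ref, ref)
        assert ev.per_node.dsc.mean() == pytest.approx(
            np.mean(ev.per_node.dsc.to_numpy()))


class TestExtractNodes:
    def test_records_consistent_with_thresholds(self, small_phantom):
        _, mask, _ = small_phantom
        for rec in extract_nodes(mask):
            assert rec.voxels > 0
            assert rec.size_class == classify_size(rec.sad_mm)

    def test_custom_thresholds_respected(self, small_phantom):
        _, mask, _ = small_phantom
        coarse = SizeThresholds(small=5.0, large=15.0)
        for rec in extract_nodes(mask, coarse):
            assert rec.size_class == classify_size(rec.sad_mm, coarse)
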