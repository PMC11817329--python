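"""Weighted Boxes Fusion: hand-computed cases, invariants, and a brute-force
oracle that re-derives the greedy cluster-and-average procedure from its
definition."""

import numpy as np
import pytest

from dentfuse import (
    Box,
    Detection,
    FusionParams,
    ImageRecord,
    fuse_confidence,
    fuse_coordinates,
    fuse_dataset,
    iou,
    weighted_boxes_fusion,
)

from conftest import random_box


def det(cx, cy, w, h, conf, model="m", label=0, image="img"):
    return Detection(Box(cx, cy, w, h), conf, label=label, model_id=model, image_id=image)


def two_overlapping():
    # pairwise IoU is exactly 1/3
    return (
        det(0.40, 0.40, 0.20, 0.20, 0.9, model="a"),
        det(0.50, 0.40, 0.20, 0.20, 0.3, model="b"),
    )


class TestFuseConfidence:
    def test_plain_average(self):
        a, b = two_overlapping()
        assert fuse_confidence([a, b]) == pytest.approx(0.6)

    def test_single_member_and_saturation(self):
        a, _ = two_overlapping()
        assert fuse_confidence([a]) == a.confidence
        ones = [det(0.5, 0.5, 0.1, 0.1, 1.0) for _ in range(3)]
        assert fuse_confidence(ones) == 1.0

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            fuse_confidence([])


class TestFuseCoordinates:
    def test_confidence_weighted_center(self):
        a, b = two_overlapping()
        fused = fuse_coordinates([a, b])
        assert fused.cx == pytest.approx((0.9 * 0.40 + 0.3 * 0.50) / 1.2)  # 0.425
        assert (fused.cy, fused.w, fused.h) == pytest.approx((0.40, 0.20, 0.20))

    def test_identical_boxes_any_confidence(self):
        members = [det(0.3, 0.3, 0.1, 0.1, c) for c in (0.2, 0.9, 0.55)]
        fused = fuse_coordinates(members)
        assert (fused.cx, fused.cy, fused.w, fused.h) == pytest.approx((0.3, 0.3, 0.1, 0.1))

    def test_single_member_is_identity(self):
        a, _ = two_overlapping()
        fused = fuse_coordinates([a])
        assert (fused.cx, fused.cy, fused.w, fused.h) == (0.40, 0.40, 0.20, 0.20)


class TestWeightedBoxesFusion:
    def params(self, iou_thr, **kw):
        return FusionParams(
            iou_thr=iou_thr, model_weights={"a": 1.0, "b": 1.0}, **kw
        )

    def test_two_boxes_merge_below_threshold(self):
        a, b = two_overlapping()
        (fused,) = weighted_boxes_fusion({"a": [a], "b": [b]}, self.params(0.30))
        assert fused.box.cx == pytest.approx(0.425)
        assert fused.confidence == pytest.approx(0.6)

    def test_two_boxes_stay_separate_above_threshold(self):
        a, b = two_overlapping()
        out = weighted_boxes_fusion({"a": [a], "b": [b]}, self.params(0.40))
        assert len(out) == 2
        assert {d.box.cx for d in out} == {0.40, 0.50}

    def test_single_detection_passes_through(self):
        a, _ = two_overlapping()
        (out,) = weighted_boxes_fusion(
            {"a": [a]}, FusionParams(iou_thr=0.5, model_weights={"a": 1.0})
        )
        assert out.box == a.box and out.confidence == pytest.approx(a.confidence)

    def test_skip_threshold_filters_raw_confidence(self):
        a, b = two_overlapping()
        out = weighted_boxes_fusion(
            {"a": [a], "b": [b]}, self.params(0.30, skip_box_thr=0.5)
        )
        assert len(out) == 1 and out[0].box.cx == pytest.approx(0.40)

    def test_unknown_model_rejected(self):
        a, _ = two_overlapping()
        with pytest.raises(KeyError):
            weighted_boxes_fusion(
                {"a": [a]}, FusionParams(iou_thr=0.5, model_weights={"b": 1.0})
            )

    def test_model_weight_pulls_fused_box(self):
        a, b = two_overlapping()
        params = FusionParams(iou_thr=0.30, model_weights={"a": 4.0, "b": 1.0})
        (fused,) = weighted_boxes_fusion({"a": [a], "b": [b]}, params)
        # weight scale: a -> 4/2.5 = 1.6, b -> 0.4; scaled confs 1.44, 0.12
        assert fused.box.cx == pytest.approx((1.44 * 0.40 + 0.12 * 0.50) / 1.56)

    def test_permutation_robust_for_distinct_confidences(self, rng):
        dets = [
            det(*_rand_geom(rng), conf, model=m)
            for m, confs in (("a", (0.91, 0.52, 0.33)), ("b", (0.77, 0.18)))
            for conf in confs
        ]
        by_model = {"a": dets[:3], "b": dets[3:]}
        reversed_order = {"b": dets[3:][::-1], "a": dets[:3][::-1]}
        p = self.params(0.4)
        out1 = weighted_boxes_fusion(by_model, p)
        out2 = weighted_boxes_fusion(reversed_order, p)
        assert [(d.box, d.confidence) for d in out1] == [
            (d.box, d.confidence) for d in out2
        ]

    def test_convexity_and_count_monotonicity(self, rng):
        for _ in range(30):
            by_model = _random_instance(rng)
            counts = []
            for thr in (0.2, 0.4, 0.6, 0.8):
                out = weighted_boxes_fusion(
                    by_model, FusionParams(iou_thr=thr, model_weights={m: 1.0 for m in by_model})
                )
                counts.append(len(out))
            total = sum(len(v) for v in by_model.values())
            assert all(c <= total for c in counts)
            assert counts == sorted(counts)  # raising iou_thr never merges more

    def test_idempotent_on_own_output(self, rng):
        by_model = _random_instance(rng)
        params = FusionParams(iou_thr=0.5, model_weights={m: 1.0 for m in by_model})
        fused = weighted_boxes_fusion(by_model, params)
        again = weighted_boxes_fusion(
            {"fused": fused}, FusionParams(iou_thr=0.5, model_weights={"fused": 1.0})
        )
        assert len(again) == len(fused)
        for a, b in zip(fused, again):
            assert a.confidence == pytest.approx(b.confidence, abs=1e-12)
            assert a.box.cx == pytest.approx(b.box.cx, abs=1e-12)


def _rand_geom(rng):
    b = random_box(rng, 0.05, 0.25)
    return b.cx, b.cy, b.w, b.h


def _random_instance(rng, max_models=3, max_boxes=10):
    n_models = int(rng.integers(1, max_models + 1))
    by_model = {}
    total = int(rng.integers(1, max_boxes + 1))
    models = [f"m{k}" for k in range(n_models)]
    for m in models:
        by_model[m] = []
    for _ in range(total):
        m = models[int(rng.integers(n_models))]
        by_model[m].append(
            det(*_rand_geom(rng), float(rng.uniform(0.05, 1.0)), model=m,
                label=int(rng.integers(2)))
        )
    return {m: v for m, v in by_model.items() if v}


def brute_force_wbf(by_model, params):
    """Independent re-derivation: greedy clustering against the running
    confidence-weighted average box, computed from scratch each step."""
    scale = {}
    if params.model_weights:
        mean_w = sum(params.model_weights.values()) / len(params.model_weights)
        scale = {m: w / mean_w for m, w in params.model_weights.items()}
    items = []
    for m in sorted(by_model):
        for i, d in enumerate(by_model[m]):
            if d.confidence >= params.skip_box_thr:
                items.append((d, d.confidence * scale.get(m, 1.0)))
    results = []
    for label in sorted({d.label for d, _ in items}):
        group = [(d, s) for d, s in items if d.label == label]
        group = sorted(
            enumerate(group), key=lambda t: (-t[1][1], t[1][0].model_id, t[0])
        )
        clusters = []  # list of lists of (det, scaled)

        def fused_of(cluster):
            ssum = sum(s for _, s in cluster)
            coords = [
                sum(s * getattr(d.box, f) for d, s in cluster) / ssum
                for f in ("cx", "cy", "w", "h")
            ]
            conf = min(sum(s for _, s in cluster) / len(cluster), 1.0)
            return Box(*coords), conf

        for _, (d, s) in group:
            best = None
            best_iou = 0.0
            for c in clusters:
                fb, _ = fused_of(c)
                ov = iou(d.box, fb)
                if ov > params.iou_thr and ov > best_iou:
                    best, best_iou = c, ov
            if best is None:
                clusters.append([(d, s)])
            else:
                best.append((d, s))
        for c in clusters:
            fb, conf = fused_of(c)
            results.append((label, fb, conf))
    results.sort(key=lambda t: -t[2])
    return results


class TestOracleEquivalence:
    def test_matches_brute_force_on_200_random_instances(self, rng):
        for _ in range(200):
            by_model = _random_instance(rng)
            thr = float(rng.uniform(0.2, 0.8))
            weights = {m: float(rng.uniform(1, 10)) for m in by_model}
            params = FusionParams(
                iou_thr=thr,
                skip_box_thr=float(rng.uniform(0.0, 0.1)),
                model_weights=weights,
            )
            ours = weighted_boxes_fusion(by_model, params)
            ref = brute_force_wbf(by_model, params)
            assert len(ours) == len(ref)
            for d, (label, fb, conf) in zip(ours, ref):
                assert d.label == label
                assert d.confidence == pytest.approx(conf, abs=1e-9)
                for f in ("cx", "cy", "w", "h"):
                    assert getattr(d.box, f) == pytest.approx(getattr(fb, f), abs=1e-9)


class TestFuseDataset:
    def test_empty_and_single_model_identity(self, rng):
        records = [ImageRecord(image_id="a"), ImageRecord(image_id="b")]
        params = FusionParams(iou_thr=0.5, model_weights={"m": 1.0})
        out = fuse_dataset(records, params)
        assert out == {"a": [], "b": []}

        d = det(0.4, 0.4, 0.1, 0.1, 0.8, model="m", image="c")
        records = [ImageRecord(image_id="c", predictions={"m": [d]})]
        out = fuse_dataset(records, params)
        assert len(out["c"]) == 1
        got = out["c"][0]
        for f in ("cx", "cy", "w", "h"):
            assert getattr(got.box, f) == pytest.approx(getattr(d.box, f), abs=1e-12)
        assert got.confidence == pytest.approx(d.confidence, abs=1e-12)

    def test_fused_count_never_exceeds_input(self, rng, small_benchmark):
        records, _ = small_benchmark
        params = FusionParams(
            iou_thr=0.5, model_weights={"recall_heavy": 1.0, "precision_heavy": 1.0}
        )
        fused = fuse_dataset(records, params)
        for rec in records:
            total = sum(len(v) for v in rec.predictions.values())
            assert len(fused[rec.image_id]) <= total
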