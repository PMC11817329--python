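"""Weighted Boxes Fusion (WBF) of detections from multiple detectors.

Instead of suppressing duplicate boxes the way NMS does, WBF merges every
cluster of mutually overlapping boxes into a single box whose coordinates are
the confidence-weighted means of the members' coordinates and whose score is
the mean of the members' scores.  Per-model weights express trust in each
detector: every detection's confidence is scaled by ``weight / mean(weights)``
before clustering, so a trusted model pulls both the greedy clustering order
and the coordinate averages toward its boxes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .geometry import Box, Detection, iou
from .io_formats import ImageRecord

__all__ = [
    "FusionParams",
    "FusedCluster",
    "fuse_confidence",
    "fuse_coordinates",
    "weighted_boxes_fusion",
    "fuse_dataset",
]

FUSED_MODEL_ID = "fused"


@dataclass(frozen=True)
class FusionParams:
    """The WBF hyperparameters.

    Parameters
    ----------
    iou_thr
        Minimum IoU between a detection and a cluster's current fused box for
        the detection to join the cluster.  The optimizer searches
        ``[0.1, 0.9]``; any value in ``(0, 1)`` is accepted when
        user-supplied.
    skip_box_thr
        Per-detector quality floor: detections whose *raw* confidence falls
        below it never enter fusion.  Search range ``[0.001, 0.1]``.
    model_weights
        Map ``model_id -> weight`` (search range ``[1, 10]`` per model).
    conf_mode
        ``"mean"`` — fused score is the plain average of the (weight-scaled)
        member scores; ``"weighted_mean"`` — average weighted by the scores
        themselves.
    rescale_by_model_count
        When set, the fused score is additionally multiplied by
        ``min(T, M) / M`` for a cluster of ``T`` members from ``M`` models,
        penalizing boxes that only one detector saw.  Off by default.
    """

    iou_thr: float = 0.55
    skip_box_thr: float = 0.0
    model_weights: Mapping[str, float] = field(default_factory=dict)
    conf_mode: str = "mean"
    rescale_by_model_count: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.iou_thr < 1.0):
            raise ValueError(f"iou_thr {self.iou_thr} outside (0, 1)")
        if self.skip_box_thr < 0.0:
            raise ValueError("skip_box_thr must be >= 0")
        if self.conf_mode not in ("mean", "weighted_mean"):
            raise ValueError(f"unknown conf_mode {self.conf_mode!r}")
        if any(w <= 0 for w in self.model_weights.values()):
            raise ValueError("all model weights must be > 0")

    def weight_scale(self) -> dict[str, float]:
        """Per-model confidence multipliers ``w_m / mean(w)``."""
        if not self.model_weights:
            return {}
        mean_w = sum(self.model_weights.values()) / len(self.model_weights)
        return {m: w / mean_w for m, w in self.model_weights.items()}


@dataclass
class FusedCluster:
    """One greedy cluster: its members and their fused representative."""

    members: list[tuple[Detection, float]]  # (detection, scaled confidence)
    fused_box: Box = None  # type: ignore[assignment]
    fused_confidence: float = 0.0

    def refresh(self, params: FusionParams) -> None:
        scaled = [s for _, s in self.members]
        self.fused_box = _weighted_mean_box([d.box for d, _ in self.members], scaled)
        self.fused_confidence = _mean_confidence(scaled, params.conf_mode)


def _mean_confidence(scaled: Sequence[float], conf_mode: str) -> float:
    if not scaled:
        raise ValueError("empty cluster")
    if conf_mode == "weighted_mean":
        total = sum(scaled)
        val = sum(s * s for s in scaled) / total
    else:
        val = sum(scaled) / len(scaled)
    return min(max(val, 0.0), 1.0)


def _weighted_mean_box(boxes: Sequence[Box], weights: Sequence[float]) -> Box:
    total = sum(weights)
    if total <= 0.0:
        raise ValueError("total confidence is zero; cannot average coordinates")
    return Box(
        sum(w * b.cx for b, w in zip(boxes, weights)) / total,
        sum(w * b.cy for b, w in zip(boxes, weights)) / total,
        sum(w * b.w for b, w in zip(boxes, weights)) / total,
        sum(w * b.h for b, w in zip(boxes, weights)) / total,
    )


def fuse_confidence(members: Sequence[Detection], conf_mode: str = "mean") -> float:
    """Fused score of a cluster: the (clipped) mean of member confidences."""
    if not members:
        raise ValueError("empty cluster")
    return _mean_confidence([d.confidence for d in members], conf_mode)


def fuse_coordinates(members: Sequence[Detection]) -> Box:
    """Fused box of a cluster: each coordinate is the confidence-weighted mean
    of the members' coordinates, ``Σ Cᵢ·vᵢ / Σ Cᵢ``."""
    if not members:
        raise ValueError("empty cluster")
    return _weighted_mean_box(
        [d.box for d in members], [d.confidence for d in members]
    )


def weighted_boxes_fusion(
    per_model_detections: Mapping[str, Sequence[Detection]],
    params: FusionParams,
) -> list[Detection]:
    """Fuse one image's detections from several models.

    Algorithm: drop detections below ``skip_box_thr`` (raw confidence); scale
    the rest by their model weight over the mean weight; per class, walk the
    detections in descending scaled confidence, joining each to the existing
    cluster whose current fused box overlaps it with IoU above ``iou_thr``
    (highest IoU wins, earlier cluster on ties) or opening a new cluster;
    refresh the cluster's fused box and score after every join.  Returns the
    fused detections in descending confidence; never more outputs than inputs.
    """
    scale = params.weight_scale()
    for model_id in per_model_detections:
        if scale and model_id not in scale:
            raise KeyError(f"model {model_id!r} has no weight in FusionParams")

    image_id = ""
    pool: list[tuple[Detection, float, int]] = []  # (det, scaled conf, input idx)
    idx = 0
    for model_id in sorted(per_model_detections):
        for det in per_model_detections[model_id]:
            if det.image_id:
                image_id = image_id or det.image_id
                if det.image_id != image_id:
                    raise ValueError(
                        "weighted_boxes_fusion fuses one image at a time; got "
                        f"{det.image_id!r} and {image_id!r}"
                    )
            if det.confidence < params.skip_box_thr:
                continue
            pool.append((det, det.confidence * scale.get(model_id, 1.0), idx))
            idx += 1

    n_models = max(len(per_model_detections), 1)
    fused: list[Detection] = []
    for label in sorted({d.label for d, _, _ in pool}):
        group = [(d, s, i) for d, s, i in pool if d.label == label]
        # stable order: scaled confidence desc, then model_id, then input order
        group.sort(key=lambda t: (-t[1], t[0].model_id, t[2]))
        clusters: list[FusedCluster] = []
        for det, scaled, _ in group:
            best_iou, best_cluster = 0.0, None
            for cluster in clusters:
                overlap = iou(det.box, cluster.fused_box)
                if overlap > params.iou_thr and overlap > best_iou:
                    best_iou, best_cluster = overlap, cluster
            if best_cluster is None:
                best_cluster = FusedCluster(members=[])
                clusters.append(best_cluster)
            best_cluster.members.append((det, scaled))
            best_cluster.refresh(params)
        for cluster in clusters:
            conf = cluster.fused_confidence
            if params.rescale_by_model_count:
                conf *= min(len(cluster.members), n_models) / n_models
            fused.append(
                Detection(
                    box=cluster.fused_box,
                    confidence=min(max(conf, 0.0), 1.0),
                    label=label,
                    model_id=FUSED_MODEL_ID,
                    image_id=image_id,
                )
            )
    fused.sort(key=lambda d: -d.confidence)
    return fused


def fuse_dataset(
    records: Iterable[ImageRecord],
    params: FusionParams,
) -> dict[str, list[Detection]]:
    """Apply :func:`weighted_boxes_fusion` image by image.

    Images missing some model's predictions are fused from the models present;
    weights for absent models simply do not contribute.
    """
    out: dict[str, list[Detection]] = {}
    for rec in records:
        present = {m: v for m, v in rec.predictions.items() if v}
        out[rec.image_id] = weighted_boxes_fusion(present, params) if present else []
    return out
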