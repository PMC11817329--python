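"""Fuse two detectors' boxes on one image with Weighted Boxes Fusion.

Two detectors report almost the same tooth, slightly offset and with very
different confidence.  WBF merges them into one box pulled toward the more
confident detection; its score is the average of the two.
"""

from dentfuse import Box, Detection, FusionParams, iou, weighted_boxes_fusion

a = Detection(Box(0.40, 0.40, 0.20, 0.20), confidence=0.9, model_id="yolo", image_id="img0")
b = Detection(Box(0.50, 0.40, 0.20, 0.20), confidence=0.3, model_id="detr", image_id="img0")
print(f"overlap between the two detections: IoU = {iou(a.box, b.box):.4f}")

params = FusionParams(iou_thr=0.30, model_weights={"yolo": 1.0, "detr": 1.0})
(fused,) = weighted_boxes_fusion({"yolo": [a], "detr": [b]}, params)
print(f"fused center x = {fused.box.cx:.4f}   (confidence-weighted mean of 0.40 and 0.50)")
print(f"fused score    = {fused.confidence:.4f} (plain mean of 0.9 and 0.3)")

# raise the clustering threshold above the pairwise IoU and the boxes no
# longer merge: each survives on its own
params = FusionParams(iou_thr=0.40, model_weights={"yolo": 1.0, "detr": 1.0})
out = weighted_boxes_fusion({"yolo": [a], "detr": [b]}, params)
print(f"with iou_thr = 0.40 the two boxes stay separate: {len(out)} outputs")
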