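# Reference fusion profile: hyperparameters reported for a tuned
# YOLOv8L + RT-DETR-L ensemble on panoramic radiographs.  An example
# configuration for `dentfuse fuse --config`, not a package default —
# optimal values are dataset- and detector-specific; re-run
# `dentfuse optimize` on your own validation split.
iou_thr: 0.3466
skip_box_thr: 0.0340
model_weights:
  yolov8l: 4.2111
  rtdetr_l: 2.9897
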