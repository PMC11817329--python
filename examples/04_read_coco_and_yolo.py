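"""Read detections from COCO-results JSON and YOLO label files.

Shows the two supported input formats converging on the same normalized
center-form boxes: a COCO pixel bbox [x, y, w, h] with a size registry, and
a YOLO prediction line with normalized coordinates plus confidence.
"""

import json
import tempfile
from pathlib import Path

from dentfuse import read_coco_detections, read_yolo_labels

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)

    # COCO detection results: pixel top-left bbox on a 200x200 image
    coco = tmp / "detections.json"
    coco.write_text(json.dumps([
        {"image_id": "scan_01", "category_id": 0, "bbox": [0, 0, 100, 100], "score": 0.87},
    ]))
    (det_coco,) = read_coco_detections(coco, image_sizes={"scan_01": (200, 200)})
    print("COCO  bbox [0,0,100,100] @ 200x200 ->",
          f"center ({det_coco.box.cx}, {det_coco.box.cy}), size "
          f"({det_coco.box.w}, {det_coco.box.h}), score {det_coco.confidence}")

    # the same box in YOLO prediction format (already normalized)
    yolo = tmp / "scan_01.txt"
    yolo.write_text("0 0.25 0.25 0.5 0.5 0.870000\n")
    (det_yolo,) = read_yolo_labels(yolo, has_confidence=True)
    print("YOLO  line '0 0.25 0.25 0.5 0.5 0.87'   ->",
          f"center ({det_yolo.box.cx}, {det_yolo.box.cy}), size "
          f"({det_yolo.box.w}, {det_yolo.box.h}), score {det_yolo.confidence}")

    same = all(
        getattr(det_coco.box, f) == getattr(det_yolo.box, f)
        for f in ("cx", "cy", "w", "h")
    )
    print(f"both readers produce the same normalized box: {same}")
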