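"""Readers/writers for detection file formats and the dataset split.

Supported formats:

* YOLO label files — one box per line, ``class cx cy w h`` with normalized
  center coordinates, plus a trailing confidence column for predictions
  (the darknet/ultralytics dialect, 0-based class indices).
* COCO detection-results JSON — ``[{image_id, category_id, bbox, score}]``
  with pixel top-left ``[x, y, w, h]`` boxes, converted to normalized center
  form via a caller-supplied image-size registry.
* Split manifests — three plain-text id lists (``train.txt``, ``val.txt``,
  ``test.txt``) in one directory.

Mixed image resolutions are handled purely through normalized coordinates;
pixel data are never read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .geometry import Box, Detection, GroundTruthBox

__all__ = [
    "ImageRecord",
    "DatasetSplit",
    "FormatError",
    "read_yolo_labels",
    "write_yolo_labels",
    "read_coco_detections",
    "split_dataset",
    "write_split_manifest",
    "read_split_manifest",
    "read_benchmark",
]

_COORD_TOL = 1e-6  # slack accepted on [0,1] bounds before a line is rejected


class FormatError(ValueError):
    """A malformed annotation/prediction file, reported with its line number."""


@dataclass
class ImageRecord:
    """All annotations attached to one image: ground truth plus per-model
    predictions."""

    image_id: str
    width: int = 0
    height: int = 0
    ground_truth: list[GroundTruthBox] = field(default_factory=list)
    predictions: dict[str, list[Detection]] = field(default_factory=dict)


@dataclass(frozen=True)
class DatasetSplit:
    """A disjoint train/validation/test partition of image ids."""

    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    fractions: tuple[float, float, float]

    def partition_of(self, image_id: str) -> str:
        for name, ids in (
            ("train", self.train_ids),
            ("val", self.val_ids),
            ("test", self.test_ids),
        ):
            if image_id in ids:
                return name
        raise KeyError(image_id)


def _parse_float(token: str, path: Path, lineno: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise FormatError(f"{path}:{lineno}: non-numeric field {token!r}") from None


def read_yolo_labels(
    path: str | Path,
    *,
    has_confidence: bool = False,
    image_id: str = "",
    model_id: str = "",
) -> list[GroundTruthBox] | list[Detection]:
    """Read a YOLO-format label (or prediction) file.

    Each non-empty line is ``class cx cy w h`` followed by a confidence when
    ``has_confidence`` is set.  Coordinates slightly outside ``[0, 1]``
    (beyond 1e-6) raise :class:`FormatError` naming the line; boxes whose
    extent overflows the frame are clipped.
    """
    path = Path(path)
    image_id = image_id or path.stem
    n_fields = 6 if has_confidence else 5
    out: list = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != n_fields:
                raise FormatError(
                    f"{path}:{lineno}: expected {n_fields} fields, got {len(parts)}"
                )
            label = int(_parse_float(parts[0], path, lineno))
            vals = [_parse_float(p, path, lineno) for p in parts[1:5]]
            for v in vals:
                if v < -_COORD_TOL or v > 1.0 + _COORD_TOL:
                    raise FormatError(
                        f"{path}:{lineno}: coordinate {v} outside [0, 1]"
                    )
            cx, cy, w, h = (min(max(v, 0.0), 1.0) for v in vals)
            box = Box(cx, cy, max(w, 1e-9), max(h, 1e-9)).clipped()
            if has_confidence:
                conf = _parse_float(parts[5], path, lineno)
                if conf < -_COORD_TOL or conf > 1.0 + _COORD_TOL:
                    raise FormatError(
                        f"{path}:{lineno}: confidence {conf} outside [0, 1]"
                    )
                out.append(
                    Detection(
                        box=box,
                        confidence=min(max(conf, 0.0), 1.0),
                        label=label,
                        model_id=model_id,
                        image_id=image_id,
                    )
                )
            else:
                out.append(GroundTruthBox(box=box, label=label, image_id=image_id))
    return out


def write_yolo_labels(
    boxes: Sequence[GroundTruthBox | Detection],
    path: str | Path,
    *,
    with_confidence: bool = False,
) -> None:
    """Write boxes as YOLO-format lines; confidences carry 6 decimals so a
    read-back round-trips within 1e-6 per field."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = []
    for item in boxes:
        b = item.box
        line = f"{item.label} {b.cx:.6f} {b.cy:.6f} {b.w:.6f} {b.h:.6f}"
        if with_confidence:
            line += f" {item.confidence:.6f}"
        lines.append(line)
    path.write_text("".join(line + "\n" for line in lines))


def read_coco_detections(
    json_path: str | Path,
    image_sizes: Mapping[str, tuple[int, int]],
    *,
    model_id: str = "",
) -> list[Detection]:
    """Read a COCO detection-results JSON array.

    ``bbox`` is pixel ``[x, y, width, height]`` with a top-left origin; each
    entry is converted to normalized center form using ``image_sizes``, a map
    ``image_id -> (width, height)`` in pixels.
    """
    entries = json.loads(Path(json_path).read_text())
    out: list[Detection] = []
    for i, entry in enumerate(entries):
        image_id = str(entry["image_id"])
        if image_id not in image_sizes:
            raise KeyError(
                f"{json_path}[{i}]: image_id {image_id!r} not in the size registry"
            )
        width, height = image_sizes[image_id]
        x, y, w, h = entry["bbox"]
        box = Box(
            (x + w / 2.0) / width,
            (y + h / 2.0) / height,
            w / width,
            h / height,
        ).clipped()
        out.append(
            Detection(
                box=box,
                confidence=float(entry["score"]),
                label=int(entry.get("category_id", 0)),
                model_id=model_id,
                image_id=image_id,
            )
        )
    return out


def split_dataset(
    image_ids: Sequence[str],
    fractions: tuple[float, float, float] = (0.80, 0.05, 0.15),
    seed: int = 0,
    *,
    strata: Mapping[str, str] | None = None,
) -> DatasetSplit:
    """Shuffle and partition image ids into train/val/test.

    The integer rule is floor for the train and test counts with the remainder
    to validation — the only rule consistent with 407 ids at (0.80, 0.05,
    0.15) yielding 325/21/61 (0.05·407 = 20.35 yet 21 validation items).
    Deterministic for a fixed seed.  ``strata`` optionally maps each id to a
    stratum; the floor rule is then applied within each stratum.
    """
    image_ids = list(image_ids)
    n = len(image_ids)
    if n < 3:
        raise ValueError(f"need at least 3 ids to form 3 partitions, got {n}")
    f_train, f_val, f_test = fractions
    if min(fractions) <= 0 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions {fractions} must be positive and sum to 1")

    if strata is not None:
        groups: dict[str, list[str]] = {}
        for iid in image_ids:
            groups.setdefault(strata[iid], []).append(iid)
        train: list[str] = []
        val: list[str] = []
        test: list[str] = []
        for key in sorted(groups):
            sub = split_dataset(groups[key], fractions, seed)
            train += sub.train_ids
            val += sub.val_ids
            test += sub.test_ids
        return DatasetSplit(tuple(train), tuple(val), tuple(test), fractions)

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    shuffled = [image_ids[i] for i in order]
    n_train = int(np.floor(f_train * n))
    n_test = int(np.floor(f_test * n))
    train = shuffled[:n_train]
    test = shuffled[n_train : n_train + n_test]
    val = shuffled[n_train + n_test :]
    return DatasetSplit(tuple(train), tuple(val), tuple(test), fractions)


def write_split_manifest(split: DatasetSplit, directory: str | Path) -> None:
    """Persist a split as three plain-text id lists (one id per line)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, ids in (
        ("train", split.train_ids),
        ("val", split.val_ids),
        ("test", split.test_ids),
    ):
        (directory / f"{name}.txt").write_text("".join(i + "\n" for i in ids))


def read_split_manifest(directory: str | Path) -> DatasetSplit:
    directory = Path(directory)
    parts = {}
    for name in ("train", "val", "test"):
        text = (directory / f"{name}.txt").read_text()
        parts[name] = tuple(line for line in text.splitlines() if line)
    n = sum(len(v) for v in parts.values())
    fractions = tuple(len(parts[k]) / n for k in ("train", "val", "test"))
    return DatasetSplit(parts["train"], parts["val"], parts["test"], fractions)


def read_benchmark(root: str | Path) -> list[ImageRecord]:
    """Load a benchmark directory (``gt/`` labels plus ``preds/<model>/``
    prediction files) into :class:`ImageRecord` objects."""
    root = Path(root)
    gt_dir = root / "gt"
    records: dict[str, ImageRecord] = {}
    for path in sorted(gt_dir.glob("*.txt")):
        iid = path.stem
        records[iid] = ImageRecord(
            image_id=iid,
            ground_truth=read_yolo_labels(path, image_id=iid),
        )
    preds_root = root / "preds"
    if preds_root.is_dir():
        for model_dir in sorted(p for p in preds_root.iterdir() if p.is_dir()):
            model_id = model_dir.name
            for path in sorted(model_dir.glob("*.txt")):
                iid = path.stem
                rec = records.setdefault(iid, ImageRecord(image_id=iid))
                rec.predictions[model_id] = read_yolo_labels(
                    path, has_confidence=True, image_id=iid, model_id=model_id
                )
    return list(records.values())
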