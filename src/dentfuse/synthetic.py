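"""Synthetic detection benchmark: ground truth plus simulated detectors.

The simulator emulates detector *behavior* — miss rates, false-positive
rates, localization jitter, confidence calibration — not radiograph pixels;
no image files are produced.  Ground-truth boxes mimic impacted-tooth
annotations on panoramic radiographs: 1–4 smallish boxes per image, centered
in two horizontal bands standing in for the upper and lower jaw.

Two detector presets mirror the qualitative asymmetry that box fusion
exploits: ``recall_heavy`` (finds nearly everything but with sloppy boxes and
frequent false alarms, YOLO-like) and ``precision_heavy`` (misses more but
localizes tightly and rarely hallucinates).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .geometry import Box, Detection, GroundTruthBox, iou
from .io_formats import (
    DatasetSplit,
    ImageRecord,
    split_dataset,
    write_split_manifest,
    write_yolo_labels,
)

__all__ = [
    "ConfidenceModel",
    "DetectorProfile",
    "SimulatorConfig",
    "PROFILES",
    "generate_ground_truth",
    "simulate_detector",
    "make_benchmark",
]

# (x1, y1, x2, y2) regions where box centers may fall: two horizontal bands
# standing in for the upper and lower jaw of a panoramic radiograph.
DEFAULT_REGIONS: tuple[tuple[float, float, float, float], ...] = (
    (0.10, 0.25, 0.90, 0.45),
    (0.10, 0.55, 0.90, 0.75),
)

MAX_GT_IOU = 0.3  # annotated teeth barely overlap; resample above this
_MAX_RESAMPLES = 1000


@dataclass(frozen=True)
class ConfidenceModel:
    """Linear-in-IoU confidence: conf = clip(a·IoU + b + ε, floor, 1) with
    Gaussian ε — the simplest model that makes confidence informative for
    WBF's weighted averages."""

    slope: float = 0.75
    intercept: float = 0.15
    noise_std: float = 0.05
    floor: float = 0.01

    def sample(self, realized_iou: float, rng: np.random.Generator) -> float:
        raw = (
            self.slope * realized_iou
            + self.intercept
            + rng.normal(0.0, self.noise_std)
        )
        return float(np.clip(raw, self.floor, 1.0))


@dataclass(frozen=True)
class DetectorProfile:
    """One simulated detector's error profile.

    ``miss_rate`` — probability a ground-truth box goes undetected;
    ``fp_rate`` — expected false positives per image (Poisson);
    ``loc_jitter`` — std of the Gaussian noise added to each of cx, cy, w, h.
    """

    name: str
    miss_rate: float = 0.05
    fp_rate: float = 0.5
    loc_jitter: float = 0.01
    conf_model: ConfidenceModel = field(default_factory=ConfidenceModel)

    def __post_init__(self) -> None:
        if not (0.0 <= self.miss_rate <= 1.0):
            raise ValueError(f"miss_rate {self.miss_rate} outside [0, 1]")
        if self.fp_rate < 0.0 or self.loc_jitter < 0.0:
            raise ValueError("fp_rate and loc_jitter must be >= 0")


#: Default detector presets.  recall_heavy trades precision for coverage
#: (low miss, many false alarms, loose boxes); precision_heavy the reverse.
PROFILES: dict[str, DetectorProfile] = {
    "recall_heavy": DetectorProfile(
        name="recall_heavy",
        miss_rate=0.03,
        fp_rate=0.9,
        loc_jitter=0.006,
        conf_model=ConfidenceModel(slope=0.75, intercept=0.15, noise_std=0.08),
    ),
    "precision_heavy": DetectorProfile(
        name="precision_heavy",
        miss_rate=0.15,
        fp_rate=0.15,
        loc_jitter=0.004,
        conf_model=ConfidenceModel(slope=0.85, intercept=0.10, noise_std=0.04),
    ),
}


@dataclass(frozen=True)
class SimulatorConfig:
    """Ground-truth generation settings.

    Defaults emulate impacted-tooth annotation statistics: 1–4 boxes per
    image with width/height fractions around 0.08 ± 0.02, centered in two
    jaw bands.
    """

    n_images: int = 200
    boxes_per_image: tuple[int, int] = (1, 4)
    box_size_mean: float = 0.08
    box_size_std: float = 0.02
    placement_regions: tuple[tuple[float, float, float, float], ...] = DEFAULT_REGIONS
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.boxes_per_image
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid boxes_per_image range {self.boxes_per_image}")
        if self.box_size_mean <= 0 or self.box_size_std < 0:
            raise ValueError("box sizes must be positive")


def _image_rng(seed: int, stream: int, index: int) -> np.random.Generator:
    # integer-indexed RNG streams: image `index` of stream `stream` always
    # sees the same draws regardless of how many images are generated
    return np.random.default_rng(np.random.SeedSequence([seed, stream, index]))


def _sample_gt_box(
    config: SimulatorConfig, rng: np.random.Generator
) -> Box:
    region = config.placement_regions[rng.integers(len(config.placement_regions))]
    x1, y1, x2, y2 = region
    cx = rng.uniform(x1, x2)
    cy = rng.uniform(y1, y2)
    w = float(np.clip(rng.normal(config.box_size_mean, config.box_size_std), 0.02, 0.3))
    h = float(np.clip(rng.normal(config.box_size_mean, config.box_size_std), 0.02, 0.3))
    return Box(cx, cy, w, h).clipped()


def generate_ground_truth(config: SimulatorConfig) -> list[ImageRecord]:
    """Generate seeded, deterministic ground truth.

    Each image receives a uniform number of boxes in ``boxes_per_image``; any
    box overlapping an existing one with IoU above 0.3 is resampled (up to
    1000 times before a generation error).
    """
    records: list[ImageRecord] = []
    width = len(str(max(config.n_images - 1, 1)))
    for i in range(config.n_images):
        rng = _image_rng(config.seed, 0, i)
        image_id = f"img_{i:0{width}d}"
        n_boxes = int(rng.integers(config.boxes_per_image[0], config.boxes_per_image[1] + 1))
        boxes: list[Box] = []
        for _ in range(n_boxes):
            for _attempt in range(_MAX_RESAMPLES):
                cand = _sample_gt_box(config, rng)
                if all(iou(cand, b) <= MAX_GT_IOU for b in boxes):
                    boxes.append(cand)
                    break
            else:
                raise RuntimeError(
                    f"could not place {n_boxes} boxes in image {image_id} after "
                    f"{_MAX_RESAMPLES} resamples; regions too small for the box sizes"
                )
        records.append(
            ImageRecord(
                image_id=image_id,
                ground_truth=[
                    GroundTruthBox(box=b, label=0, image_id=image_id) for b in boxes
                ],
            )
        )
    return records


def simulate_detector(
    records: Sequence[ImageRecord],
    profile: DetectorProfile,
    seed: int,
    *,
    regions: tuple[tuple[float, float, float, float], ...] = DEFAULT_REGIONS,
    box_size_mean: float = 0.08,
    box_size_std: float = 0.02,
) -> dict[str, list[Detection]]:
    """Simulate one detector's predictions on every image.

    Each ground-truth box is detected with probability ``1 − miss_rate``; the
    detection's coordinates receive i.i.d. Gaussian jitter and its confidence
    is drawn from the profile's confidence model given the realized IoU with
    its source box.  Poisson(``fp_rate``) false positives per image are
    placed uniformly in the jaw bands with confidences from the low tail of
    the same model (IoU = 0).
    """
    # stable per-profile stream id (str hash is randomized per process)
    stream = 1 + zlib.crc32(profile.name.encode()) % 1000
    out: dict[str, list[Detection]] = {}
    for i, rec in enumerate(records):
        rng = _image_rng(seed, stream, i)
        dets: list[Detection] = []
        for gt in rec.ground_truth:
            if rng.uniform() < profile.miss_rate:
                continue
            b = gt.box
            if profile.loc_jitter > 0:
                jit = rng.normal(0.0, profile.loc_jitter, size=4)
            else:
                jit = np.zeros(4)
            jittered = Box(
                float(np.clip(b.cx + jit[0], 0.0, 1.0)),
                float(np.clip(b.cy + jit[1], 0.0, 1.0)),
                max(b.w + jit[2], 0.01),
                max(b.h + jit[3], 0.01),
            ).clipped()
            realized = iou(jittered, b)
            conf = profile.conf_model.sample(realized, rng)
            dets.append(
                Detection(
                    box=jittered,
                    confidence=conf,
                    label=gt.label,
                    model_id=profile.name,
                    image_id=rec.image_id,
                )
            )
        n_fp = int(rng.poisson(profile.fp_rate))
        for _ in range(n_fp):
            region = regions[rng.integers(len(regions))]
            x1, y1, x2, y2 = region
            fp_box = Box(
                float(rng.uniform(x1, x2)),
                float(rng.uniform(y1, y2)),
                float(np.clip(rng.normal(box_size_mean, box_size_std), 0.02, 0.3)),
                float(np.clip(rng.normal(box_size_mean, box_size_std), 0.02, 0.3)),
            ).clipped()
            conf = profile.conf_model.sample(0.0, rng)
            dets.append(
                Detection(
                    box=fp_box,
                    confidence=conf,
                    label=0,
                    model_id=profile.name,
                    image_id=rec.image_id,
                )
            )
        out[rec.image_id] = dets
    return out


def make_benchmark(
    config: SimulatorConfig,
    profiles: Sequence[DetectorProfile],
    out_dir: str | Path | None = None,
    split_fractions: tuple[float, float, float] = (0.80, 0.05, 0.15),
    seed: int | None = None,
) -> tuple[list[ImageRecord], DatasetSplit]:
    """Build a complete benchmark: ground truth, every profile's predictions
    and a train/val/test split; optionally persisted as YOLO-format files
    plus a split manifest.  Fully deterministic per seed.
    """
    if len(profiles) < 2:
        raise ValueError("a fusion benchmark needs at least 2 detector profiles")
    seed = config.seed if seed is None else seed
    if seed != config.seed:
        config = replace(config, seed=seed)
    records = generate_ground_truth(config)
    for profile in profiles:
        preds = simulate_detector(records, profile, seed)
        for rec in records:
            rec.predictions[profile.name] = preds[rec.image_id]
    split = split_dataset(
        [r.image_id for r in records], split_fractions, seed=seed
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        for rec in records:
            write_yolo_labels(rec.ground_truth, out_dir / "gt" / f"{rec.image_id}.txt")
            for model_id, dets in rec.predictions.items():
                write_yolo_labels(
                    dets,
                    out_dir / "preds" / model_id / f"{rec.image_id}.txt",
                    with_confidence=True,
                )
        write_split_manifest(split, out_dir / "split")
    return records, split
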