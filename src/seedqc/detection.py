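"""End-to-end detection: segment a tray image, classify every seed crop.

``detect`` runs the watershed pipeline, feeds each surviving crop through
the classifier, and returns one :class:`Detection` (bounding box, class,
softmax confidence) per crop, sorted by (y0, x0), plus an annotated
overlay.  ``batch_detect`` scores a directory of scenes against optional
ground-truth manifests by greedy IoU matching (a detection counts for a
ground-truth seed when their boxes overlap with IoU >= 0.5).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from .arch import SeedClassifier
from .segmentation import SegmentationConfig, load_image, segment_scene
from .synthgen import BBox, DEFECTIVE, GOOD, CLASSES
from .traineval import ConfusionCounts, MetricsReport, metrics, predict, prepare_crop

logger = logging.getLogger(__name__)

#: IoU above which a detection is matched to a ground-truth seed
IOU_MATCH = 0.5

_COLORS = {GOOD: (60, 220, 60), DEFECTIVE: (230, 60, 60)}


@dataclass(frozen=True)
class Detection:
    bbox: BBox
    predicted_class: str
    confidence: float

    def __post_init__(self) -> None:
        if self.predicted_class not in CLASSES:
            raise ValueError(f"unknown class {self.predicted_class!r}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "bbox": self.bbox.as_list(),
            "class": self.predicted_class,
            "confidence": float(self.confidence),
        }

    @staticmethod
    def from_dict(d: dict) -> "Detection":
        return Detection(
            bbox=BBox(*d["bbox"]),
            predicted_class=d["class"],
            confidence=float(d["confidence"]),
        )


def detections_to_json(detections: list[Detection]) -> str:
    return json.dumps(
        {"detections": [d.to_dict() for d in detections]}, indent=1, sort_keys=True
    )


def detections_from_json(text: str) -> list[Detection]:
    return [Detection.from_dict(d) for d in json.loads(text)["detections"]]


def annotate(image: np.ndarray, detections: list[Detection]) -> np.ndarray:
    """Draw class-coloured boxes with confidence text on a copy of the scene."""
    im = Image.fromarray(image.astype(np.uint8)).convert("RGB")
    draw = ImageDraw.Draw(im)
    for det in detections:
        color = _COLORS[det.predicted_class]
        b = det.bbox
        draw.rectangle([b.x0, b.y0, b.x1 - 1, b.y1 - 1], outline=color, width=2)
        draw.text((b.x0 + 2, max(0, b.y0 - 12)), f"{det.confidence:.2f}", fill=color)
    return np.asarray(im)


def detect(
    image: str | Path | np.ndarray,
    model: SeedClassifier,
    config: SegmentationConfig | None = None,
) -> tuple[list[Detection], np.ndarray]:
    """Segment + classify one scene; return detections and annotated image."""
    config = config or SegmentationConfig()
    if isinstance(image, (str, Path)):
        image = load_image(image)
    t0 = time.perf_counter()
    crops, _ = segment_scene(image, config)
    if not crops:
        logger.warning("detect: no seeds found in scene")
        return [], annotate(image, [])
    # classify from margin-expanded patches (same 4 px margin the training
    # crops carry) while reporting the tight segmentation bbox
    h, w = image.shape[:2]
    patches = []
    for c in crops:
        bb = BBox(c.bbox.x0 - 4, c.bbox.y0 - 4, c.bbox.x1 + 4, c.bbox.y1 + 4).clip(w, h)
        patches.append(prepare_crop(image[bb.y0 : bb.y1, bb.x0 : bb.x1], model.config.input_size))
    batch = np.stack(patches)
    labels, confidences = predict(model, batch)
    detections = [
        Detection(bbox=c.bbox, predicted_class=str(l), confidence=float(conf))
        for c, l, conf in zip(crops, labels, confidences)
    ]
    detections.sort(key=lambda d: (d.bbox.y0, d.bbox.x0))
    logger.info(
        "detect: %d seed(s) in %.2f s", len(detections), time.perf_counter() - t0
    )
    return detections, annotate(image, detections)


def _greedy_match(
    detections: list[Detection], gt_boxes: list[BBox]
) -> list[tuple[int, int]]:
    """Greedy one-to-one (detection, ground truth) pairs by descending IoU."""
    pairs = []
    for i, det in enumerate(detections):
        for j, gt in enumerate(gt_boxes):
            iou = det.bbox.iou(gt)
            if iou >= IOU_MATCH:
                pairs.append((iou, i, j))
    pairs.sort(reverse=True)
    used_d: set[int] = set()
    used_g: set[int] = set()
    matches = []
    for _, i, j in pairs:
        if i in used_d or j in used_g:
            continue
        used_d.add(i)
        used_g.add(j)
        matches.append((i, j))
    return matches


def score_detections(
    detections: list[Detection], ground_truth: list[tuple[BBox, str]]
) -> ConfusionCounts:
    """Confusion counts for one scene after IoU matching.

    Matched pairs contribute their (true, predicted) outcome.  Unmatched
    ground truth is a miss, scored as the wrong prediction (defective
    missed -> FN, good missed -> FP); spurious unmatched detections count
    as false positives.
    """
    gt_boxes = [b for b, _ in ground_truth]
    matches = _greedy_match(detections, gt_boxes)
    matched_d = {i for i, _ in matches}
    matched_g = {j for _, j in matches}
    tp = tn = fp = fn = 0
    for i, j in matches:
        true, pred = ground_truth[j][1], detections[i].predicted_class
        if true == DEFECTIVE and pred == DEFECTIVE:
            tp += 1
        elif true == DEFECTIVE:
            fn += 1
        elif pred == DEFECTIVE:
            fp += 1
        else:
            tn += 1
    for j, (_, true) in enumerate(ground_truth):
        if j not in matched_g:
            if true == DEFECTIVE:
                fn += 1
            else:
                fp += 1
    fp += sum(1 for i in range(len(detections)) if i not in matched_d)
    return ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)


def _load_ground_truth(scene_path: Path) -> list[tuple[BBox, str]] | None:
    js = scene_path.with_suffix(".json")
    if not js.exists():
        return None
    data = json.loads(js.read_text())
    return [(BBox(*s["bbox"]), s["class"]) for s in data["seeds"]]


def batch_detect(
    directory: str | Path,
    model: SeedClassifier,
    config: SegmentationConfig | None = None,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, MetricsReport | None]:
    """Detect over every image in a directory; score scenes with ground truth.

    Ground truth is looked up as ``<scene>.json`` next to each image (the
    format the scene generator writes).  Returns a per-image frame and,
    when any scene had ground truth, the aggregate metrics over the pooled
    confusion counts; without manifests only detections are produced.
    """
    directory = Path(directory)
    config = config or SegmentationConfig()
    images = sorted(
        p
        for p in directory.iterdir()
        if p.suffix.lower() in (".png", ".jpg", ".jpeg", ".tif", ".tiff")
    )
    if not images:
        raise FileNotFoundError(f"no images found in {directory}")
    rows = []
    pooled = np.zeros(4, dtype=int)  # TP, TN, FP, FN
    any_gt = False
    for path in images:
        detections, overlay = detect(path, model, config)
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            Image.fromarray(overlay).save(out / f"{path.stem}_overlay.png")
            (out / f"{path.stem}_detections.json").write_text(
                detections_to_json(detections)
            )
        row: dict = {"scene": str(path), "n_detections": len(detections)}
        gt = _load_ground_truth(path)
        if gt is not None:
            any_gt = True
            counts = score_detections(detections, gt)
            pooled += np.array([counts.TP, counts.TN, counts.FP, counts.FN])
            row.update(TP=counts.TP, TN=counts.TN, FP=counts.FP, FN=counts.FN)
            row["accuracy"] = metrics(counts).accuracy if counts.total else float("nan")
        rows.append(row)
    frame = pd.DataFrame(rows)
    aggregate = None
    if any_gt:
        aggregate = metrics(
            ConfusionCounts(
                TP=int(pooled[0]), TN=int(pooled[1]), FP=int(pooled[2]), FN=int(pooled[3])
            )
        )
    return frame, aggregate
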