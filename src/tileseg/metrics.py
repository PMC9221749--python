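"""Pixelwise multi-label segmentation metrics.

Confusion counts (TP/FP/FN) are accumulated per channel and pooled
micro-style across images; F1, sensitivity and IoU derive from the pooled
counts.  The "overall" figure pools the four channels' pixel counts as well.
Degenerate 0/0 metrics are 1.0 by convention (perfect agreement on an empty
class); an alternative is to exclude such channels from pooling, which this
module deliberately does not do.  Specificity is not reported: in semantic
segmentation the negative class is the background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from tileseg.channels import CLASS_NAMES, N_CLASSES
from tileseg import tiling

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "binarize",
    "confusion_counts",
    "f1_from_counts",
    "sensitivity_from_counts",
    "iou_from_counts",
    "predict_full_image",
    "evaluate_model",
]


@dataclass
class ConfusionCounts:
    """Pixel counts of true positives, false positives and false negatives."""

    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if self.tp < 0 or self.fp < 0 or self.fn < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)

    def __iadd__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return self + other


def binarize(prob_map: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map; a pixel is set iff ``prob >= threshold``."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    prob_map = np.asarray(prob_map)
    if prob_map.size and (prob_map.min() < 0 or prob_map.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    return prob_map >= threshold


def confusion_counts(pred: np.ndarray, target: np.ndarray):
    """Per-channel TP/FP/FN between binary masks.

    2-D inputs give a single :class:`ConfusionCounts`; channel-stacked
    ``(C, H, W)`` inputs give a list with one entry per channel.
    """
    pred = np.asarray(pred).astype(bool)
    target = np.asarray(target).astype(bool)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs target {target.shape}")
    if pred.ndim == 2:
        return ConfusionCounts(
            tp=int((pred & target).sum()),
            fp=int((pred & ~target).sum()),
            fn=int((~pred & target).sum()),
        )
    return [confusion_counts(p, t) for p, t in zip(pred, target)]


def _safe_ratio(num: int, den: int) -> float:
    # 0/0 means perfect agreement on an empty class
    return 1.0 if den == 0 else num / den


def f1_from_counts(c: ConfusionCounts) -> float:
    """F1 = 2TP / (2TP + FP + FN); harmonic mean of precision and recall."""
    return _safe_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn)


def sensitivity_from_counts(c: ConfusionCounts) -> float:
    """Sensitivity (recall) = TP / (TP + FN)."""
    return _safe_ratio(c.tp, c.tp + c.fn)


def iou_from_counts(c: ConfusionCounts) -> float:
    """Intersection over union = TP / (TP + FP + FN)."""
    return _safe_ratio(c.tp, c.tp + c.fp + c.fn)


_METRIC_FNS = {
    "f1": f1_from_counts,
    "sensitivity": sensitivity_from_counts,
    "iou": iou_from_counts,
}


@dataclass
class MetricsReport:
    """Per-channel and overall metrics with the underlying pooled counts."""

    per_channel: dict = field(default_factory=dict)  # name -> {metric -> float}
    overall: dict = field(default_factory=dict)  # metric -> float
    counts: dict = field(default_factory=dict)  # name -> ConfusionCounts
    n_images: int = 0
    tile_count: int = 1

    @classmethod
    def from_counts(
        cls,
        counts: Sequence[ConfusionCounts],
        n_images: int,
        tile_count: int,
    ) -> "MetricsReport":
        if len(counts) != N_CLASSES:
            raise ValueError(f"expected {N_CLASSES} channel counts, got {len(counts)}")
        per_channel = {
            name: {m: fn(c) for m, fn in _METRIC_FNS.items()}
            for name, c in zip(CLASS_NAMES, counts)
        }
        pooled = ConfusionCounts()
        for c in counts:
            pooled = pooled + c
        overall = {m: fn(pooled) for m, fn in _METRIC_FNS.items()}
        return cls(
            per_channel=per_channel,
            overall=overall,
            counts=dict(zip(CLASS_NAMES, counts)),
            n_images=n_images,
            tile_count=tile_count,
        )

    def to_rows(self) -> list[dict]:
        """Flatten into result-CSV rows (one per channel plus 'overall')."""
        rows = []
        for name in CLASS_NAMES:
            c = self.counts[name]
            rows.append(
                {
                    "tile_count": self.tile_count,
                    "channel": name,
                    **self.per_channel[name],
                    "tp": c.tp,
                    "fp": c.fp,
                    "fn": c.fn,
                }
            )
        pooled = ConfusionCounts()
        for name in CLASS_NAMES:
            pooled = pooled + self.counts[name]
        rows.append(
            {
                "tile_count": self.tile_count,
                "channel": "overall",
                **self.overall,
                "tp": pooled.tp,
                "fp": pooled.fp,
                "fn": pooled.fn,
            }
        )
        return rows

    def to_json_dict(self) -> dict:
        return {
            "tile_count": self.tile_count,
            "n_images": self.n_images,
            "per_channel": self.per_channel,
            "overall": self.overall,
            "counts": {
                name: {"tp": c.tp, "fp": c.fp, "fn": c.fn}
                for name, c in self.counts.items()
            },
        }


def predict_full_image(model, image: np.ndarray, n_tiles: int) -> np.ndarray:
    """Tile an image, predict each tile, stitch probabilities back together.

    Returns a ``(4, H, W)`` float probability map.  ``model`` follows the
    tile-predictor protocol of :func:`tileseg.model.predict_tiles`.
    """
    from tileseg.model import predict_tiles  # deferred: avoid import cycle

    height, width = image.shape[-2:]
    layout = tiling.select_grid(n_tiles, height, width)
    regions = tiling.tile_bounds(layout, height, width)
    crops = tiling.extract_tiles(image, regions)
    prob_tiles = predict_tiles(model, crops)
    return tiling.stitch_tiles(prob_tiles, regions, height, width)


def evaluate_model(
    model,
    test_images,
    n_tiles: int,
    threshold: float = 0.5,
    average: str = "micro",
) -> MetricsReport:
    """Tile-predict-stitch evaluation of a model on held-out full images.

    Confusion counts are pooled over all images per channel (micro).  With
    ``average="macro"`` metrics are instead computed per image and averaged;
    the report's counts remain the pooled ones either way.
    """
    if not test_images:
        raise ValueError("test set is empty")
    if average not in ("micro", "macro"):
        raise ValueError(f"unknown average {average!r}")

    pooled = [ConfusionCounts() for _ in range(N_CLASSES)]
    per_image_reports = []
    for item in test_images:
        image, target = item.image, item.mask
        probs = predict_full_image(model, image, n_tiles)
        pred = binarize(probs, threshold)
        counts = confusion_counts(pred, target)
        pooled = [a + b for a, b in zip(pooled, counts)]
        if average == "macro":
            per_image_reports.append(
                MetricsReport.from_counts(counts, n_images=1, tile_count=n_tiles)
            )

    report = MetricsReport.from_counts(pooled, n_images=len(test_images), tile_count=n_tiles)
    if average == "macro":
        for name in CLASS_NAMES:
            report.per_channel[name] = {
                m: float(np.mean([r.per_channel[name][m] for r in per_image_reports]))
                for m in _METRIC_FNS
            }
        report.overall = {
            m: float(np.mean([r.overall[m] for r in per_image_reports]))
            for m in _METRIC_FNS
        }
    return report
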