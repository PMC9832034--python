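"""Image-wise segmentation metrics with class-weighted aggregation.

Metrics (Dice, sensitivity, specificity) are computed per image and per
lesion class from one-vs-rest pixel confusion counts.  Aggregation follows
the image-wise protocol: for each class, images where either the reference
or the prediction is empty are skipped (no zero-division surrogates); the
remaining per-image scores are averaged, and the final summary weights the
per-class means by the number of evaluated images in which the class is
present in the reference.  A lesion-size analysis bins each record into
reference-area quartiles (per class) and reports the score distribution
per bin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .phantom import CLASS_COLORS, CLASS_NAMES

LESION_CLASSES = (1, 2, 3)


@dataclass
class EvalRecord:
    """One-vs-rest confusion counts of one class on one image."""

    image_id: str
    class_id: int
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def ref_area(self) -> int:
        return self.tp + self.fn

    @property
    def pred_area(self) -> int:
        return self.tp + self.fp

    @property
    def n_pixels(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(ref: np.ndarray, pred: np.ndarray, class_id: int,
              image_id: str = "") -> EvalRecord:
    if ref.shape != pred.shape:
        raise ValueError("reference and prediction shapes differ")
    if class_id not in LESION_CLASSES:
        raise ValueError(f"class_id must be one of {LESION_CLASSES}")
    r = ref == class_id
    p = pred == class_id
    tp = int(np.sum(r & p))
    fp = int(np.sum(~r & p))
    fn = int(np.sum(r & ~p))
    tn = int(np.sum(~r & ~p))
    return EvalRecord(image_id=image_id, class_id=class_id, tp=tp, fp=fp, fn=fn, tn=tn)


def evaluate_pair(ref: np.ndarray, pred: np.ndarray, image_id: str = "") -> list:
    """Records for all three lesion classes of one image pair."""
    return [confusion(ref, pred, c, image_id) for c in LESION_CLASSES]


def dice(rec: EvalRecord) -> float:
    return 2.0 * rec.tp / (2.0 * rec.tp + rec.fp + rec.fn)


def sensitivity(rec: EvalRecord) -> float:
    return rec.tp / (rec.tp + rec.fn)


def specificity(rec: EvalRecord) -> float:
    return rec.tn / (rec.tn + rec.fp)


METRICS = {"dice": dice, "sensitivity": sensitivity, "specificity": specificity}


@dataclass
class AggregateResult:
    per_class: pd.DataFrame  # class x (metric mean/std, n_used, n_skipped)
    weighted: dict  # metric -> weighted mean over classes
    weights: dict  # class -> weight (sums to 1 over usable classes)
    n_images: int

    def to_frame(self) -> pd.DataFrame:
        df = self.per_class.copy()
        row = {f"{m}_mean": v for m, v in self.weighted.items()}
        row["class"] = "MEAN"
        return pd.concat([df, pd.DataFrame([row])], ignore_index=True)


def aggregate(records: list, skip_empty: bool = True) -> AggregateResult:
    """Image-wise aggregation with the skip-empty rule.

    Per class, records with an empty reference or an empty prediction are
    dropped; a class with no usable record is reported as missing (NaN)
    and excluded from the weighted mean (its weight is not redistributed
    as zero — weights always sum to 1 over the usable classes).
    """
    image_ids = {r.image_id for r in records}
    rows = []
    weights_raw = {}
    for c in LESION_CLASSES:
        recs = [r for r in records if r.class_id == c]
        used = [r for r in recs if not skip_empty or (r.ref_area > 0 and r.pred_area > 0)]
        skipped = len(recs) - len(used)
        row = {"class": CLASS_NAMES[c], "n_used": len(used), "n_skipped": skipped}
        for name, fn in METRICS.items():
            vals = np.array([fn(r) for r in used])
            row[f"{name}_mean"] = float(vals.mean()) if vals.size else float("nan")
            row[f"{name}_std"] = float(vals.std(ddof=0)) if vals.size else float("nan")
        rows.append(row)
        # weight: evaluated images in which the class is present in the reference
        weights_raw[c] = sum(1 for r in used if r.ref_area > 0)
    per_class = pd.DataFrame(rows)

    usable = [c for c in LESION_CLASSES if weights_raw[c] > 0]
    total = sum(weights_raw[c] for c in usable)
    weights = {c: weights_raw[c] / total for c in usable} if total else {}
    weighted = {}
    for name in METRICS:
        if usable:
            weighted[name] = float(
                sum(weights[c] * per_class.loc[i, f"{name}_mean"]
                    for i, c in enumerate(LESION_CLASSES) if c in usable)
            )
        else:
            weighted[name] = float("nan")
    return AggregateResult(per_class=per_class, weighted=weighted,
                           weights={CLASS_NAMES[c]: w for c, w in weights.items()},
                           n_images=len(image_ids))


def weighted_mean(values, counts) -> float:
    """Class-weighted mean with weights proportional to presence counts."""
    values = np.asarray(values, dtype=float)
    counts = np.asarray(counts, dtype=float)
    return float(np.sum(values * counts) / np.sum(counts))


def lesion_size_quartiles(areas: np.ndarray) -> np.ndarray:
    """q1..q3 boundaries of the reference-area distribution."""
    return np.quantile(np.asarray(areas, dtype=float), [0.25, 0.5, 0.75])


def assign_quartile(area: float, bounds: np.ndarray) -> int:
    """Quartile bin 1..4; boundaries are right-inclusive (ties go low)."""
    return int(1 + np.searchsorted(bounds, area, side="left"))


def lesion_size_analysis(records: list, metric: str = "dice") -> pd.DataFrame:
    """Per-class, per-quartile distribution of a metric over usable records.

    Records must already satisfy the skip rule (non-empty reference and
    prediction).  Returns one row per (class, quartile) with mean/std/
    median/q1/q3 of the metric and the bin boundaries used.
    """
    fn = METRICS[metric]
    rows = []
    for c in LESION_CLASSES:
        recs = [r for r in records if r.class_id == c and r.ref_area > 0 and r.pred_area > 0]
        if not recs:
            continue
        if len(recs) < 4:
            raise ValueError(f"need at least 4 usable records per class, got {len(recs)}")
        areas = np.array([r.ref_area for r in recs], dtype=float)
        bounds = lesion_size_quartiles(areas)
        bins = np.array([assign_quartile(a, bounds) for a in areas])
        vals = np.array([fn(r) for r in recs])
        for q in (1, 2, 3, 4):
            sel = vals[bins == q]
            if sel.size == 0:
                continue
            rows.append({
                "class": CLASS_NAMES[c], "quartile": f"q{q}", "n": int(sel.size),
                f"{metric}_mean": float(sel.mean()), f"{metric}_std": float(sel.std(ddof=0)),
                f"{metric}_median": float(np.median(sel)),
                f"{metric}_q1": float(np.quantile(sel, 0.25)),
                f"{metric}_q3": float(np.quantile(sel, 0.75)),
                "area_bounds": bounds.tolist(),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reporting


def records_frame(records: list) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "image_id": r.image_id, "class": CLASS_NAMES[r.class_id],
            "tp": r.tp, "fp": r.fp, "fn": r.fn, "tn": r.tn,
            "ref_area": r.ref_area, "pred_area": r.pred_area,
        })
    return pd.DataFrame(rows, columns=["image_id", "class", "tp", "fp", "fn", "tn",
                                       "ref_area", "pred_area"])


def export_report(out_dir, records: list, aggregate_result: AggregateResult | None = None,
                  size_analysis: pd.DataFrame | None = None) -> dict:
    """Serialize per-image records, the aggregate table and the size
    analysis; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    rec_path = out / "records.csv"
    records_frame(records).to_csv(rec_path, index=False)
    paths["records"] = rec_path
    if aggregate_result is not None:
        agg_path = out / "metrics.csv"
        aggregate_result.to_frame().to_csv(agg_path, index=False)
        paths["metrics"] = agg_path
        (out / "weights.json").write_text(json.dumps(aggregate_result.weights, indent=2))
        paths["weights"] = out / "weights.json"
    if size_analysis is not None:
        size_path = out / "lesion_size.json"
        size_path.write_text(size_analysis.to_json(orient="records", indent=2))
        paths["lesion_size"] = size_path
    return paths


def overlay_png(image: np.ndarray, mask: np.ndarray, path, alpha: float = 0.45):
    """Write an RGB overlay of a label mask on a grayscale B-scan."""
    from PIL import Image

    rgb = np.stack([image] * 3, axis=-1).astype(float)
    for c, color in CLASS_COLORS.items():
        if c == 0:
            continue
        sel = mask == c
        rgb[sel] = (1 - alpha) * rgb[sel] + alpha * np.array(color, dtype=float)
    Image.fromarray(np.round(rgb).astype(np.uint8), mode="RGB").save(path)
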