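"""Saliency-annotation consistency scoring: IoU, SC, GC and aggregates.

For a binary saliency mask S and annotation mask G:

    IoU = |S∩G| / |S∪G|     (Jaccard index)
    SC  = |S∩G| / |S|       (saliency cover; precision-like)
    GC  = |S∩G| / |G|       (ground-truth cover; sensitivity-like)

Conventions: both masks empty gives IoU = 1 (perfect agreement on
absence); exactly one empty gives IoU = 0.  SC is undefined when |S| = 0
and GC when |G| = 0; undefined values are carried as ``None`` and excluded
from summaries with a reported exclusion count, never imputed.

The analytic ceiling on IoU imposed by an area mismatch alone is
``max_achievable_iou(r) = min(r, 1/r)`` for area ratio r = |S|/|G| — the
value attained when the smaller mask is perfectly nested in the larger.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigurationError

METRICS = ("iou", "sc", "gc")


@dataclass(frozen=True)
class MetricTriple:
    iou: float
    sc: float | None
    gc: float | None


@dataclass(frozen=True)
class ConsistencyRecord:
    image_id: str
    annotator_id: str
    model_id: str
    variant: str  # "S_o" | "S_h"
    iou: float | None
    sc: float | None
    gc: float | None
    area_s: int
    area_g: int


def compute_metrics(s: np.ndarray, g: np.ndarray) -> MetricTriple:
    """IoU/SC/GC between a saliency mask S and an annotation mask G."""
    s = np.asarray(s, dtype=bool)
    g = np.asarray(g, dtype=bool)
    if s.shape != g.shape:
        raise AlignmentError(f"mask shapes differ: {s.shape} vs {g.shape}")
    inter = int((s & g).sum())
    area_s = int(s.sum())
    area_g = int(g.sum())
    union = area_s + area_g - inter
    if union == 0:
        iou = 1.0  # agreement on absence
    else:
        iou = inter / union
    sc = inter / area_s if area_s > 0 else None
    gc = inter / area_g if area_g > 0 else None
    return MetricTriple(iou=iou, sc=sc, gc=gc)


def make_record(image_id: str, annotator_id: str, model_id: str, variant: str,
                s: np.ndarray, g: np.ndarray) -> ConsistencyRecord:
    t = compute_metrics(s, g)
    return ConsistencyRecord(
        image_id=image_id, annotator_id=annotator_id, model_id=model_id,
        variant=variant, iou=t.iou, sc=t.sc, gc=t.gc,
        area_s=int(np.asarray(s, dtype=bool).sum()),
        area_g=int(np.asarray(g, dtype=bool).sum()),
    )


def is_consistent(iou: float | None, threshold: float = 0.5) -> bool:
    """Boundary-inclusive IoU decision (detection-benchmark convention)."""
    if iou is None or not np.isfinite(iou):
        raise ConfigurationError("is_consistent requires a defined IoU")
    return iou >= threshold


def records_to_frame(records: Iterable[ConsistencyRecord]) -> pd.DataFrame:
    rows = [
        {
            "image_id": r.image_id, "annotator_id": r.annotator_id,
            "model_id": r.model_id, "variant": r.variant,
            "iou": np.nan if r.iou is None else r.iou,
            "sc": np.nan if r.sc is None else r.sc,
            "gc": np.nan if r.gc is None else r.gc,
            "area_s": r.area_s, "area_g": r.area_g,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


@dataclass
class ConsistencySummary:
    """Per-annotator medians/IQRs plus pooled overall medians.

    ``table`` has one row per (model, variant, metric) with an
    ``overall_median`` column (median over all pooled defined records) and
    per-annotator ``{annotator}_median`` / ``_q1`` / ``_q3`` columns, the
    layout of a per-model consistency table.  ``excluded`` counts records
    dropped because a metric was undefined.
    """

    table: pd.DataFrame
    excluded: pd.DataFrame  # (model, variant, metric) -> n undefined


def aggregate(records: Sequence[ConsistencyRecord]) -> ConsistencySummary:
    df = records_to_frame(records)
    if df.empty:
        raise ConfigurationError("no records to aggregate")
    annotators = sorted(df["annotator_id"].unique())
    rows, excl = [], []
    for (model, variant), sub in df.groupby(["model_id", "variant"], sort=True):
        for metric in METRICS:
            vals = sub[metric]
            defined = vals.dropna()
            excl.append({"model_id": model, "variant": variant, "metric": metric,
                         "n_undefined": int(vals.isna().sum())})
            if defined.empty:
                rows.append({"model_id": model, "variant": variant,
                             "metric": metric, "overall_median": np.nan})
                continue
            row = {"model_id": model, "variant": variant, "metric": metric,
                   "overall_median": float(defined.median())}
            for a in annotators:
                av = sub.loc[sub["annotator_id"] == a, metric].dropna()
                if av.empty:
                    row[f"{a}_median"] = np.nan
                    row[f"{a}_q1"] = np.nan
                    row[f"{a}_q3"] = np.nan
                else:
                    row[f"{a}_median"] = float(av.median())
                    row[f"{a}_q1"] = float(av.quantile(0.25))
                    row[f"{a}_q3"] = float(av.quantile(0.75))
            rows.append(row)
    return ConsistencySummary(table=pd.DataFrame(rows), excluded=pd.DataFrame(excl))


def area_ratio_analysis(records: Sequence[ConsistencyRecord]) -> pd.DataFrame:
    """Median and min-max range of |S|/|G| per (model, variant, annotator).

    Records with an empty annotation (|G| = 0) are excluded.  The summary
    also carries a pooled per-(model, variant) row with annotator ``*``.
    """
    df = records_to_frame(records)
    df = df[df["area_g"] > 0].copy()
    if df.empty:
        raise ConfigurationError("no records with nonempty annotations")
    df["ratio"] = df["area_s"] / df["area_g"]
    rows = []
    for (model, variant), sub in df.groupby(["model_id", "variant"], sort=True):
        groups = [("*", sub)] + list(sub.groupby("annotator_id", sort=True))
        for annot, g in groups:
            rows.append({
                "model_id": model, "variant": variant, "annotator_id": annot,
                "median_ratio": float(g["ratio"].median()),
                "min_ratio": float(g["ratio"].min()),
                "max_ratio": float(g["ratio"].max()),
                "n": int(len(g)),
            })
    return pd.DataFrame(rows)


def max_achievable_iou(ratio: float) -> float:
    """IoU ceiling for area ratio |S|/|G| = r: min(r, 1/r), attained when
    the smaller mask is nested inside the larger."""
    if not np.isfinite(ratio) or ratio <= 0:
        raise ConfigurationError("area ratio must be a positive finite number")
    return float(min(ratio, 1.0 / ratio))
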