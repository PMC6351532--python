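"""Pixel-level segmentation evaluation with exclusion regions and stratified reports.

Epithelium is the positive class throughout.  F1 (Dice) and the Jaccard index
are related by ``F1 = 2J / (1 + J)``; both are reported alongside plain pixel
accuracy.  Evaluation can exclude pixels (e.g. slide background and gland
lumina, which coarse gland-level annotations include but a pixel-level
segmentation legitimately labels as background).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .maskgen import detect_tissue

__all__ = [
    "SegmentationMetrics",
    "RegionRecord",
    "confusion",
    "region_report",
    "exclusion_from_background",
    "STRATA",
]

STRATA = ("benign", "cancer", "grade_group_1", "grade_group_2", "grade_group_3",
          "grade_group_4", "grade_group_5")


@dataclass(frozen=True)
class SegmentationMetrics:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def f1(self) -> float:
        if self.tp == 0:
            # no true positives anywhere: perfect score iff nothing was
            # predicted or expected positive, else 0
            return 1.0 if (self.fp == 0 and self.fn == 0) else 0.0
        return 2 * self.tp / (2 * self.tp + self.fp + self.fn)

    @property
    def jaccard(self) -> float:
        if self.tp == 0:
            return 1.0 if (self.fp == 0 and self.fn == 0) else 0.0
        return self.tp / (self.tp + self.fp + self.fn)


@dataclass(frozen=True)
class RegionRecord:
    """Per-region metrics plus stratum labels for Table-style reporting."""

    region_id: str
    metrics: SegmentationMetrics
    strata: tuple[str, ...] = ()

    def __post_init__(self):
        for s in self.strata:
            if s not in STRATA:
                raise ValueError(f"unknown stratum {s!r}; allowed: {STRATA}")


def confusion(
    pred: np.ndarray, truth: np.ndarray, exclude: np.ndarray | None = None
) -> SegmentationMetrics:
    """Pixel confusion counts of a predicted vs reference mask.

    Pixels where ``exclude`` is true do not contribute.  Raises if the shapes
    differ or no evaluable pixels remain.
    """
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    keep = np.ones(pred.shape, dtype=bool)
    if exclude is not None:
        exclude = np.asarray(exclude, dtype=bool)
        if exclude.shape != pred.shape:
            raise ValueError("exclusion mask shape mismatch")
        keep = ~exclude
    if not keep.any():
        raise ValueError("no evaluable pixels: exclusion mask covers the whole image")
    p, t = pred[keep], truth[keep]
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return SegmentationMetrics(tp=tp, fp=fp, fn=fn, tn=tn)


def _summarise(records: list[RegionRecord]) -> dict:
    f1s = np.array([r.metrics.f1 for r in records])
    return {
        "N": len(records),
        "f1_mean": f1s.mean(),
        "f1_sd": f1s.std(ddof=0),
        "f1_min": f1s.min(),
        "f1_max": f1s.max(),
        "accuracy_mean": float(np.mean([r.metrics.accuracy for r in records])),
        "jaccard_mean": float(np.mean([r.metrics.jaccard for r in records])),
    }


def region_report(
    records: list[RegionRecord],
    strata: list[str] | None = None,
    pooled: bool = False,
) -> pd.DataFrame:
    """Stratified summary table of per-region metrics.

    One row per requested stratum plus an always-present "all_regions" row:
    N, mean +/- sd of per-region F1 with min and max, and mean accuracy and
    Jaccard.  With ``pooled=True`` the accuracy/Jaccard columns are instead
    computed from the summed pixel counts of the stratum.
    """
    if not records:
        raise ValueError("no records to report")
    strata = list(strata) if strata is not None else [
        s for s in STRATA if any(s in r.strata for r in records)
    ]
    for s in strata:
        if s not in STRATA:
            raise ValueError(f"unknown stratum {s!r}; allowed: {STRATA}")
    rows = {}
    for name, group in [("all_regions", records)] + [
        (s, [r for r in records if s in r.strata]) for s in strata
    ]:
        if not group:
            continue
        row = _summarise(group)
        if pooled:
            pool = SegmentationMetrics(
                tp=sum(r.metrics.tp for r in group), fp=sum(r.metrics.fp for r in group),
                fn=sum(r.metrics.fn for r in group), tn=sum(r.metrics.tn for r in group),
            )
            row["accuracy_mean"] = pool.accuracy
            row["jaccard_mean"] = pool.jaccard
        rows[name] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def format_report(table: pd.DataFrame) -> str:
    """Render a report as aligned text, Table-style: ``F1 mean +/- sd (min, max)``."""
    lines = [f"{'Regions':<16}{'N':>5}  {'F1 mean (min, max)':<28}{'Accuracy':>9}{'Jaccard':>9}"]
    for name, row in table.iterrows():
        f1 = f"{row.f1_mean:.3f} ± {row.f1_sd:.2f} ({row.f1_min:.3f}, {row.f1_max:.3f})"
        lines.append(
            f"{name:<16}{int(row.N):>5}  {f1:<28}{row.accuracy_mean:>9.3f}{row.jaccard_mean:>9.3f}"
        )
    return "\n".join(lines)


def exclusion_from_background(
    image: np.ndarray, tissue_mask: np.ndarray | None = None, od_threshold: float = 0.10
) -> np.ndarray:
    """Exclusion mask for gland-level reference data: everything that is not
    tissue (glass background and empty lumina, by the total-OD criterion) is
    excluded from scoring."""
    if tissue_mask is None:
        tissue_mask = detect_tissue(image, od_threshold=od_threshold, fill_holes=False)
    return ~np.asarray(tissue_mask, dtype=bool)
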