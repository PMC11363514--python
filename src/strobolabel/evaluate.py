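"""Keypoint-error evaluation: per-image Euclidean distances, summary
statistics and the independent two-sample t test.

Given predictions from two models and a ground-truth annotation set (all
in the CollectedData CSV dialect), computes per-image mean Euclidean
distances over keypoints present in both prediction and truth, summarizes
each group (mean, sample SD, SEM = sd/√n) and compares group means with
an unpaired two-sample t test.

Two t-statistic routes are provided.  ``from_sem`` computes
t = (m₁ − m₂)/√(sem₁² + sem₂²) directly from reported summaries with
df = n₁ + n₂ − 2 — the arithmetic that reproduces published results
stated as means and SEMs.  ``pooled`` is the classical pooled-variance
test from the raw per-image distances, with a Welch option; the two
coincide only when group sizes and variances agree with the reported
SEMs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pipeline import AnnotationRecord


@dataclass
class ErrorSummary:
    """Summary of one group of per-image mean distances (pixels)."""

    n: int
    mean: float
    sd: float
    sem: float
    distances: list[float]

    @classmethod
    def from_distances(cls, distances: Sequence[float]) -> "ErrorSummary":
        return summarize(distances)

    @classmethod
    def from_stats(cls, n: int, mean: float, sem: float) -> "ErrorSummary":
        """Build a summary from reported n / mean / SEM (no raw data)."""
        return cls(n=n, mean=mean, sd=sem * math.sqrt(n), sem=sem, distances=[])


@dataclass
class TTestResult:
    """t statistic (sign convention: group1 − group2), df and two-sided p."""

    t: float
    df: float
    p: float


def euclid_errors(
    predictions: Iterable[AnnotationRecord],
    truth: Iterable[AnnotationRecord],
) -> tuple[list[float], int]:
    """Per-image mean Euclidean distance between prediction and truth.

    Keypoints contribute only when present in both records (ABSENT slots
    are excluded pairwise, never imputed).  Returns the distance list in
    ascending image-id order and the count of shared images skipped
    because they had no shared keypoint.  Symmetric in its arguments.
    """
    by_image, n_empty = _per_image_distances(predictions, truth)
    return list(by_image.values()), n_empty


def _per_image_distances(
    predictions: Iterable[AnnotationRecord],
    truth: Iterable[AnnotationRecord],
) -> tuple[dict[int, float], int]:
    pred_map = {r.image_id: r for r in predictions}
    true_map = {r.image_id: r for r in truth}
    shared = sorted(pred_map.keys() & true_map.keys())
    if not shared:
        raise ValueError("predictions and truth share no image ids")
    by_image: dict[int, float] = {}
    n_empty = 0
    for image_id in shared:
        p, t = pred_map[image_id], true_map[image_id]
        ds = [
            math.hypot(pk[0] - tk[0], pk[1] - tk[1])
            for bp, pk in p.keypoints.items()
            if pk is not None and (tk := t.keypoints[bp]) is not None
        ]
        if not ds:
            n_empty += 1
            continue
        by_image[image_id] = float(np.mean(ds))
    return by_image, n_empty


def summarize(distances: Sequence[float]) -> ErrorSummary:
    """Mean, sample SD (n−1 denominator) and SEM of a distance list."""
    d = np.asarray(distances, dtype=float)
    if d.size < 2:
        raise ValueError(f"need at least 2 distances to summarize, got {d.size}")
    sd = float(d.std(ddof=1))
    return ErrorSummary(
        n=int(d.size), mean=float(d.mean()), sd=sd,
        sem=sd / math.sqrt(d.size), distances=[float(x) for x in d],
    )


def two_sample_t(
    a: ErrorSummary,
    b: ErrorSummary,
    mode: str = "pooled",
    welch: bool = False,
) -> TTestResult:
    """Independent two-sample t test between two error groups.

    ``from_sem``: t = (a.mean − b.mean)/√(a.sem² + b.sem²) with
    df = a.n + b.n − 2 (Welch–Satterthwaite df if ``welch``).  ``pooled``:
    classical pooled-variance statistic from the raw distance lists.
    Degenerate variance: zero spread with equal means gives t = 0, p = 1;
    zero spread with unequal means is an error.
    """
    if mode not in {"from_sem", "pooled"}:
        raise ValueError(f"mode must be 'from_sem' or 'pooled', got {mode!r}")
    diff = a.mean - b.mean
    if mode == "from_sem":
        se2_a, se2_b = a.sem**2, b.sem**2
        se = math.sqrt(se2_a + se2_b)
        if se == 0.0:
            if diff == 0.0:
                return TTestResult(t=0.0, df=a.n + b.n - 2, p=1.0)
            raise ValueError("degenerate variance: zero SEMs with unequal means")
        if welch:
            df = (se2_a + se2_b) ** 2 / (
                se2_a**2 / (a.n - 1) + se2_b**2 / (b.n - 1))
        else:
            df = a.n + b.n - 2
        t = diff / se
    else:
        if not a.distances or not b.distances:
            raise ValueError("pooled mode requires the raw distance lists")
        xa = np.asarray(a.distances, float)
        xb = np.asarray(b.distances, float)
        na, nb = xa.size, xb.size
        sp2 = ((na - 1) * xa.var(ddof=1) + (nb - 1) * xb.var(ddof=1)) / (na + nb - 2)
        se = math.sqrt(sp2 * (1 / na + 1 / nb))
        if se == 0.0:
            if diff == 0.0:
                return TTestResult(t=0.0, df=na + nb - 2, p=1.0)
            raise ValueError("degenerate variance: zero pooled variance with unequal means")
        df = na + nb - 2
        t = diff / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(t=float(t), df=float(df), p=min(p, 1.0))


def per_image_report(
    pred_a: Iterable[AnnotationRecord],
    pred_b: Iterable[AnnotationRecord],
    truth: Iterable[AnnotationRecord],
    label_a: str = "model_a",
    label_b: str = "model_b",
) -> pd.DataFrame:
    """Long-format table of per-image distances for two prediction sets.

    One row per (image, model); a ``group_mean`` column repeats each
    model's mean for plotting mean lines.
    """
    truth = list(truth)
    rows = []
    for label, preds in ((label_a, pred_a), (label_b, pred_b)):
        by_image, _ = _per_image_distances(list(preds), truth)
        mean = float(np.mean(list(by_image.values())))
        for image_id, d in by_image.items():
            rows.append({"model": label, "image_id": image_id,
                         "distance_px": d, "group_mean": mean})
    return pd.DataFrame(rows)
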