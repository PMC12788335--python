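"""Detection-quality metrics: transition distances, event P/R, Rand index.

Per stream, three views of agreement between predicted and true contacts:

* **Transition distances** -- IC and TC events pooled as one transition
  train per side; for every true transition the distance to the nearest
  predicted one and vice versa form a symmetric nearest-neighbour
  multiset. Its mean and median are the "mean/median Hausdorff" distances
  reported per stream (the classical Hausdorff maximum would be a single
  worst case; the averaged form is what yields informative sub-frame
  per-run values, and the max is available as an option).
* **Event precision/recall** -- predicted contacts are matched one-to-one
  to true contacts by frame overlap, greedily in temporal order; precision
  = TP/(TP+FP), recall = TP/(TP+FN).
* **Rand index** -- each frame's binary label is a cluster assignment; the
  Rand index is the fraction of frame pairs on which the two labelings
  agree (both in contact, both in flight, or consistently split),
  computed in closed form from the 2x2 confusion counts.

Dataset summaries average per-stream values (mean +- sample SD; the median
Hausdorff aggregates as median +- median absolute deviation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from sprintgc.contacts import ContactSegment
from sprintgc.errors import MetricUndefinedError, ValidationError


@dataclass
class RunMetrics:
    """Per-stream detection metrics."""

    stream_id: str
    mean_hausdorff_frames: float
    median_hausdorff_frames: float
    precision: float
    recall: float
    rand_index: float
    n_true_events: int
    n_pred_events: int
    fs: float = 250.0

    @property
    def mean_hausdorff_ms(self) -> float:
        return self.mean_hausdorff_frames * 1000.0 / self.fs

    @property
    def median_hausdorff_ms(self) -> float:
        return self.median_hausdorff_frames * 1000.0 / self.fs


def transition_distances(
    pred_events: Sequence[int], true_events: Sequence[int]
) -> np.ndarray:
    """Symmetric nearest-neighbour distance multiset between event trains.

    One distance per true event (to its nearest predicted event) plus one
    per predicted event (to its nearest true event); missed or spurious
    events therefore contribute large distances twice as hard as small
    jitter does.
    """
    p = np.asarray(pred_events, dtype=np.int64)
    t = np.asarray(true_events, dtype=np.int64)
    if p.size == 0 or t.size == 0:
        raise MetricUndefinedError("transition distances need nonempty event lists")
    d_pt = np.abs(p[:, None] - t[None, :]).min(axis=1)
    d_tp = np.abs(t[:, None] - p[None, :]).min(axis=1)
    return np.concatenate([d_tp, d_pt])


def hausdorff_stats(
    pred_events: Sequence[int], true_events: Sequence[int], kind: str = "averaged"
) -> tuple[float, float]:
    """(mean, median) of the symmetric NN multiset; ``kind='max'`` gives the
    classical symmetric Hausdorff maximum in both slots."""
    d = transition_distances(pred_events, true_events)
    if kind == "max":
        m = float(d.max())
        return m, m
    return float(d.mean()), float(np.median(d))


def event_precision_recall(
    pred_segments: Sequence[ContactSegment],
    true_segments: Sequence[ContactSegment],
) -> tuple[float, float, int]:
    """Greedy one-to-one overlap matching of predicted vs true contacts.

    A predicted contact is a true positive iff it shares at least one frame
    with a not-yet-matched true contact, scanning both lists in temporal
    order. Empty predictions against nonempty truth give precision 1.0 by
    convention (no false positives exist) and recall 0. Returns
    (precision, recall, n_matched).
    """
    tp = 0
    ti = 0
    n_true = len(true_segments)
    for seg in pred_segments:
        while ti < n_true and true_segments[ti].tc <= seg.ic:
            ti += 1
        if ti < n_true and seg.overlaps(true_segments[ti]):
            tp += 1
            ti += 1
    n_pred = len(pred_segments)
    precision = tp / n_pred if n_pred else 1.0
    recall = tp / n_true if n_true else 1.0
    return precision, recall, tp


def rand_index(a: np.ndarray, b: np.ndarray) -> float:
    """Rand index of two equal-length binary frame labelings.

    Closed form from the 2x2 confusion counts n_ij: with L frames and
    C(n, 2) = n(n-1)/2,

        RI = 1 + [2 sum_ij C(n_ij,2) - sum_i C(n_i.,2) - sum_j C(n_.j,2)] / C(L,2)
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("rand_index needs two equal-length 1-D series")
    L = a.size
    if L < 2:
        raise ValidationError("rand_index needs length >= 2")

    def comb2(n: np.ndarray) -> np.ndarray:
        return n * (n - 1) // 2

    n = np.zeros((2, 2), dtype=np.int64)
    for i in (0, 1):
        for j in (0, 1):
            n[i, j] = int(np.count_nonzero((a == i) & (b == j)))
    rows = n.sum(axis=1)
    cols = n.sum(axis=0)
    total = comb2(np.int64(L))
    agree_adjust = 2 * comb2(n).sum() - comb2(rows).sum() - comb2(cols).sum()
    return float(1.0 + agree_adjust / total)


def stream_metrics(
    stream_id: str,
    pred_binary: np.ndarray,
    true_binary: np.ndarray,
    fs: float = 250.0,
    hausdorff_kind: str = "averaged",
) -> RunMetrics:
    """All per-stream metrics from two aligned binary series."""
    from sprintgc.contacts import extract_segments

    pred_segs, pred_events = extract_segments(np.asarray(pred_binary), fs=fs)
    true_segs, true_events = extract_segments(np.asarray(true_binary), fs=fs)
    try:
        mean_h, med_h = hausdorff_stats(
            pred_events.all_events, true_events.all_events, kind=hausdorff_kind
        )
    except MetricUndefinedError:
        mean_h = med_h = math.nan
    precision, recall, _ = event_precision_recall(pred_segs, true_segs)
    ri = rand_index(pred_binary, true_binary)
    return RunMetrics(
        stream_id=stream_id,
        mean_hausdorff_frames=mean_h,
        median_hausdorff_frames=med_h,
        precision=precision,
        recall=recall,
        rand_index=ri,
        n_true_events=2 * len(true_segs),
        n_pred_events=2 * len(pred_segs),
        fs=fs,
    )


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    values = values[~np.isnan(values)]
    if values.size == 0:
        return math.nan, math.nan
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return float(values.mean()), sd


def aggregate(per_stream: Sequence[RunMetrics]) -> dict:
    """Dataset summary: mean +- sample SD per metric; the median Hausdorff
    aggregates as median +- MAD. Frame quantities are mirrored in ms."""
    if not per_stream:
        raise ValidationError("aggregate needs at least one stream")
    fs = per_stream[0].fs
    mh = np.array([m.mean_hausdorff_frames for m in per_stream], dtype=float)
    dh = np.array([m.median_hausdorff_frames for m in per_stream], dtype=float)
    prec = np.array([m.precision for m in per_stream], dtype=float)
    rec = np.array([m.recall for m in per_stream], dtype=float)
    ri = np.array([m.rand_index for m in per_stream], dtype=float)

    mean_h, sd_h = _mean_sd(mh)
    dh_clean = dh[~np.isnan(dh)]
    med_h = float(np.median(dh_clean)) if dh_clean.size else math.nan
    mad_h = float(np.median(np.abs(dh_clean - med_h))) if dh_clean.size else math.nan
    frames_to_ms = 1000.0 / fs
    out = {
        "n_streams": len(per_stream),
        "mean_hausdorff_frames": (mean_h, sd_h),
        "mean_hausdorff_ms": (mean_h * frames_to_ms, sd_h * frames_to_ms),
        "median_hausdorff_frames": (med_h, mad_h),
        "median_hausdorff_ms": (med_h * frames_to_ms, mad_h * frames_to_ms),
        "precision": _mean_sd(prec),
        "recall": _mean_sd(rec),
        "rand_index": _mean_sd(ri),
    }
    return out


def metrics_table(per_stream: Sequence[RunMetrics]):
    """Per-stream metric table as a DataFrame (frames and ms side by side)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "stream_id": m.stream_id,
                "mean_hausdorff_frames": m.mean_hausdorff_frames,
                "mean_hausdorff_ms": m.mean_hausdorff_ms,
                "median_hausdorff_frames": m.median_hausdorff_frames,
                "median_hausdorff_ms": m.median_hausdorff_ms,
                "precision": m.precision,
                "recall": m.recall,
                "rand_index": m.rand_index,
                "n_true_events": m.n_true_events,
                "n_pred_events": m.n_pred_events,
            }
            for m in per_stream
        ]
    )
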