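"""From per-frame probabilities to ground contacts.

A ground contact (GC) is a maximal run of 1s in a binary per-frame series:
it starts at the initial contact (IC, the 0->1 transition frame) and ends
at the terminal contact (TC, the first flight frame after the contact, i.e.
the 1->0 transition position), so contacts are half-open intervals
[ic, tc) and duration = tc - ic frames. Model probabilities are binarized
at 0.5; predicted contacts shorter than 12 frames (48 ms at 250 Hz --
roughly half the shortest elite sprint contact) are physiologically
impossible and removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np

from sprintgc.errors import ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from sprintgc.inception_net import GroundContactNet
    from sprintgc.study_io import ImuStream

#: default binarization threshold on model probabilities
THRESHOLD = 0.5
#: contacts shorter than this many frames are removed in postprocessing
MIN_CONTACT_FRAMES = 12


@dataclass(frozen=True)
class ContactSegment:
    """One ground contact as a half-open frame interval [ic, tc)."""

    ic: int
    tc: int
    fs: float = 250.0
    open_ended: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.ic < self.tc):
            raise ValidationError(f"invalid segment [{self.ic}, {self.tc})")

    @property
    def duration_frames(self) -> int:
        return self.tc - self.ic

    @property
    def duration_ms(self) -> float:
        return self.duration_frames * 1000.0 / self.fs

    def overlaps(self, other: "ContactSegment") -> bool:
        return self.ic < other.tc and other.ic < self.tc


@dataclass(frozen=True)
class EventSet:
    """Sorted IC and TC transition indices of one stream."""

    ic_indices: np.ndarray
    tc_indices: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "ic_indices", np.asarray(self.ic_indices, dtype=np.int64))
        object.__setattr__(self, "tc_indices", np.asarray(self.tc_indices, dtype=np.int64))
        if self.ic_indices.size != self.tc_indices.size:
            raise ValidationError("IC and TC counts differ")
        if self.ic_indices.size:
            if not (self.tc_indices > self.ic_indices).all():
                raise ValidationError("each TC must follow its IC")
            if (self.ic_indices[1:] < self.tc_indices[:-1]).any():
                raise ValidationError("contacts must not overlap")

    @property
    def all_events(self) -> np.ndarray:
        """IC and TC indices pooled and sorted (the transition train)."""
        return np.sort(np.concatenate([self.ic_indices, self.tc_indices]))

    def __len__(self) -> int:
        return int(self.ic_indices.size)


def _check_binary(b: np.ndarray) -> np.ndarray:
    b = np.asarray(b)
    if b.size and not np.isin(np.unique(b), (0, 1)).all():
        raise ValidationError("series must be binary 0/1")
    return b.astype(np.int8)


def binarize(probs: np.ndarray, threshold: float = THRESHOLD) -> np.ndarray:
    """Threshold probabilities: values >= threshold map to 1, below to 0."""
    probs = np.asarray(probs, dtype=float)
    if probs.size and (np.nanmin(probs) < 0 or np.nanmax(probs) > 1):
        raise ValidationError("probabilities must lie in [0, 1]")
    return (probs >= threshold).astype(np.int8)


def _runs_of_ones(b: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) intervals of maximal 1-runs."""
    if b.size == 0:
        return []
    padded = np.concatenate([[0], b, [0]])
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def remove_short_contacts(b: np.ndarray, min_frames: int = MIN_CONTACT_FRAMES) -> np.ndarray:
    """Zero out maximal 1-runs strictly shorter than ``min_frames``.

    Runs of exactly ``min_frames`` are kept; flight (0-runs) is never
    modified. Idempotent.
    """
    b = _check_binary(b)
    out = b.copy()
    for start, end in _runs_of_ones(b):
        if end - start < min_frames:
            out[start:end] = 0
    return out


def extract_segments(
    b: np.ndarray, fs: float = 250.0
) -> tuple[list[ContactSegment], EventSet]:
    """Maximal 1-runs as ContactSegments plus their IC/TC transition train.

    A run touching either stream boundary is flagged ``open_ended`` (its
    true start or end lies outside the recording) and should be excluded
    from duration statistics.
    """
    b = _check_binary(b)
    segments = []
    for start, end in _runs_of_ones(b):
        open_ended = start == 0 or end == b.size
        segments.append(ContactSegment(start, end, fs=fs, open_ended=open_ended))
    events = EventSet(
        np.array([s.ic for s in segments], dtype=np.int64),
        np.array([s.tc for s in segments], dtype=np.int64),
    )
    return segments, events


@dataclass
class PredictionResult:
    """End-to-end detection output for one stream."""

    probs: np.ndarray
    binary_raw: np.ndarray
    binary: np.ndarray
    segments_raw: list[ContactSegment]
    segments: list[ContactSegment]
    events: EventSet
    fs: float = 250.0


def predict_contacts(
    model: "GroundContactNet",
    stream: "ImuStream",
    T: int,
    stride: int,
    threshold: float = THRESHOLD,
    min_frames: int = MIN_CONTACT_FRAMES,
    batch_size: int = 50,
) -> PredictionResult:
    """Full detection path for one stream.

    Stages, in order: per-run min-max scaling, fixed-length window slicing,
    network forward pass, overlap-average reassembly (frames covered by no
    complete window reset to 0), thresholding, short-segment removal,
    segment/event extraction. Both raw and postprocessed binarizations are
    retained.
    """
    from sprintgc import windowing

    if len(stream) < T:
        raise ValidationError(
            f"stream length {len(stream)} < window {T}; use a smaller window"
        )
    scaled = windowing.scale_minmax(stream)
    ws = windowing.slice_windows(scaled, None, T, stride)
    probs_w = np.empty((ws.n_windows, T), dtype=np.float32)
    for i in range(0, ws.n_windows, batch_size):
        probs_w[i : i + batch_size] = model.predict_proba(ws.X[i : i + batch_size])
    probs = windowing.reassemble(probs_w, ws.starts, ws.source_length)
    binary_raw = binarize(probs, threshold)
    binary = remove_short_contacts(binary_raw, min_frames)
    segments_raw, _ = extract_segments(binary_raw, fs=stream.fs)
    segments, events = extract_segments(binary, fs=stream.fs)
    return PredictionResult(
        probs=probs,
        binary_raw=binary_raw,
        binary=binary,
        segments_raw=segments_raw,
        segments=segments,
        events=events,
        fs=stream.fs,
    )


def contact_table(
    segments_by_stream: dict[str, Sequence[ContactSegment]]
):
    """Flat per-contact table: stream_id, step_index, ic, tc, duration_ms."""
    import pandas as pd

    rows = []
    for sid, segs in segments_by_stream.items():
        for step, s in enumerate(segs, start=1):
            rows.append(
                {
                    "stream_id": sid,
                    "step_index": step,
                    "ic_frame": s.ic,
                    "tc_frame": s.tc,
                    "duration_ms": s.duration_ms,
                    "open_ended": s.open_ended,
                }
            )
    return pd.DataFrame(rows)
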