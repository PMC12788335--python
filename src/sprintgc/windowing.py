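"""Per-run scaling, sliding-window slicing and overlap-average reassembly.

Runs have different lengths, so the network consumes fixed-length windows
of T frames cut with a stride; incomplete windows at the end of a run are
discarded. Features are min-max scaled to [-1.5, 1.5] per channel per run
before slicing -- touchdown peak magnitudes vary strongly across athletes,
steps and legs, and the per-run scale removes that variation (and any
dependence on physical units). For evaluation, per-window probabilities
are reassembled into a continuous series by averaging all windows covering
each frame; frames covered by no complete window are reset to 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from sprintgc.errors import ValidationError
from sprintgc.study_io import ImuStream, LabelStream

SCALE_LO = -1.5
SCALE_HI = 1.5


@dataclass
class ScaledStream:
    """A (2, L) feature array scaled to [-1.5, 1.5] with scale provenance."""

    channels: np.ndarray
    scale_params: list[tuple[float, float]]
    fs: float = 250.0
    stream_id: str = ""

    def __len__(self) -> int:
        return self.channels.shape[1]


@dataclass
class WindowSet:
    """Sliced tensors X in R^{N x 2 x T}, Y in {0,1}^{N x T} plus bookkeeping.

    ``starts`` are the window start frames in the source stream;
    ``stream_ids`` routes each window back to its source when several
    streams are concatenated.
    """

    X: np.ndarray
    Y: np.ndarray | None
    starts: np.ndarray
    T: int
    stride: int
    source_length: int
    stream_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))

    def __post_init__(self) -> None:
        if self.X.ndim != 3:
            raise ValidationError(f"X must be (N, C, T), got {self.X.shape}")
        if self.Y is not None and self.Y.shape != (self.X.shape[0], self.T):
            raise ValidationError("Y shape inconsistent with X")
        if self.X.shape[0] != self.starts.size:
            raise ValidationError("starts length inconsistent with X")

    @property
    def n_windows(self) -> int:
        return self.X.shape[0]


def scale_minmax(s: ImuStream | np.ndarray, stream_id: str = "") -> ScaledStream:
    """Min-max scale each channel independently to [-1.5, 1.5].

    x -> -1.5 + 3 (x - min) / (max - min); a degenerate constant channel
    maps to all-zeros (the midpoint). Idempotent up to float tolerance.
    """
    if isinstance(s, ImuStream):
        channels = s.channels
        fs = s.fs
        stream_id = stream_id or "_".join(s.key)
    else:
        channels = np.asarray(s, dtype=float)
        if channels.ndim == 1:
            channels = channels[None, :]
        fs = 250.0
    if channels.size == 0:
        raise ValidationError("cannot scale an empty stream")
    if np.isnan(channels).any():
        raise ValidationError("stream contains NaN")
    out = np.empty_like(channels, dtype=np.float32)
    params = []
    for c in range(channels.shape[0]):
        lo = float(channels[c].min())
        hi = float(channels[c].max())
        params.append((lo, hi))
        if hi == lo:
            out[c] = 0.0
        else:
            out[c] = SCALE_LO + (SCALE_HI - SCALE_LO) * (channels[c] - lo) / (hi - lo)
    return ScaledStream(out, params, fs=fs, stream_id=stream_id)


def window_starts(length: int, T: int, stride: int) -> np.ndarray:
    """Start frames 0, stride, 2*stride, ... while start + T <= length."""
    if length < T:
        return np.array([], dtype=np.int64)
    return np.arange(0, length - T + 1, stride, dtype=np.int64)


def slice_windows(
    features: ScaledStream,
    labels: LabelStream | None,
    T: int,
    stride: int,
) -> WindowSet:
    """Cut fixed-length windows of T frames every ``stride`` frames.

    Windows that would extend past the end of the stream are discarded, so
    N = floor((L - T) / stride) + 1. Stride >= T (non-overlapping gaps) is
    rejected as an invalid combination.
    """
    if not 0 < stride < T:
        raise ValidationError(f"need 0 < stride < T, got stride={stride}, T={T}")
    L = len(features)
    if labels is not None and len(labels) != L:
        raise ValidationError("labels and features lengths differ")
    starts = window_starts(L, T, stride)
    if starts.size == 0:
        warnings.warn(
            f"stream of length {L} shorter than window {T}: empty WindowSet",
            stacklevel=2,
        )
    C = features.channels.shape[0]
    X = np.empty((starts.size, C, T), dtype=np.float32)
    Y = np.empty((starts.size, T), dtype=np.float32) if labels is not None else None
    for i, st in enumerate(starts):
        X[i] = features.channels[:, st : st + T]
        if Y is not None:
            Y[i] = labels.values[st : st + T]
    sids = np.array([features.stream_id] * starts.size, dtype=object)
    return WindowSet(X, Y, starts, T, stride, L, stream_ids=sids)


def reassemble(
    probs_per_window: np.ndarray,
    starts: np.ndarray,
    source_length: int,
) -> np.ndarray:
    """Average overlapping window predictions back into one series.

    Frame t covered by k >= 1 windows receives the arithmetic mean of the
    k predictions at t; frames covered by no complete window (the tail
    shorter than one window, or everything if no window fits) are 0.
    """
    probs_per_window = np.asarray(probs_per_window, dtype=float)
    starts = np.asarray(starts, dtype=np.int64)
    if probs_per_window.ndim != 2 or probs_per_window.shape[0] != starts.size:
        raise ValidationError("window predictions inconsistent with starts")
    T = probs_per_window.shape[1] if probs_per_window.size else 0
    if starts.size and starts.max() + T > source_length:
        raise ValidationError("window extends past source_length")
    acc = np.zeros(source_length)
    cnt = np.zeros(source_length)
    for i, st in enumerate(starts):
        acc[st : st + T] += probs_per_window[i]
        cnt[st : st + T] += 1
    out = np.zeros(source_length)
    covered = cnt > 0
    out[covered] = acc[covered] / cnt[covered]
    return out


def concat_window_sets(sets: Sequence[WindowSet]) -> WindowSet:
    """Concatenate window sets from several streams, keeping provenance."""
    sets = [s for s in sets if s.n_windows > 0]
    if not sets:
        return WindowSet(
            np.empty((0, 2, 1), dtype=np.float32), None,
            np.array([], dtype=np.int64), 1, 1, 0,
        )
    T, stride = sets[0].T, sets[0].stride
    for s in sets:
        if s.T != T or s.stride != stride:
            raise ValidationError("cannot concatenate window sets with mixed T/stride")
    has_y = all(s.Y is not None for s in sets)
    return WindowSet(
        X=np.concatenate([s.X for s in sets]),
        Y=np.concatenate([s.Y for s in sets]) if has_y else None,
        starts=np.concatenate([s.starts for s in sets]),
        T=T,
        stride=stride,
        source_length=max(s.source_length for s in sets),
        stream_ids=np.concatenate([s.stream_ids for s in sets]),
    )


@dataclass
class DatasetBundle:
    """Concatenated windows of many streams with per-stream routing."""

    windows: WindowSet
    source_lengths: dict[str, int]
    fs: float

    @property
    def X(self) -> np.ndarray:
        return self.windows.X

    @property
    def Y(self) -> np.ndarray | None:
        return self.windows.Y

    @property
    def n_windows(self) -> int:
        return self.windows.n_windows

    def stream_index(self, stream_id: str) -> np.ndarray:
        return np.flatnonzero(self.windows.stream_ids == stream_id)

    def reassemble_stream(self, probs_all: np.ndarray, stream_id: str) -> np.ndarray:
        """Route the windows of one stream and overlap-average them."""
        idx = self.stream_index(stream_id)
        return reassemble(
            np.asarray(probs_all)[idx],
            self.windows.starts[idx],
            self.source_lengths[stream_id],
        )


def export_dataset(bundle: DatasetBundle, path) -> None:
    """Write a dataset as an array container (X, Y, starts, stream_ids,
    T, stride) plus the per-stream source lengths."""
    import json

    w = bundle.windows
    np.savez(
        path,
        X=w.X,
        Y=w.Y if w.Y is not None else np.empty((0, w.T)),
        starts=w.starts,
        stream_ids=w.stream_ids.astype(str),
        T=np.array(w.T),
        stride=np.array(w.stride),
        fs=np.array(bundle.fs),
        source_lengths=json.dumps(bundle.source_lengths),
    )


def import_dataset(path) -> DatasetBundle:
    """Read a dataset written by :func:`export_dataset`."""
    import json

    with np.load(path, allow_pickle=False) as z:
        T = int(z["T"])
        stride = int(z["stride"])
        Y = z["Y"] if z["Y"].shape[0] else None
        lengths = {k: int(v) for k, v in json.loads(str(z["source_lengths"])).items()}
        ws = WindowSet(
            X=z["X"], Y=Y, starts=z["starts"], T=T, stride=stride,
            source_length=max(lengths.values()) if lengths else 0,
            stream_ids=z["stream_ids"].astype(object),
        )
        return DatasetBundle(windows=ws, source_lengths=lengths, fs=float(z["fs"]))


def build_dataset(runs, T: int, stride: int) -> DatasetBundle:
    """Scale, slice and concatenate a collection of runs.

    ``runs`` is an iterable of RunRecord-like objects exposing ``imu``,
    ``labels`` and ``stream_id``. Scaling is per run, slicing per stream;
    windows are concatenated with provenance so predictions can be routed
    back. Mixed sampling rates are rejected.
    """
    runs = list(runs)
    if not runs:
        return DatasetBundle(
            windows=concat_window_sets([]), source_lengths={}, fs=250.0
        )
    fs = runs[0].imu.fs
    sets, lengths = [], {}
    for r in runs:
        if r.imu.fs != fs:
            raise ValidationError(
                f"mixed sampling rates: {r.imu.fs} vs {fs} in one dataset"
            )
        sid = r.stream_id
        if sid in lengths:
            raise ValidationError(f"duplicate stream_id {sid!r}")
        scaled = scale_minmax(r.imu, stream_id=sid)
        sets.append(slice_windows(scaled, r.labels, T, stride))
        lengths[sid] = len(r.imu)
    return DatasetBundle(windows=concat_window_sets(sets), source_lengths=lengths, fs=fs)
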