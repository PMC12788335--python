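"""Stream containers, resultant computation, resampling and synchronization.

Raw recordings are tri-axial accelerometer + gyroscope series from a
shank-mounted IMU (typically 1125 Hz). The working representation is a pair
of nonnegative resultant channels -- the Euclidean norm of the three axis
components per frame -- resampled to 250 Hz, aligned with a binary
ground-contact label series (1 = contact, 0 = flight) derived from
high-speed video. Alignment between the two acquisition chains is recovered
by cross-correlating impulse trains built from candidate contact events.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _sig

from sprintgc.errors import SynchronizationError, ValidationError

logger = logging.getLogger(__name__)

TRAIN = "TRAIN"
VAL = "VAL"
TEST = "TEST"

_LEGS = ("left", "right")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class TriaxialRecord:
    """Raw six-channel IMU record: (3, L) accelerometer and gyroscope arrays.

    Units are arbitrary; downstream per-run min-max scaling removes any
    dependence on them.
    """

    accel_xyz: np.ndarray
    gyro_xyz: np.ndarray
    fs: float = 1125.0

    def __post_init__(self) -> None:
        self.accel_xyz = np.asarray(self.accel_xyz, dtype=float)
        self.gyro_xyz = np.asarray(self.gyro_xyz, dtype=float)
        for name, arr in (("accel_xyz", self.accel_xyz), ("gyro_xyz", self.gyro_xyz)):
            if arr.ndim != 2 or arr.shape[0] != 3:
                raise ValidationError(f"{name} must have shape (3, L), got {arr.shape}")
        if self.accel_xyz.shape[1] != self.gyro_xyz.shape[1]:
            raise ValidationError(
                "accel_xyz and gyro_xyz lengths differ: "
                f"{self.accel_xyz.shape[1]} vs {self.gyro_xyz.shape[1]}"
            )
        if self.fs <= 0:
            raise ValidationError("fs must be positive")

    def __len__(self) -> int:
        return self.accel_xyz.shape[1]


@dataclass
class ImuStream:
    """One leg's two resultant channels with identity and sampling rate."""

    a_res: np.ndarray
    w_res: np.ndarray
    fs: float = 250.0
    athlete_id: str = ""
    run_id: str = ""
    leg: str = "left"

    def __post_init__(self) -> None:
        self.a_res = np.asarray(self.a_res, dtype=float)
        self.w_res = np.asarray(self.w_res, dtype=float)
        if self.a_res.ndim != 1 or self.w_res.ndim != 1:
            raise ValidationError("resultant channels must be 1-D")
        if self.a_res.shape != self.w_res.shape:
            raise ValidationError(
                f"a_res and w_res lengths differ: {self.a_res.size} vs {self.w_res.size}"
            )
        if self.fs <= 0:
            raise ValidationError("fs must be positive")
        if self.leg not in _LEGS:
            raise ValidationError(f"leg must be one of {_LEGS}, got {self.leg!r}")
        for name, arr in (("a_res", self.a_res), ("w_res", self.w_res)):
            if arr.size and np.isnan(arr).any():
                raise ValidationError(f"{name} contains NaN")
            if arr.size and (arr < 0).any():
                raise ValidationError(f"{name} must be nonnegative (resultant norm)")

    def __len__(self) -> int:
        return self.a_res.size

    @property
    def channels(self) -> np.ndarray:
        """Stack as a (2, L) channel-first array (a_res first)."""
        return np.stack([self.a_res, self.w_res])

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.athlete_id, self.run_id, self.leg)


@dataclass
class LabelStream:
    """Binary per-frame ground-contact series aligned to an ImuStream."""

    values: np.ndarray
    fs: float = 250.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 1:
            raise ValidationError("label values must be 1-D")
        if arr.size and np.isnan(arr.astype(float)).any():
            raise ValidationError("label values contain NaN")
        uniq = np.unique(arr) if arr.size else np.array([])
        if uniq.size and not np.isin(uniq, (0, 1)).all():
            raise ValidationError(f"label values must be 0/1, found {uniq.tolist()}")
        self.values = arr.astype(np.int8)
        if self.fs <= 0:
            raise ValidationError("fs must be positive")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class StudyDesign:
    """Athlete x run x leg layout with exclusions and split assignment.

    ``split_rule`` maps ``(athlete_id, run_id)`` to TRAIN/VAL/TEST; legs of
    one run always share a split (the split is by athlete and run, never by
    leg).
    """

    athletes: Sequence[tuple[str, str]]
    run_ids: Sequence[str]
    legs: Sequence[str] = _LEGS
    exclusions: Sequence[tuple[str, str]] = ()
    split_rule: Mapping[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [a for a, _ in self.athletes]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate athlete ids in design")
        excl = set(self.exclusions)
        for key, split in self.split_rule.items():
            if split not in (TRAIN, VAL, TEST):
                raise ValidationError(f"unknown split {split!r} for {key}")
            if key in excl:
                raise ValidationError(f"excluded run {key} appears in split_rule")

    def combinations(self) -> list[tuple[str, str, str]]:
        """All non-excluded (athlete, run, leg) stream keys, in design order."""
        excl = set(self.exclusions)
        out = []
        for aid, _sex in self.athletes:
            for rid in self.run_ids:
                if (aid, rid) in excl:
                    continue
                for leg in self.legs:
                    out.append((aid, rid, leg))
        return out

    def split_of(self, athlete_id: str, run_id: str) -> str:
        try:
            return self.split_rule[(athlete_id, run_id)]
        except KeyError:
            raise ValidationError(
                f"({athlete_id}, {run_id}) has no split assignment"
            ) from None

    def split_keys(self, split: str) -> list[tuple[str, str, str]]:
        return [k for k in self.combinations() if self.split_of(k[0], k[1]) == split]


def paper_design() -> StudyDesign:
    """The study layout: 12 athletes (6 F, 6 M) x 3 runs x 2 legs.

    Run 3 of athlete 1 is excluded (sensor download failure), leaving 70
    athlete-run-leg streams. Athletes 2-11 contribute runs 1-2 to TRAIN and
    run 3 to VAL; athletes 1 and 12 are held out entirely as TEST.
    """
    athletes = [(f"a{i:02d}", "F" if i % 2 else "M") for i in range(1, 13)]
    run_ids = ["r1", "r2", "r3"]
    exclusions = [("a01", "r3")]
    split_rule: dict[tuple[str, str], str] = {}
    for aid, _sex in athletes:
        n = int(aid[1:])
        for rid in run_ids:
            if (aid, rid) in exclusions:
                continue
            if n in (1, 12):
                split_rule[(aid, rid)] = TEST
            else:
                split_rule[(aid, rid)] = VAL if rid == "r3" else TRAIN
    return StudyDesign(athletes, run_ids, _LEGS, exclusions, split_rule)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def compute_resultant(
    rec: TriaxialRecord,
    athlete_id: str = "",
    run_id: str = "",
    leg: str = "left",
) -> ImuStream:
    """Per-frame Euclidean norm of the tri-axial channels.

    The resultant is rotation-invariant, which removes any dependence on
    sensor mounting orientation on the shank.
    """
    a_res = np.linalg.norm(rec.accel_xyz, axis=0)
    w_res = np.linalg.norm(rec.gyro_xyz, axis=0)
    return ImuStream(a_res, w_res, fs=rec.fs, athlete_id=athlete_id, run_id=run_id, leg=leg)


def _resample_channel(x: np.ndarray, up: int, down: int, n_out: int) -> np.ndarray:
    if x.size == 0:
        return x.copy()
    y = _sig.resample_poly(x, up, down, padtype="line")
    return y[:n_out]


def resample_stream(s: ImuStream, target_fs: float) -> ImuStream:
    """Rational-ratio polyphase FIR resampling of both channels.

    1125 -> 250 Hz is the exact ratio 2/9; the anti-aliasing FIR keeps
    band-limited content below the target Nyquist. Output length is
    ``round(L * target_fs / fs)``.
    """
    if target_fs <= 0:
        raise ValidationError("target_fs must be positive")
    if target_fs > s.fs:
        logger.warning(
            "upsampling stream %s from %g Hz to %g Hz", s.key, s.fs, target_fs
        )
    frac = Fraction(target_fs / s.fs).limit_denominator(10_000)
    up, down = frac.numerator, frac.denominator
    n_out = round(len(s) * target_fs / s.fs)
    a = _resample_channel(s.a_res, up, down, n_out)
    w = _resample_channel(s.w_res, up, down, n_out)
    # FIR ringing can produce tiny negative excursions on nonnegative input
    return ImuStream(
        np.clip(a, 0.0, None), np.clip(w, 0.0, None),
        fs=target_fs, athlete_id=s.athlete_id, run_id=s.run_id, leg=s.leg,
    )


def synchronize_by_events(
    imu_events: Sequence[int],
    label_events: Sequence[int],
    max_lag: int = 100,
) -> int:
    """Integer lag aligning two candidate-event trains by cross-correlation.

    Both arguments are sorted frame indices of the same physical events seen
    by the two acquisition chains (IMU impact peaks vs video contacts). The
    events are expanded into binary impulse trains and the returned lag
    maximizes their cross-correlation over [-max_lag, +max_lag]; shifting
    the second train by the returned lag aligns it with the first. Exact
    coincidence counting keeps the peak at the true offset even when a
    minority of events carry +-1 frame labeling jitter. Ties are broken
    toward the smallest |lag| (then the negative one).
    """
    a = np.asarray(imu_events, dtype=np.int64)
    b = np.asarray(label_events, dtype=np.int64)
    if a.size == 0 or b.size == 0:
        raise ValidationError("event lists must be nonempty")
    if (np.diff(a) < 0).any() or (np.diff(b) < 0).any():
        raise ValidationError("event lists must be sorted")
    a_set = set(a.tolist())
    lags = sorted(range(-max_lag, max_lag + 1), key=lambda l: (abs(l), l))
    best_lag, best_score = 0, -1
    for lag in lags:
        score = sum(1 for e in b if e + lag in a_set)
        if score > best_score:
            best_lag, best_score = lag, score
    if best_score == 0:
        raise SynchronizationError(
            f"no event coincidences at any lag in [-{max_lag}, {max_lag}]"
        )
    return best_lag


def crop(stream: ImuStream | LabelStream, start: int, end: int):
    """Frame-window crop [start, end); returns the same stream type."""
    if isinstance(stream, ImuStream):
        return ImuStream(
            stream.a_res[start:end], stream.w_res[start:end], fs=stream.fs,
            athlete_id=stream.athlete_id, run_id=stream.run_id, leg=stream.leg,
        )
    return LabelStream(stream.values[start:end], fs=stream.fs)


# ---------------------------------------------------------------------------
# file round trips
# ---------------------------------------------------------------------------

_COLUMNS = ("time_s", "a_res", "w_res", "label")


def write_run(path: str | Path, imu: ImuStream, labels: LabelStream) -> Path:
    """Write one stream to delimited text (.csv) or an array container (.npz).

    The text format has header ``time_s,a_res,w_res,label`` with 9
    significant digits; the npz container stores named arrays plus ``fs``.
    """
    path = Path(path)
    if len(imu) != len(labels):
        raise ValidationError(
            f"imu length {len(imu)} != label length {len(labels)}"
        )
    if path.suffix == ".npz":
        np.savez(
            path,
            a_res=imu.a_res,
            w_res=imu.w_res,
            label=labels.values,
            fs=np.array(imu.fs),
        )
        return path
    t = np.arange(len(imu)) / imu.fs
    df = pd.DataFrame(
        {"time_s": t, "a_res": imu.a_res, "w_res": imu.w_res, "label": labels.values}
    )
    df.to_csv(path, index=False, float_format="%.9g")
    return path


def read_run(
    path: str | Path,
    athlete_id: str = "",
    run_id: str = "",
    leg: str = "left",
) -> tuple[ImuStream, LabelStream]:
    """Read a stream file written by :func:`write_run`, validating fields."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as z:
            for name in ("a_res", "w_res", "label"):
                if name not in z:
                    raise ValidationError(f"missing {name} in {path.name}")
            fs = float(z["fs"]) if "fs" in z else 250.0
            a, w, lab = z["a_res"], z["w_res"], z["label"]
    else:
        df = pd.read_csv(path)
        for name in _COLUMNS:
            if name not in df.columns:
                raise ValidationError(f"missing {name} in {path.name}")
        if df[list(_COLUMNS)].isna().any().any():
            bad = [c for c in _COLUMNS if df[c].isna().any()]
            raise ValidationError(f"NaN values in column(s) {bad} of {path.name}")
        a, w, lab = df["a_res"].to_numpy(), df["w_res"].to_numpy(), df["label"].to_numpy()
        if len(df) > 1:
            dt = np.diff(df["time_s"].to_numpy())
            fs = 1.0 / float(np.median(dt))
            fs = round(fs, 6)
        else:
            fs = 250.0
    if not np.isin(np.unique(lab), (0, 1)).all():
        raise ValidationError(f"label column of {path.name} is not binary")
    imu = ImuStream(a, w, fs=fs, athlete_id=athlete_id, run_id=run_id, leg=leg)
    labels = LabelStream(lab, fs=fs)
    return imu, labels


def write_manifest(path: str | Path, design: StudyDesign) -> Path:
    """Persist a study design as a delimited-text manifest."""
    path = Path(path)
    rows = []
    sex = dict(design.athletes)
    for aid, rid, leg in design.combinations():
        rows.append(
            {
                "athlete_id": aid,
                "sex": sex[aid],
                "run_id": rid,
                "leg": leg,
                "split": design.split_of(aid, rid),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_manifest(path: str | Path) -> StudyDesign:
    df = pd.read_csv(path)
    need = {"athlete_id", "sex", "run_id", "leg", "split"}
    if not need.issubset(df.columns):
        raise ValidationError(f"manifest missing columns {sorted(need - set(df.columns))}")
    athletes = list(dict.fromkeys(zip(df["athlete_id"], df["sex"])))
    run_ids = sorted(set(df["run_id"]))
    legs = list(dict.fromkeys(df["leg"]))
    present = set(zip(df["athlete_id"], df["run_id"]))
    exclusions = [
        (aid, rid)
        for aid, _ in athletes
        for rid in run_ids
        if (aid, rid) not in present
    ]
    split_rule = {
        (r.athlete_id, r.run_id): r.split for r in df.itertuples()
    }
    return StudyDesign(athletes, run_ids, legs, exclusions, split_rule)
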