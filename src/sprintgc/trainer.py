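"""Training loop, early stopping and grid-search hyperparameter tuning.

Optimization is Adam on the mean per-timestep binary cross-entropy over
shuffled minibatches (default batch 50, at most 30 epochs). Early stopping
watches the validation BCE: training stops once it has failed to improve
strictly for five consecutive epochs, and the weights of the best
validation epoch are restored.

Tuning enumerates the study's hyperparameter grid -- window size in
{25, 50, 75, 100, 150, 200}, stride in {5, 10, 15, 20, 25, 30}, block
count in {6, 9, 12, 15, 18, 21}, learning rate in {0.01, 0.001, 0.0001},
combinations with stride >= window skipped (612 of 648 remain) -- and
ranks combinations by the mean Hausdorff distance of postprocessed
validation predictions, computed per stream then averaged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np

from sprintgc.contacts import predict_contacts
from sprintgc.errors import TrainingDivergedError, ValidationError
from sprintgc.inception_net import GroundContactNet, ModelSpec
from sprintgc.metrics import stream_metrics
from sprintgc.nn import bce_with_logits
from sprintgc.windowing import DatasetBundle, WindowSet, build_dataset


@dataclass(frozen=True)
class TrainConfig:
    max_epochs: int = 30
    batch_size: int = 50
    patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.patience < self.max_epochs:
            raise ValidationError("need 0 < patience < max_epochs")
        if self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")


@dataclass
class TrainResult:
    train_loss: list[float]
    val_loss: list[float]
    best_epoch: int
    epochs_run: int
    stopped_early: bool


def evaluate_bce(model: GroundContactNet, ws: WindowSet, batch_size: int = 50) -> float:
    """Mean per-timestep BCE over a window set, eval mode."""
    was_training = model.training
    model.eval()
    total, count = 0.0, 0
    for i in range(0, ws.n_windows, batch_size):
        z = model.forward_logits(ws.X[i : i + batch_size])
        y = ws.Y[i : i + batch_size]
        loss, _ = bce_with_logits(z, y)
        total += loss * z.size
        count += z.size
    model.training = was_training
    return total / count


def early_stopping_trace(val_losses: Sequence[float], patience: int) -> tuple[int, int]:
    """(epochs_run, best_epoch), 1-based, under the strict-improvement rule.

    Training stops after the epoch at which the validation loss has failed
    to beat the best value seen so far for ``patience`` consecutive epochs.
    """
    best = math.inf
    best_epoch = 0
    bad = 0
    for epoch, loss in enumerate(val_losses, start=1):
        if loss < best:
            best, best_epoch, bad = loss, epoch, 0
        else:
            bad += 1
            if bad >= patience:
                return epoch, best_epoch
    return len(val_losses), best_epoch


def train(
    model: GroundContactNet,
    train_set: WindowSet | DatasetBundle,
    val_set: WindowSet | DatasetBundle,
    cfg: TrainConfig = TrainConfig(),
) -> TrainResult:
    """Optimize ``model`` in place; restores the best-validation weights."""
    tr = train_set.windows if isinstance(train_set, DatasetBundle) else train_set
    va = val_set.windows if isinstance(val_set, DatasetBundle) else val_set
    if tr.n_windows == 0 or va.n_windows == 0:
        raise ValidationError("train and validation sets must be nonempty")
    if tr.Y is None or va.Y is None:
        raise ValidationError("training requires label tensors")
    if tr.T != va.T:
        raise ValidationError("train and validation window sizes differ")

    rng = np.random.default_rng(cfg.seed)
    opt = model.make_optimizer()
    history_train: list[float] = []
    history_val: list[float] = []
    best_val = math.inf
    best_epoch = 0
    best_state = model.state_dict()
    bad = 0
    stopped_early = False

    for epoch in range(1, cfg.max_epochs + 1):
        model.train()
        order = rng.permutation(tr.n_windows)
        epoch_loss, n_seen = 0.0, 0
        for i in range(0, tr.n_windows, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            X, Y = tr.X[idx], tr.Y[idx]
            opt.zero_grad()
            z = model.forward_logits(X)
            loss, dz = bce_with_logits(z, Y)
            if not math.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite training loss at epoch {epoch}"
                )
            model.backward(dz)
            opt.step()
            epoch_loss += loss * len(idx)
            n_seen += len(idx)
        history_train.append(epoch_loss / n_seen)

        val_loss = evaluate_bce(model, va, cfg.batch_size)
        if not math.isfinite(val_loss):
            raise TrainingDivergedError(f"non-finite validation loss at epoch {epoch}")
        history_val.append(val_loss)

        if val_loss < best_val:
            best_val, best_epoch, bad = val_loss, epoch, 0
            best_state = model.state_dict()
        else:
            bad += 1
            if bad >= cfg.patience:
                stopped_early = True
                break

    model.load_state_dict(best_state)
    model.eval()
    return TrainResult(
        train_loss=history_train,
        val_loss=history_val,
        best_epoch=best_epoch,
        epochs_run=len(history_val),
        stopped_early=stopped_early,
    )


# ---------------------------------------------------------------------------
# hyperparameter grid
# ---------------------------------------------------------------------------


class HyperCombo(NamedTuple):
    window: int
    stride: int
    n_blocks: int
    lr: float


@dataclass(frozen=True)
class TuneGrid:
    windows: tuple[int, ...] = (25, 50, 75, 100, 150, 200)
    strides: tuple[int, ...] = (5, 10, 15, 20, 25, 30)
    n_blocks: tuple[int, ...] = (6, 9, 12, 15, 18, 21)
    lrs: tuple[float, ...] = (0.01, 0.001, 0.0001)


def enumerate_grid(grid: TuneGrid = TuneGrid()) -> list[HyperCombo]:
    """Cartesian product minus stride >= window, in deterministic order."""
    combos = []
    for w in grid.windows:
        for s in grid.strides:
            if s >= w:
                continue
            for b in grid.n_blocks:
                for lr in grid.lrs:
                    combos.append(HyperCombo(w, s, b, lr))
    return combos


@dataclass
class TuneEntry:
    combo: HyperCombo
    objective: float
    epochs_run: int
    best_epoch: int


@dataclass
class TuneResult:
    best: HyperCombo
    leaderboard: list[TuneEntry]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "window": e.combo.window,
                    "stride": e.combo.stride,
                    "n_blocks": e.combo.n_blocks,
                    "lr": e.combo.lr,
                    "objective": e.objective,
                    "epochs_run": e.epochs_run,
                    "best_epoch": e.best_epoch,
                }
                for e in self.leaderboard
            ]
        )


def val_mean_hausdorff(
    model: GroundContactNet,
    val_runs: Sequence,
    T: int,
    stride: int,
    postprocess: bool = True,
) -> float:
    """Mean over VAL streams of the per-stream mean transition distance.

    Computed on postprocessed predictions: short spurious spikes are
    trivially removable and should not steer model selection.
    """
    values = []
    for run in val_runs:
        pred = predict_contacts(model, run.imu, T, stride)
        binary = pred.binary if postprocess else pred.binary_raw
        m = stream_metrics(run.stream_id, binary, run.labels.values, fs=run.imu.fs)
        values.append(m.mean_hausdorff_frames)
    arr = np.asarray(values, dtype=float)
    if arr.size == 0 or np.isnan(arr).all():
        return math.nan
    return float(np.nanmean(arr))


def tune(
    train_runs: Sequence,
    val_runs: Sequence,
    grid: TuneGrid = TuneGrid(),
    cfg: TrainConfig = TrainConfig(),
    base_spec: ModelSpec = ModelSpec(),
) -> TuneResult:
    """Exhaustive in-process grid search against validation mean Hausdorff.

    Each combination gets a deterministic seed derived from the master
    training seed and its grid index. Ties in the objective prefer fewer
    blocks, then larger stride (the cheaper model).
    """
    combos = enumerate_grid(grid)
    if not combos:
        raise ValidationError("empty hyperparameter grid")
    entries: list[TuneEntry] = []
    failures: list[str] = []
    for idx, combo in enumerate(combos):
        try:
            spec = replace(
                base_spec, n_blocks=combo.n_blocks, lr=combo.lr,
                seed=(cfg.seed * 1009 + idx) % (2**31),
            )
            model = GroundContactNet(spec)
            train_ds = build_dataset(train_runs, combo.window, combo.stride)
            val_ds = build_dataset(val_runs, combo.window, combo.stride)
            result = train(model, train_ds, val_ds, replace(cfg, seed=spec.seed))
            obj = val_mean_hausdorff(model, val_runs, combo.window, combo.stride)
            entries.append(TuneEntry(combo, obj, result.epochs_run, result.best_epoch))
        except Exception as exc:  # noqa: BLE001 - per-combination diagnostics
            failures.append(f"{combo}: {exc}")
    if not entries:
        raise RuntimeError("all grid combinations failed:\n" + "\n".join(failures))
    entries.sort(
        key=lambda e: (
            e.objective if math.isfinite(e.objective) else math.inf,
            e.combo.n_blocks,
            -e.combo.stride,
        )
    )
    return TuneResult(best=entries[0].combo, leaderboard=entries)
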