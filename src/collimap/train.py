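"""Training and evaluation harness for the phase-map regressor.

Optimisation follows the study protocol: Adam at an initial learning
rate of 1e-3, reduced by a factor of 0.75 after 3 epochs without
validation-loss improvement, mini-batches of 4, horizontal (left-right)
flipping as the only augmentation, and selection of the checkpoint with
the lowest validation BerHu loss.  "No improvement" means the validation
loss failing to drop by more than 1e-6 absolute.

A dataset here is a list of :class:`TrainingSample` — preprocessed input
series (normalised to [0, 1]) with targets on the [-0.9, 0.9] scale.
One master seed fans out to data shuffling, augmentation and weight
initialisation.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import BrainMask, CollateralMapSet, PerfusionSeries, SubjectRecord, PHASE_NAMES
from .metrics import LossConfig, METRIC_NAMES, berhu_loss_grad, evaluate_subject, r_squared
from .model import ModelConfig, MoReT3D
from .nn import Adam, ReduceLROnPlateau, no_grad
from .preprocess import PreprocessConfig, preprocess_series, preprocess_targets

__all__ = [
    "TrainConfig",
    "TrainState",
    "TrainingSample",
    "augment_flip",
    "train",
    "predict",
    "evaluate_cohort",
    "aggregate_report",
    "prepare_samples",
]


@dataclass(frozen=True)
class TrainConfig:
    lr0: float = 1e-3
    plateau_factor: float = 0.75
    plateau_patience: int = 3
    min_delta: float = 1e-6
    batch_size: int = 4
    max_epochs: int = 300
    flip_prob: float = 0.5
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)
    early_stop_val_r2: float | None = None  # optional stop once reached

    def __post_init__(self) -> None:
        if not 0.0 < self.plateau_factor < 1.0:
            raise ValueError("plateau_factor must lie in (0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class TrainState:
    epoch: int = 0
    current_lr: float = 0.0
    best_val_loss: float = np.inf
    best_epoch: int = -1
    best_params: list[np.ndarray] | None = None
    history: list[dict] = field(default_factory=list)

    def restore_best(self, model: MoReT3D) -> None:
        """Load the minimum-validation-loss weights into the model."""
        if self.best_params is None:
            raise ValueError("no best checkpoint recorded")
        for p, data in zip(model.parameters(), self.best_params):
            p.data[...] = data


@dataclass
class TrainingSample:
    """One preprocessed subject ready for the network."""

    x: np.ndarray          # (T, D, H, W) float32, [0, 1]
    y: np.ndarray          # (5, D, H, W) float32, [-0.9, 0.9]
    mask: np.ndarray       # (D, H, W) bool
    subject_id: str = ""


def augment_flip(x: np.ndarray, y: np.ndarray, rng: np.random.Generator,
                 flip_prob: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Jointly flip input and targets along the left-right (x) axis.

    Input and targets are always flipped together: flipping only one
    would break the voxel correspondence the regression relies on.
    Applying the flip twice is the identity.
    """
    if rng.random() < flip_prob:
        return x[..., ::-1].copy(), y[..., ::-1].copy()
    return x, y


def prepare_samples(records: list[SubjectRecord],
                    cfg: PreprocessConfig | None = None) -> list[TrainingSample]:
    """Preprocess cohort records into network-ready samples.

    Series: brain mask -> [0, 1] normalisation -> centre crop.  Targets:
    [0, 1] scaling with clipping -> median filter -> [-0.9, 0.9] -> crop.
    """
    if cfg is None:
        # crop is a no-op when the grid is already at (or below) 224
        cfg = PreprocessConfig()
    out = []
    for rec in records:
        if rec.targets is None:
            raise ValueError(f"subject {rec.subject_id} has no targets")
        size = min(cfg.crop_size, rec.series.spatial[0], rec.series.spatial[1])
        ccfg = PreprocessConfig(
            mask_threshold=cfg.mask_threshold, morph_radius=cfg.morph_radius,
            median_kernel=cfg.median_kernel, crop_size=size,
            target_low=cfg.target_low, target_high=cfg.target_high)
        series, mask = preprocess_series(rec.series, ccfg, mask=rec.mask)
        targets = preprocess_targets(rec.targets, ccfg)
        out.append(TrainingSample(
            x=series.data.astype(np.float32), y=targets.maps.astype(np.float32),
            mask=mask.mask, subject_id=rec.subject_id))
    return out


def _val_metrics(model: MoReT3D, samples: list[TrainingSample],
                 loss_cfg: LossConfig, want_r2: bool) -> tuple[float, float]:
    losses, r2s = [], []
    for s in samples:
        pred = model.predict_array(s.x)
        loss, _ = berhu_loss_grad(pred, s.y, loss_cfg)
        losses.append(loss)
        if want_r2:
            r2s.append(np.mean([
                r_squared(s.y[i][s.mask], pred[i][s.mask]) for i in range(5)]))
    return float(np.mean(losses)), (float(np.mean(r2s)) if want_r2 else np.nan)


def train(model: MoReT3D, train_set: list[TrainingSample],
          val_set: list[TrainingSample],
          cfg: TrainConfig = TrainConfig()) -> TrainState:
    """Optimise the model; returns the state with the best checkpoint.

    Aborts with a diagnostic if the loss becomes non-finite.
    """
    if not train_set or not val_set:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr0)
    sched = ReduceLROnPlateau(opt, factor=cfg.plateau_factor,
                              patience=cfg.plateau_patience,
                              min_delta=cfg.min_delta)
    state = TrainState(current_lr=cfg.lr0)
    n = len(train_set)
    for epoch in range(cfg.max_epochs):
        model.train(True)
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xs, ys = [], []
            for i in idx:
                s = train_set[i]
                x, y = augment_flip(s.x, s.y, rng, cfg.flip_prob)
                xs.append(x)
                ys.append(y)
            xb = np.stack(xs)
            yb = np.stack(ys)
            out = model.forward(xb)
            loss, grad = berhu_loss_grad(out, yb, cfg.loss)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: loss = {loss}")
            model.zero_grad()
            model.backward(grad)
            opt.step()
            epoch_losses.append(loss)
        want_r2 = cfg.early_stop_val_r2 is not None
        val_loss, val_r2 = _val_metrics(model, val_set, cfg.loss, want_r2)
        if not np.isfinite(val_loss):
            raise FloatingPointError(
                f"validation loss non-finite at epoch {epoch}")
        if val_loss < state.best_val_loss:
            state.best_val_loss = val_loss
            state.best_epoch = epoch
            state.best_params = [p.data.copy() for p in model.parameters()]
        sched.step(val_loss)
        state.epoch = epoch + 1
        state.current_lr = opt.lr
        state.history.append({
            "epoch": epoch, "train_loss": float(np.mean(epoch_losses)),
            "val_loss": val_loss, "val_r2": val_r2, "lr": opt.lr})
        if want_r2 and val_r2 >= cfg.early_stop_val_r2:
            break
    return state


def predict(model: MoReT3D, series: PerfusionSeries) -> CollateralMapSet:
    """Single forward pass; output lies in (-1, 1) by the Tanh head and is
    interpreted on the [-0.9, 0.9] target scale."""
    out = model.predict_array(series.data.astype(np.float32))
    return CollateralMapSet(maps=np.asarray(out, dtype=np.float64),
                            value_range="raw")


def evaluate_cohort(model: MoReT3D, records: list[SubjectRecord],
                    samples: list[TrainingSample] | None = None) -> pd.DataFrame:
    """Per-subject, per-phase metrics as a tidy DataFrame.

    ``samples`` may carry pre-computed network inputs (in record order);
    otherwise records are preprocessed here.
    """
    if samples is None:
        samples = prepare_samples(records)
    rows = []
    for rec, s in zip(records, samples):
        pred = model.predict_array(s.x)
        pred_set = CollateralMapSet(maps=np.asarray(pred, np.float64), value_range="raw")
        truth_set = CollateralMapSet(maps=np.asarray(s.y, np.float64), value_range="signed")
        res = evaluate_subject(pred_set, truth_set, BrainMask(mask=s.mask))
        for phase, metrics in res.items():
            for metric, value in metrics.items():
                rows.append({"subject": s.subject_id or rec.subject_id,
                             "group": rec.group, "center": rec.center,
                             "phase": phase, "metric": metric, "value": value})
    return pd.DataFrame(rows)


def aggregate_report(df: pd.DataFrame, by: str | None = None) -> pd.DataFrame:
    """Mean +/- sample SD (ddof=1) per phase and metric, optionally per
    subgroup (``by`` = "group" or "center")."""
    keys = ["metric", "phase"] + ([by] if by else [])
    agg = df.groupby(keys)["value"].agg(["mean", lambda v: v.std(ddof=1), "count"])
    agg.columns = ["mean", "sd", "n"]
    return agg.reset_index()
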