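"""BerHu regression loss and the four evaluation metrics.

The BerHu (reverse Huber) loss is L1 for residuals up to a threshold c
and scaled-quadratic ((r^2 + c^2) / 2c) beyond it; the two branches agree
at |r| = c and both have slope 1 there, so the loss is C^1 at the knot.
c = 0.2 on the [-0.9, 0.9] target scale.

Metrics — R^2, mean absolute error, Tanimoto measure (the real-valued
Jaccard similarity <y, y_hat> / (||y||^2 + ||y_hat||^2 - <y, y_hat>)) and
SSIM — are computed per phase per subject over brain-mask voxels.  SSIM
is evaluated globally (single means/variances/covariance over the masked
voxel population) with stabilisers C1 = (K1 L)^2, C2 = (K2 L)^2 where
L = 1.8 is the width of the target range; a windowed mean-SSIM variant is
available but not the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import BrainMask, CollateralMapSet, PHASE_NAMES

__all__ = [
    "LossConfig",
    "SSIMConfig",
    "berhu_loss",
    "berhu_loss_grad",
    "r_squared",
    "mae",
    "tanimoto",
    "ssim_global",
    "ssim_windowed",
    "evaluate_subject",
    "METRIC_NAMES",
]

METRIC_NAMES = ("r_squared", "mae", "ssim", "tanimoto")


@dataclass(frozen=True)
class LossConfig:
    c: float = 0.2
    reduction: str = "mean"

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("BerHu threshold c must be positive")
        if self.reduction not in ("mean", "sum"):
            raise ValueError("reduction must be 'mean' or 'sum'")


@dataclass(frozen=True)
class SSIMConfig:
    dynamic_range: float = 1.8  # width of the [-0.9, 0.9] target scale
    K1: float = 0.01
    K2: float = 0.03

    @property
    def C1(self) -> float:
        return (self.K1 * self.dynamic_range) ** 2

    @property
    def C2(self) -> float:
        return (self.K2 * self.dynamic_range) ** 2


def _residuals(y: np.ndarray, y_hat: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {y_hat.shape}")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(y_hat))):
        raise ValueError("non-finite inputs")
    return y - y_hat


def berhu_loss(y: np.ndarray, y_hat: np.ndarray,
               cfg: LossConfig = LossConfig()) -> float:
    """Elementwise reverse-Huber loss of the residuals, reduced."""
    r = np.abs(_residuals(y, y_hat))
    c = cfg.c
    vals = np.where(r <= c, r, (r * r + c * c) / (2.0 * c))
    return float(vals.mean() if cfg.reduction == "mean" else vals.sum())


def berhu_loss_grad(pred: np.ndarray, target: np.ndarray,
                    cfg: LossConfig = LossConfig()) -> tuple[float, np.ndarray]:
    """Loss and its gradient w.r.t. the prediction (for training)."""
    pred = np.asarray(pred)
    r = pred.astype(np.float64) - np.asarray(target, dtype=np.float64)
    a = np.abs(r)
    c = cfg.c
    vals = np.where(a <= c, a, (a * a + c * c) / (2.0 * c))
    grad = np.where(a <= c, np.sign(r), r / c)
    if cfg.reduction == "mean":
        return float(vals.mean()), (grad / r.size).astype(pred.dtype)
    return float(vals.sum()), grad.astype(pred.dtype)


def r_squared(y: np.ndarray, y_hat: np.ndarray) -> float:
    """1 - SS_res / SS_tot; 1 iff exact, unbounded below (not clamped)."""
    r = _residuals(y, y_hat)
    y = np.asarray(y, dtype=np.float64)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("constant ground truth: R^2 undefined")
    return 1.0 - float(np.sum(r * r)) / ss_tot


def mae(y: np.ndarray, y_hat: np.ndarray) -> float:
    return float(np.mean(np.abs(_residuals(y, y_hat))))


def tanimoto(y: np.ndarray, y_hat: np.ndarray) -> float:
    _residuals(y, y_hat)  # shape/finite checks
    y = np.asarray(y, dtype=np.float64).ravel()
    y_hat = np.asarray(y_hat, dtype=np.float64).ravel()
    dot = float(y @ y_hat)
    denom = float(y @ y) + float(y_hat @ y_hat) - dot
    if denom == 0.0:
        raise ValueError("Tanimoto undefined: both inputs are all-zero")
    return dot / denom


def ssim_global(y: np.ndarray, y_hat: np.ndarray,
                cfg: SSIMConfig = SSIMConfig()) -> float:
    """Single global SSIM statistic over the voxel population."""
    _residuals(y, y_hat)
    y = np.asarray(y, dtype=np.float64).ravel()
    y_hat = np.asarray(y_hat, dtype=np.float64).ravel()
    if y.size < 2:
        raise ValueError("need at least 2 voxels")
    mu_y, mu_p = y.mean(), y_hat.mean()
    var_y, var_p = y.var(), y_hat.var()  # population (1/n) moments
    cov = float(((y - mu_y) * (y_hat - mu_p)).mean())
    C1, C2 = cfg.C1, cfg.C2
    return float(((2 * mu_p * mu_y + C1) * (2 * cov + C2))
                 / ((mu_p ** 2 + mu_y ** 2 + C1) * (var_p + var_y + C2)))


def ssim_windowed(y: np.ndarray, y_hat: np.ndarray,
                  cfg: SSIMConfig = SSIMConfig()) -> float:
    """Windowed mean-SSIM (Gaussian weighting) over a volume; non-default."""
    from skimage.metrics import structural_similarity

    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    return float(structural_similarity(
        y, y_hat, data_range=cfg.dynamic_range, gaussian_weights=True,
        use_sample_covariance=False, K1=cfg.K1, K2=cfg.K2))


def evaluate_subject(pred: CollateralMapSet, truth: CollateralMapSet,
                     mask: BrainMask,
                     ssim_cfg: SSIMConfig = SSIMConfig()) -> dict[str, dict[str, float]]:
    """All four metrics for each of the five phases over masked voxels.

    Returns ``{phase: {metric: value}}`` — 20 numbers per subject.  Pass a
    full mask to evaluate over the whole volume instead.
    """
    if pred.maps.shape != truth.maps.shape:
        raise ValueError("prediction/truth shape mismatch")
    if mask.mask.shape != truth.maps.shape[1:]:
        raise ValueError("mask shape mismatch")
    out: dict[str, dict[str, float]] = {}
    for i, phase in enumerate(PHASE_NAMES):
        y = truth.maps[i][mask.mask]
        y_hat = pred.maps[i][mask.mask]
        out[phase] = {
            "r_squared": r_squared(y, y_hat),
            "mae": mae(y, y_hat),
            "ssim": ssim_global(y, y_hat, ssim_cfg),
            "tanimoto": tanimoto(y, y_hat),
        }
    return out
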