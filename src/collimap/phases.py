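"""Semi-automatic five-phase ground-truth generation.

The collateral status of a subject is summarised by five temporal windows
of the bolus passage — arterial (Art), capillary (Cap), early venous
(EVen), late venous (LVen) and delay (Del) — delimited by landmarks read
off the signal-time curves of two reference vessels: the middle cerebral
artery (MCA, arterial side) and the superior sagittal sinus (SSS, venous
side).  This module implements the procedure end to end:

* baseline subtraction (contrast causes a T2* signal drop, so the
  default subtraction is baseline minus frame, clipped at zero);
* temporal maximum-intensity projection over a window (the sMIP);
* ROI curve extraction;
* deterministic landmark detection with optional manual overrides,
  standing in for the expert interaction of the original procedure;
* phase partitioning and per-phase map composition (temporal maximum by
  default; mean and sum are available alternatives).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import BrainMask, CollateralMapSet, PerfusionSeries, PHASE_NAMES

__all__ = [
    "SignalTimeCurve",
    "PhaseLandmarks",
    "PhaseWindows",
    "subtract_baseline",
    "temporal_mip",
    "extract_roi_curve",
    "detect_landmarks",
    "partition_phases",
    "compose_phase_maps",
    "ground_truth_maps",
]


@dataclass
class SignalTimeCurve:
    """Mean subtracted signal over an ROI, one value per time point."""

    values: np.ndarray
    dt_seconds: float = 1.6

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("curve must be 1D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("curve contains non-finite values")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class PhaseLandmarks:
    """Discrete time indices delimiting the five phases."""

    t_arrival: int
    t_arterial_peak: int
    t_venous_peak: int
    t_plateau_start: int
    t_venous_end: int

    def validate(self, t_count: int) -> None:
        lm = (self.t_arrival, self.t_arterial_peak, self.t_venous_peak,
              self.t_plateau_start, self.t_venous_end)
        if not (0 <= self.t_arrival <= self.t_arterial_peak
                < self.t_venous_peak < self.t_plateau_start
                <= self.t_venous_end < t_count):
            raise ValueError(f"landmark ordering violated: {lm} with T={t_count}")


@dataclass(frozen=True)
class PhaseWindows:
    """Five inclusive index intervals, ordered, disjoint and contiguous."""

    windows: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.windows) != len(PHASE_NAMES):
            raise ValueError("expected exactly five windows")

    def __getitem__(self, phase: str) -> tuple[int, int]:
        return self.windows[PHASE_NAMES.index(phase)]

    def items(self):
        return zip(PHASE_NAMES, self.windows)


def subtract_baseline(series: PerfusionSeries, sign: str = "drop") -> PerfusionSeries:
    """Subtract the first (pre-contrast) frame, clipping at zero.

    ``sign="drop"`` (T2* convention) computes ``max(0, I_0 - I_t)`` so the
    bolus passage becomes a positive signal; ``sign="rise"`` computes
    ``max(0, I_t - I_0)`` for contrast-enhancing acquisitions.
    """
    base = series.data[0]
    if sign == "drop":
        sub = base[None] - series.data
    elif sign == "rise":
        sub = series.data - base[None]
    else:
        raise ValueError(f"unknown sign {sign!r}")
    return series.with_data(np.maximum(sub, 0.0))


def temporal_mip(subtracted: PerfusionSeries,
                 window: tuple[int, int]) -> np.ndarray:
    """Voxelwise maximum of the subtracted frames over an inclusive window."""
    lo, hi = int(window[0]), int(window[1])
    if lo > hi:
        raise ValueError(f"empty window [{lo}, {hi}]")
    if lo < 0 or hi >= subtracted.t_count:
        raise ValueError(f"window [{lo}, {hi}] outside [0, {subtracted.t_count - 1}]")
    return subtracted.data[lo:hi + 1].max(axis=0)


def extract_roi_curve(subtracted: PerfusionSeries, roi: BrainMask) -> SignalTimeCurve:
    """Per-time-point mean over the ROI voxels."""
    if roi.mask.shape != subtracted.data.shape[1:]:
        raise ValueError("ROI shape inconsistent with series")
    values = subtracted.data[:, roi.mask].mean(axis=1)
    return SignalTimeCurve(values=values, dt_seconds=subtracted.dt_seconds)


def _check_bolus(curve: np.ndarray, name: str) -> int:
    peak = int(np.argmax(curve))
    if curve[peak] <= 0 or peak == 0 or peak == len(curve) - 1:
        raise ValueError(f"no bolus detected in {name} curve")
    return peak


def detect_landmarks(mca: SignalTimeCurve, sss: SignalTimeCurve,
                     arrival_frac: float = 0.1, plateau_tol: float = 0.05,
                     overrides: dict[str, int] | None = None) -> PhaseLandmarks:
    """Deterministic landmark detection from the MCA and SSS curves.

    Rules: the arterial and venous peaks are the curve argmaxes; contrast
    arrival is the first index where the MCA curve exceeds
    ``arrival_frac`` of its maximum; the venous plateau starts at the
    first index after the venous peak whose forward difference falls
    below ``plateau_tol`` of the SSS maximum, and ends at the last index
    of that run of small steps (capped at T-2 so a delay phase remains).
    Any landmark may be overridden manually via ``overrides``; the
    ordering invariant is re-checked afterwards.
    """
    m = np.asarray(mca.values, dtype=float)
    s = np.asarray(sss.values, dtype=float)
    T = len(m)
    if len(s) != T:
        raise ValueError("MCA and SSS curves have different lengths")
    t_apeak = _check_bolus(m, "MCA")
    t_vpeak = _check_bolus(s, "SSS")
    if t_vpeak <= t_apeak:
        raise ValueError("venous peak does not follow the arterial peak")

    thresh = arrival_frac * m[t_apeak]
    above = np.nonzero(m >= thresh)[0]
    t_arrival = int(above[0])

    tol = plateau_tol * s[t_vpeak]
    diffs_ok = np.abs(np.diff(s)) <= tol  # step k -> |s[k+1] - s[k]|
    t_plateau = None
    for k in range(t_vpeak + 1, T - 1):
        if diffs_ok[k]:
            t_plateau = k
            break
    if t_plateau is None:
        raise ValueError("no venous plateau found after the venous peak")
    k = t_plateau
    while k < T - 1 and diffs_ok[k]:
        k += 1
    t_vend = min(k, T - 2)  # k = one past the last small step

    lm = dict(t_arrival=t_arrival, t_arterial_peak=t_apeak, t_venous_peak=t_vpeak,
              t_plateau_start=t_plateau, t_venous_end=t_vend)
    if overrides:
        unknown = set(overrides) - set(lm)
        if unknown:
            raise ValueError(f"unknown landmark override(s): {sorted(unknown)}")
        lm.update({k: int(v) for k, v in overrides.items()})
    out = PhaseLandmarks(**lm)
    out.validate(T)
    return out


def partition_phases(lm: PhaseLandmarks, T: int) -> PhaseWindows:
    """Partition [t_arrival, T-1] into the five phase windows.

    Art = [arrival, arterial peak]; Cap = (arterial peak, venous peak];
    EVen = (venous peak, plateau start]; LVen = (plateau start, venous
    end]; Del = (venous end, T-1].  The venous phase — everything after
    the venous peak up to the venous end — is split at the plateau onset
    into its early and late halves.
    """
    lm.validate(T)
    windows = (
        (lm.t_arrival, lm.t_arterial_peak),
        (lm.t_arterial_peak + 1, lm.t_venous_peak),
        (lm.t_venous_peak + 1, lm.t_plateau_start),
        (lm.t_plateau_start + 1, lm.t_venous_end),
        (lm.t_venous_end + 1, T - 1),
    )
    for name, (lo, hi) in zip(PHASE_NAMES, windows):
        if lo > hi:
            raise ValueError(f"empty {name} window [{lo}, {hi}]")
    return PhaseWindows(windows=windows)


def compose_phase_maps(subtracted: PerfusionSeries, windows: PhaseWindows,
                       statistic: str = "max") -> CollateralMapSet:
    """Per-phase map over its window: temporal max (default), mean or sum."""
    reducers = {"max": np.max, "mean": np.mean, "sum": np.sum}
    if statistic not in reducers:
        raise ValueError(f"unknown statistic {statistic!r}")
    reduce = reducers[statistic]
    maps = np.stack([
        reduce(subtracted.data[lo:hi + 1], axis=0) for _, (lo, hi) in windows.items()
    ])
    return CollateralMapSet(maps=maps, value_range="raw")


def ground_truth_maps(series: PerfusionSeries, mca_roi: BrainMask,
                      sss_roi: BrainMask, sign: str = "drop",
                      arrival_frac: float = 0.1, plateau_tol: float = 0.05,
                      statistic: str = "max",
                      overrides: dict[str, int] | None = None
                      ) -> tuple[CollateralMapSet, PhaseLandmarks, PhaseWindows]:
    """Full procedure: subtract, extract curves, detect, partition, compose."""
    sub = subtract_baseline(series, sign=sign)
    mca = extract_roi_curve(sub, mca_roi)
    sss = extract_roi_curve(sub, sss_roi)
    lm = detect_landmarks(mca, sss, arrival_frac=arrival_frac,
                          plateau_tol=plateau_tol, overrides=overrides)
    windows = partition_phases(lm, series.t_count)
    maps = compose_phase_maps(sub, windows, statistic=statistic)
    return maps, lm, windows
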