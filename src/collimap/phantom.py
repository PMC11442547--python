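"""Synthetic DSC perfusion phantom with analytic bolus dynamics.

The phantom emulates the T2* signal drop of a gadolinium bolus passing
through a brain-like volume with four tissue compartments — a middle
cerebral artery (MCA) tube, a cortical capillary ribbon, a superior
sagittal sinus (SSS) tube and background parenchyma — each following a
gamma-variate concentration curve c(t) (peak at t0 + alpha*beta).  The
venous curve additionally carries a slow recirculation ramp so the SSS
signal settles onto a plateau, which is what defines the late-venous
landmarks.  The signal model is a multiplicative drop,

    I(t) = baseline * (1 - drop_fraction * c(t))  + Gaussian noise,

with c peak-normalised per compartment; a stroke lesion replaces the
kinetics of the affected voxels by a delayed, amplitude-scaled copy.
Voxels outside the head carry no signal (air).

Because every voxel of a compartment shares one concentration curve, the
noiseless ROI signal-time curves are exact positive multiples of the
compartment curves, so the discrete phase landmarks returned by the
generator (computed directly from the sampled analytic curves with the
same threshold rules used for detection) are the ground truth that curve
extraction + landmark detection must reproduce exactly at zero noise.

The default grid is 40 frames x 20 slices x 64 x 64 so that complete
pipeline experiments run on one CPU in minutes; pass a (T, D, 230, 230)
grid for native-geometry phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import BrainMask, CollateralMapSet, PerfusionSeries, SubjectRecord
from .phases import (PhaseLandmarks, PhaseWindows, compose_phase_maps,
                     partition_phases, subtract_baseline)

__all__ = [
    "GammaVariate",
    "Compartment",
    "LesionSpec",
    "PhantomSpec",
    "PhantomSubject",
    "gamma_variate_curve",
    "make_phantom",
    "make_cohort",
]


@dataclass(frozen=True)
class GammaVariate:
    """Peak-normalised gamma-variate bolus curve.

    c(t) = K * ((t - t0) / (alpha*beta))^alpha * exp(alpha - (t - t0)/beta)
    for t > t0, else 0; the peak sits at t0 + alpha*beta with value K.
    """

    t0: float
    alpha: float
    beta: float
    K: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.K <= 0:
            raise ValueError("amplitude K must be positive")

    @property
    def t_peak(self) -> float:
        return self.t0 + self.alpha * self.beta


def gamma_variate_curve(gv: GammaVariate, times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or np.any(np.diff(times) < 0):
        raise ValueError("times must be an ascending 1D array")
    tau = (times - gv.t0) / (gv.alpha * gv.beta)
    out = np.zeros_like(times)
    pos = tau > 0
    out[pos] = gv.K * tau[pos] ** gv.alpha * np.exp(
        gv.alpha - (times[pos] - gv.t0) / gv.beta)
    return out


@dataclass(frozen=True)
class Compartment:
    """One tissue compartment: bolus kinetics plus an optional plateau.

    ``plateau`` adds ``plateau * min(1, (t - t0)/plateau_rise)`` to the
    concentration — the recirculation tail that gives the venous curve
    its flat late phase.
    """

    gv: GammaVariate
    recirculation: float = 0.0      # amplitude of the second-pass bolus
    recirculation_delay: float = 12.8
    recirculation_broaden: float = 2.5

    def curve(self, times: np.ndarray) -> np.ndarray:
        c = gamma_variate_curve(self.gv, times)
        if self.recirculation > 0:
            second = GammaVariate(
                t0=self.gv.t0 + self.recirculation_delay, alpha=self.gv.alpha,
                beta=self.gv.beta * self.recirculation_broaden,
                K=self.recirculation)
            c = c + gamma_variate_curve(second, times)
        return c


@dataclass(frozen=True)
class LesionSpec:
    """Stroke lesion: delayed, attenuated kinetics inside a sphere."""

    center: tuple[float, float, float] = (10.0, 32.0, 45.0)  # (z, y, x)
    radius: float = 7.0
    delay_s: float = 3.2
    amplitude_factor: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.amplitude_factor <= 1.0:
            raise ValueError("amplitude_factor must lie in (0, 1]")


def _default_compartments() -> dict[str, Compartment]:
    """First-pass gamma-variates; every compartment carries a weaker,
    broadened second-pass (recirculation) bolus, which flattens the
    venous curve into its late plateau before the signal decays again."""
    return {
        "artery": Compartment(GammaVariate(t0=4.8, alpha=2.0, beta=2.4, K=1.0),
                              recirculation=0.10),
        "capillary": Compartment(GammaVariate(t0=6.4, alpha=2.5, beta=2.8, K=0.55),
                                 recirculation=0.08),
        "vein": Compartment(GammaVariate(t0=11.2, alpha=3.0, beta=3.2, K=0.75),
                            recirculation=0.40, recirculation_delay=11.2,
                            recirculation_broaden=1.3),
        "parenchyma": Compartment(GammaVariate(t0=7.2, alpha=2.5, beta=3.0, K=0.25),
                                  recirculation=0.05),
    }


@dataclass(frozen=True)
class PhantomSpec:
    grid: tuple[int, int, int, int] = (40, 20, 64, 64)  # (T, D, H, W)
    dt_seconds: float = 1.6
    baseline_intensity: float = 1000.0
    drop_fraction: float = 0.6
    compartments: dict = field(default_factory=_default_compartments)
    lesion: LesionSpec | None = None
    noise_sigma: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.drop_fraction < 1.0:
            raise ValueError("drop_fraction must lie in (0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        art = self.compartments["artery"].gv
        vein = self.compartments["vein"].gv
        if vein.t_peak <= art.t_peak:
            raise ValueError("venous peak must follow the arterial peak")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.grid[0]) * self.dt_seconds

    @property
    def peak_signal_drop(self) -> float:
        """Largest noiseless signal excursion (arterial compartment)."""
        return self.baseline_intensity * self.drop_fraction


@dataclass
class PhantomSubject:
    """Everything the generator knows about one synthetic subject."""

    series: PerfusionSeries
    brain: BrainMask
    mca_roi: BrainMask
    sss_roi: BrainMask
    landmarks: PhaseLandmarks
    windows: PhaseWindows
    maps: CollateralMapSet          # noiseless analytic phase maps (raw scale)
    labels: np.ndarray              # compartment index volume (z, y, x)


def _geometry(grid: tuple[int, int, int, int]) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Compartment masks on the (D, H, W) grid.

    Brain = centred ellipsoid; artery = anterior midline tube; vein
    (SSS) = posterior midline tube; capillary = cortical shell just
    inside the brain surface; parenchyma = remaining brain tissue.
    Masks are pairwise disjoint by construction.
    """
    _, D, H, W = grid
    z, y, x = np.mgrid[0:D, 0:H, 0:W].astype(float)
    zc, yc, xc = (D - 1) / 2, (H - 1) / 2, (W - 1) / 2
    rz, ry, rx = 0.50 * D, 0.42 * H, 0.42 * W
    r2 = ((z - zc) / rz) ** 2 + ((y - yc) / ry) ** 2 + ((x - xc) / rx) ** 2
    brain = r2 <= 1.0
    shell = (r2 <= 1.0) & (r2 >= 0.70)

    tube_r = max(2.5, 0.05 * W)  # MCA/SSS calibre scaled to the field of view
    zlo, zhi = int(0.15 * D), int(0.85 * D)
    tube_z = (z >= zlo) & (z <= zhi)
    artery = (((y - 0.30 * H) ** 2 + (x - xc) ** 2) <= tube_r ** 2) & tube_z & brain
    vein = (((y - 0.72 * H) ** 2 + (x - xc) ** 2) <= tube_r ** 2) & tube_z & brain

    capillary = shell & ~artery & ~vein
    parenchyma = brain & ~artery & ~vein & ~capillary
    masks = {"artery": artery, "vein": vein, "capillary": capillary,
             "parenchyma": parenchyma}
    if not (artery.any() and vein.any() and capillary.any() and parenchyma.any()):
        raise ValueError("grid too small for the compartment geometry")
    return brain, masks


def _scan_landmarks(art: np.ndarray, ven: np.ndarray,
                    arrival_frac: float = 0.1,
                    plateau_tol: float = 0.05) -> PhaseLandmarks:
    """Definitional scan of the sampled analytic curves (brute force).

    Independent of the curve-extraction path: operates on the pure
    compartment concentration curves, to which any noiseless ROI curve is
    proportional.
    """
    T = len(art)
    t_apeak = int(np.argmax(art))
    t_vpeak = int(np.argmax(ven))
    t_arrival = int(np.nonzero(art >= arrival_frac * art[t_apeak])[0][0])
    tol = plateau_tol * ven[t_vpeak]
    t_plateau = None
    for k in range(t_vpeak + 1, T - 1):
        if abs(ven[k + 1] - ven[k]) <= tol:
            t_plateau = k
            break
    if t_plateau is None:
        raise ValueError("phantom venous curve has no plateau")
    k = t_plateau
    while k < T - 1 and abs(ven[k + 1] - ven[k]) <= tol:
        k += 1
    return PhaseLandmarks(t_arrival=t_arrival, t_arterial_peak=t_apeak,
                          t_venous_peak=t_vpeak, t_plateau_start=t_plateau,
                          t_venous_end=min(k, T - 2))


_COMPARTMENT_ORDER = ("artery", "capillary", "vein", "parenchyma")


def _noiseless_volume(spec: PhantomSpec,
                      masks: dict[str, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless series (T, D, H, W) and the compartment label volume."""
    T, D, H, W = spec.grid
    times = spec.times
    signal = np.zeros((T, D, H, W), dtype=np.float64)
    labels = np.zeros((D, H, W), dtype=np.int8)  # 0 = air
    for idx, name in enumerate(_COMPARTMENT_ORDER, start=1):
        comp = spec.compartments[name]
        c = comp.curve(times)
        frames = spec.baseline_intensity * (1.0 - spec.drop_fraction * c)
        signal[:, masks[name]] = frames[:, None]
        labels[masks[name]] = idx
    if spec.lesion is not None:
        les = spec.lesion
        z, y, x = np.mgrid[0:D, 0:H, 0:W].astype(float)
        sphere = ((z - les.center[0]) ** 2 + (y - les.center[1]) ** 2
                  + (x - les.center[2]) ** 2) <= les.radius ** 2
        for name in _COMPARTMENT_ORDER:
            sel = masks[name] & sphere
            if not sel.any():
                continue
            comp = spec.compartments[name]
            delayed = replace(
                comp, gv=replace(comp.gv, t0=comp.gv.t0 + les.delay_s,
                                 K=comp.gv.K * les.amplitude_factor),
                recirculation=comp.recirculation * les.amplitude_factor)
            frames = spec.baseline_intensity * (1.0 - spec.drop_fraction
                                                * delayed.curve(times))
            signal[:, sel] = frames[:, None]
    return signal, labels


def make_phantom(spec: PhantomSpec = PhantomSpec(),
                 rng: np.random.Generator | None = None) -> PhantomSubject:
    """Generate one phantom subject.

    Returns the noisy series together with the compartment ROI masks, the
    analytic discrete landmarks, the phase windows they imply, and the
    exact phase maps of the noiseless series.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    brain, masks = _geometry(spec.grid)
    clean, labels = _noiseless_volume(spec, masks)

    times = spec.times
    lm = _scan_landmarks(spec.compartments["artery"].curve(times),
                         spec.compartments["vein"].curve(times))
    windows = partition_phases(lm, spec.grid[0])

    clean_series = PerfusionSeries(data=clean, dt_seconds=spec.dt_seconds)
    maps = compose_phase_maps(subtract_baseline(clean_series), windows)

    noisy = clean if spec.noise_sigma == 0 else \
        clean + rng.normal(0.0, spec.noise_sigma, size=clean.shape)
    series = PerfusionSeries(data=noisy, dt_seconds=spec.dt_seconds,
                             subject_id=f"phantom-{spec.seed}",
                             meta={"noise_sigma": spec.noise_sigma})
    return PhantomSubject(
        series=series, brain=BrainMask(mask=brain),
        mca_roi=BrainMask(mask=masks["artery"]),
        sss_roi=BrainMask(mask=masks["vein"]),
        landmarks=lm, windows=windows, maps=maps, labels=labels)


def _jitter_compartments(comps: dict[str, Compartment],
                         rng: np.random.Generator,
                         rel: float = 0.10) -> dict[str, Compartment]:
    out = {}
    for name, comp in comps.items():
        f = lambda v: float(v * (1.0 + rng.uniform(-rel, rel)))
        out[name] = replace(comp, gv=replace(comp.gv, t0=f(comp.gv.t0),
                                             alpha=f(comp.gv.alpha),
                                             beta=f(comp.gv.beta)))
    return out


def make_cohort(n_stroke: int, n_control: int,
                base_spec: PhantomSpec = PhantomSpec(),
                seed: int = 0) -> list[SubjectRecord]:
    """A cohort of jittered phantoms; lesions only in stroke subjects.

    Per-subject kinetics are jittered by +/-10% on t0, alpha and beta;
    subjects alternate between two synthetic centers.  Targets are the
    noiseless analytic phase maps (raw scale).
    """
    rng = np.random.default_rng(seed)
    records: list[SubjectRecord] = []
    groups = ["stroke"] * n_stroke + ["control"] * n_control
    for i, group in enumerate(groups):
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        spec = replace(
            base_spec,
            compartments=_jitter_compartments(base_spec.compartments, rng),
            lesion=(base_spec.lesion or LesionSpec()) if group == "stroke" else None,
            seed=sub_seed)
        ph = make_phantom(spec)
        ph.series.subject_id = f"{group}-{i:03d}"
        records.append(SubjectRecord(
            series=ph.series, mask=ph.brain, targets=ph.maps, group=group,
            center=str(1 + i % 2), subject_id=ph.series.subject_id))
    return records
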