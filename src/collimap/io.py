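"""Domain types and NIfTI/DICOM I/O for 4D perfusion series and phase maps.

Axis convention, used by every module in the package: in memory a
perfusion series is ``(t, z, y, x)`` — time, slice, row, column — and a
phase-map set is ``(phase, z, y, x)``.  On disk the canonical container is
NIfTI-1 with the usual ``(x, y, z, t)`` dimension order (time/phase as the
4th dimension); DICOM series directories are read-only input.  A JSON
sidecar carries the phase names, temporal resolution and provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import nibabel as nib
import numpy as np

__all__ = [
    "PHASE_NAMES",
    "PerfusionSeries",
    "BrainMask",
    "CollateralMapSet",
    "SubjectRecord",
    "read_perfusion",
    "write_perfusion",
    "read_maps",
    "write_maps",
    "validate_series",
]

#: Fixed phase order: arterial, capillary, early venous, late venous, delay.
PHASE_NAMES = ("Art", "Cap", "EVen", "LVen", "Del")


@dataclass
class PerfusionSeries:
    """A 4D dynamic susceptibility contrast perfusion series.

    ``data`` is indexed ``(t, z, y, x)``; ``dt_seconds`` is the temporal
    resolution (1.6 s for the canonical 40-frame acquisition); temporal
    index 0 is the first, pre-contrast frame.
    """

    data: np.ndarray
    dt_seconds: float = 1.6
    subject_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D series (t, z, y, x), got {self.data.ndim}D")
        if self.t_count < 2:
            raise ValueError("a perfusion series needs at least 2 time points")
        if self.dt_seconds <= 0:
            raise ValueError("dt_seconds must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("series contains non-finite voxels")

    @property
    def t_count(self) -> int:
        return self.data.shape[0]

    @property
    def z_count(self) -> int:
        return self.data.shape[1]

    @property
    def spatial(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.t_count) * self.dt_seconds

    def with_data(self, data: np.ndarray) -> "PerfusionSeries":
        return PerfusionSeries(data=data, dt_seconds=self.dt_seconds,
                               subject_id=self.subject_id, meta=dict(self.meta))


@dataclass
class BrainMask:
    """Binary 3D mask over ``(z, y, x)``; must contain foreground."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError("brain mask must be 3D (z, y, x)")
        if not self.mask.any():
            raise ValueError("empty mask")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class CollateralMapSet:
    """Five-phase collateral maps ``(phase, z, y, x)`` in fixed order.

    ``value_range`` declares the scale the values live on: ``"raw"`` (as
    composed from subtracted intensities), ``"unit"`` (nominally [0, 1];
    outliers may remain until normalisation clips them) or ``"signed"``
    ([-0.9, 0.9], the network's target scale, strictly enforced).
    """

    maps: np.ndarray
    value_range: Literal["raw", "unit", "signed"] = "raw"

    _BOUNDS = {"signed": (-0.9, 0.9)}

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps)
        if self.maps.ndim != 4 or self.maps.shape[0] != len(PHASE_NAMES):
            raise ValueError(
                f"expected maps of shape (5, z, y, x), got {self.maps.shape}")
        if not np.all(np.isfinite(self.maps)):
            raise ValueError("maps contain non-finite values")
        if self.value_range in self._BOUNDS:
            lo, hi = self._BOUNDS[self.value_range]
            if self.maps.size and (self.maps.min() < lo or self.maps.max() > hi):
                raise ValueError(
                    f"values outside declared range {self.value_range} "
                    f"[{lo}, {hi}]: [{self.maps.min()}, {self.maps.max()}]")

    @property
    def phase_names(self) -> tuple[str, ...]:
        return PHASE_NAMES

    def phase(self, name: str) -> np.ndarray:
        return self.maps[PHASE_NAMES.index(name)]


@dataclass
class SubjectRecord:
    """One subject: series, mask, optional targets, cohort labels."""

    series: PerfusionSeries
    mask: BrainMask
    targets: CollateralMapSet | None = None
    group: Literal["stroke", "control"] = "control"
    center: str = "1"
    subject_id: str = ""

    def __post_init__(self) -> None:
        vol_shape = self.series.data.shape[1:]
        if self.mask.mask.shape != vol_shape:
            raise ValueError("mask shape inconsistent with series")
        if self.targets is not None and self.targets.maps.shape[1:] != vol_shape:
            raise ValueError("target maps shape inconsistent with series")


def validate_series(series: PerfusionSeries, expect: tuple[int, int]) -> None:
    """Check the (time, slice) counts; finiteness is enforced on construction."""
    t, d = expect
    if series.t_count != t:
        raise ValueError(f"time axis has {series.t_count} frames, expected {t}")
    if series.z_count != d:
        raise ValueError(f"slice axis has {series.z_count} slices, expected {d}")
    if not np.all(np.isfinite(series.data)):
        raise ValueError("series contains non-finite voxels")


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_perfusion(series: PerfusionSeries, path: str | Path) -> None:
    """Write a series as 4D NIfTI ``(x, y, z, t)`` plus a JSON sidecar."""
    path = Path(path)
    disk = np.transpose(series.data, (3, 2, 1, 0))
    img = nib.Nifti1Image(disk, affine=np.eye(4))
    img.header["pixdim"][4] = series.dt_seconds
    img.header.set_xyzt_units(xyz="mm", t="sec")
    nib.save(img, str(path))
    sidecar = {"dt_seconds": series.dt_seconds, "subject_id": series.subject_id,
               "meta": series.meta}
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))


def _read_nifti_4d(path: Path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"expected 4D series, got {data.ndim}D image")
    dt = float(img.header["pixdim"][4])
    return np.transpose(data, (3, 2, 1, 0)), dt


def read_perfusion(path: str | Path, format: str = "nifti", *,
                   dt_seconds: float | None = None,
                   subject_id: str | None = None) -> PerfusionSeries:
    """Read a 4D perfusion series from NIfTI or a DICOM directory.

    Header metadata (temporal resolution, subject id) is used when present;
    explicit arguments override it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format == "nifti":
        data, dt = _read_nifti_4d(path)
        meta: dict = {"source": str(path), "format": "nifti"}
        sid = subject_id or ""
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            info = json.loads(sidecar.read_text())
            dt = float(info.get("dt_seconds", dt))
            sid = subject_id or info.get("subject_id", "")
            meta.update(info.get("meta", {}))
        if dt_seconds is not None:
            dt = dt_seconds
        if dt <= 0:
            dt = 1.6
        return PerfusionSeries(data=data, dt_seconds=dt, subject_id=sid, meta=meta)
    if format == "dicom_dir":
        return _read_dicom_dir(path, dt_seconds=dt_seconds, subject_id=subject_id)
    raise ValueError(f"unknown format {format!r}")


def _read_dicom_dir(path: Path, *, dt_seconds: float | None,
                    subject_id: str | None) -> PerfusionSeries:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file() and p.suffix.lower() in
                   {".dcm", ".ima", ""})
    if not files:
        raise FileNotFoundError(f"no DICOM instances under {path}")
    frames = []
    for f in files:
        ds = pydicom.dcmread(str(f))
        t_idx = int(getattr(ds, "TemporalPositionIdentifier",
                            getattr(ds, "AcquisitionNumber", 0)) or 0)
        z_loc = float(getattr(ds, "SliceLocation",
                              getattr(ds, "InstanceNumber", 0)) or 0)
        frames.append((t_idx, z_loc, ds))
    t_values = sorted({t for t, _, _ in frames})
    z_values = sorted({z for _, z, _ in frames})
    n_t, n_z = len(t_values), len(z_values)
    if n_t * n_z != len(frames):
        raise ValueError(
            f"inconsistent DICOM grid: {len(frames)} instances cannot tile "
            f"{n_t} time points x {n_z} slices")
    t_index = {t: i for i, t in enumerate(t_values)}
    z_index = {z: i for i, z in enumerate(z_values)}
    first = frames[0][2].pixel_array
    data = np.zeros((n_t, n_z) + first.shape, dtype=np.float64)
    seen = np.zeros((n_t, n_z), dtype=bool)
    for t, z, ds in frames:
        ti, zi = t_index[t], z_index[z]
        if seen[ti, zi]:
            raise ValueError(f"duplicate DICOM instance at time {t}, slice {z}")
        seen[ti, zi] = True
        data[ti, zi] = ds.pixel_array
    ds0 = frames[0][2]
    dt = dt_seconds
    if dt is None:
        rep = float(getattr(ds0, "RepetitionTime", 0) or 0) / 1000.0
        dt = rep if rep > 0 else 1.6
    sid = subject_id or str(getattr(ds0, "PatientID", ""))
    return PerfusionSeries(data=data, dt_seconds=dt, subject_id=sid,
                           meta={"source": str(path), "format": "dicom_dir"})


def write_maps(maps: CollateralMapSet, path: str | Path) -> None:
    """Write a five-phase map set as 4D NIfTI with a phase-name sidecar."""
    path = Path(path)
    disk = np.transpose(maps.maps, (3, 2, 1, 0))
    img = nib.Nifti1Image(disk, affine=np.eye(4))
    try:
        nib.save(img, str(path))
    except Exception as exc:  # unwritable path
        raise OSError(f"cannot write maps to {path}: {exc}") from exc
    sidecar = {"phases": list(PHASE_NAMES), "value_range": maps.value_range}
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))


def read_maps(path: str | Path) -> CollateralMapSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError("expected a 4D phase-map image")
    value_range = "raw"
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        info = json.loads(sidecar.read_text())
        if tuple(info.get("phases", PHASE_NAMES)) != PHASE_NAMES:
            raise ValueError("phase order on disk does not match the fixed order")
        value_range = info.get("value_range", "raw")
    return CollateralMapSet(maps=np.transpose(data, (3, 2, 1, 0)),
                            value_range=value_range)
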