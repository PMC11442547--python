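"""Preprocessing for perfusion series and collateral phase maps.

Four steps, applied in this order:

1. brain-mask creation — sum the series over time, min-max normalise,
   threshold at 0.1, then refine with morphological closing, erosion and
   dilation using a spherical (Euclidean-ball) element of radius 6;
2. intensity normalisation — series min-max scaled to [0, 1] over masked
   voxels across all time points (global, so temporal bolus dynamics are
   preserved); target maps scaled to [0, 1] with outliers clipped, then
   affinely mapped onto [-0.9, 0.9];
3. median filtering of the target maps (5x5, per slice);
4. centre-cropping of both to 224 x 224 (230-native input keeps index
   range [3, 227) on each spatial axis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import ball

from .io import BrainMask, CollateralMapSet, PerfusionSeries

__all__ = [
    "PreprocessConfig",
    "build_brain_mask",
    "normalize_series",
    "normalize_targets",
    "median_filter_targets",
    "center_crop",
    "preprocess_series",
    "preprocess_targets",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """``morph_radius`` is the in-plane radius (voxels) of the spherical
    structuring element; ``morph_z_radius`` is its slice-axis radius.  The
    default (6, 1) realises a physically near-spherical kernel on the
    strongly anisotropic acquisition grid (~1 mm pixels, 7 mm slice
    pitch); an isotropic ball is obtained with morph_z_radius ==
    morph_radius."""

    mask_threshold: float = 0.1
    morph_radius: int = 6
    morph_z_radius: int = 1
    median_kernel: int = 5
    crop_size: int = 224
    target_low: float = -0.9
    target_high: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 < self.mask_threshold < 1.0:
            raise ValueError("mask_threshold must lie in (0, 1)")
        if self.morph_radius < 1 or self.morph_z_radius < 1:
            raise ValueError("morphology radii must be >= 1")
        if self.median_kernel % 2 != 1:
            raise ValueError("median_kernel must be odd")
        if self.target_low >= self.target_high:
            raise ValueError("target range is empty")


def build_brain_mask(series: PerfusionSeries,
                     cfg: PreprocessConfig = PreprocessConfig()) -> BrainMask:
    """Threshold the time-summed series and refine with 3D morphology.

    The morphological sequence is closing, then erosion, then dilation,
    each with the same spherical element; the mask is therefore invariant
    to any strictly increasing affine rescaling of the input intensities.
    """
    summed = series.data.sum(axis=0)
    lo, hi = float(summed.min()), float(summed.max())
    if hi <= lo:
        raise ValueError("empty mask: series has no intensity contrast")
    norm = (summed - lo) / (hi - lo)
    raw = norm >= cfg.mask_threshold
    selem = _spherical_element(cfg.morph_radius, cfg.morph_z_radius)
    mask = ndimage.binary_closing(raw, structure=selem)
    mask = ndimage.binary_erosion(mask, structure=selem)
    mask = ndimage.binary_dilation(mask, structure=selem)
    if not mask.any():
        raise ValueError("empty mask after morphology")
    return BrainMask(mask=mask)


def _spherical_element(r: int, rz: int) -> np.ndarray:
    """Discrete Euclidean ball, ellipsoidal when the z radius differs."""
    if rz == r:
        return ball(r)
    z, y, x = np.mgrid[-rz:rz + 1, -r:r + 1, -r:r + 1].astype(float)
    return (z / rz) ** 2 + (y / r) ** 2 + (x / r) ** 2 <= 1.0


def normalize_series(series: PerfusionSeries, mask: BrainMask) -> PerfusionSeries:
    """Min-max normalise to [0, 1] over masked voxels across all frames.

    Voxels outside the mask are zeroed.  Idempotent given the same mask.
    """
    if mask.mask.shape != series.data.shape[1:]:
        raise ValueError("mask shape inconsistent with series")
    vals = series.data[:, mask.mask]
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        raise ValueError("zero dynamic range within the brain mask")
    out = (series.data - lo) / (hi - lo)
    out = out * mask.mask[None]
    return series.with_data(out)


def _to_unit(maps: CollateralMapSet) -> np.ndarray:
    """Bring maps onto the [0, 1] scale; clip outliers to 0 or 1."""
    data = np.asarray(maps.maps, dtype=np.float64)
    if maps.value_range == "signed":
        raise ValueError("maps are already on the signed target scale")
    if maps.value_range == "raw":
        lo, hi = float(data.min()), float(data.max())
        if hi > lo:
            data = (data - lo) / (hi - lo)
        else:
            data = np.zeros_like(data)
    return np.clip(data, 0.0, 1.0)


def normalize_targets(maps: CollateralMapSet,
                      cfg: PreprocessConfig = PreprocessConfig()) -> CollateralMapSet:
    """Scale maps to [0, 1] (clipping outliers) then map onto [-0.9, 0.9].

    The affine step is ``v -> (high - low) * v + low`` which for the
    default range is ``v -> 1.8 v - 0.9``, a bijection of [0, 1] onto
    [-0.9, 0.9]; 0.5 maps to exactly 0.
    """
    unit = _to_unit(maps)
    signed = (cfg.target_high - cfg.target_low) * unit + cfg.target_low
    return CollateralMapSet(maps=signed, value_range="signed")


def median_filter_targets(maps: CollateralMapSet,
                          cfg: PreprocessConfig = PreprocessConfig()) -> CollateralMapSet:
    """Per-phase, per-slice 2D median filter (default 5x5 window).

    Filtering is 2D because slice thickness is roughly 20x the in-plane
    resolution; the median commutes with the monotone affine target
    mapping, so applying it before or after is equivalent.
    """
    k = cfg.median_kernel
    filtered = ndimage.median_filter(maps.maps, size=(1, 1, k, k), mode="nearest")
    return CollateralMapSet(maps=filtered, value_range=maps.value_range)


def _crop_slices(size: int, crop: int) -> slice:
    if size < crop:
        raise ValueError(f"input size {size} smaller than crop size {crop}")
    lo = (size - crop) // 2  # odd leftover goes to the high-index side
    return slice(lo, lo + crop)


def center_crop(volume, cfg: PreprocessConfig = PreprocessConfig()):
    """Symmetric centre crop of the two trailing spatial axes.

    Accepts a ``PerfusionSeries``, a ``CollateralMapSet`` or a bare
    array whose last two axes are spatial; time/slice axes are untouched.
    """
    if isinstance(volume, PerfusionSeries):
        arr = volume.data
    elif isinstance(volume, CollateralMapSet):
        arr = volume.maps
    else:
        arr = np.asarray(volume)
    sy = _crop_slices(arr.shape[-2], cfg.crop_size)
    sx = _crop_slices(arr.shape[-1], cfg.crop_size)
    cropped = arr[..., sy, sx]
    if isinstance(volume, PerfusionSeries):
        return volume.with_data(cropped)
    if isinstance(volume, CollateralMapSet):
        return CollateralMapSet(maps=cropped, value_range=volume.value_range)
    return cropped


def preprocess_series(series: PerfusionSeries,
                      cfg: PreprocessConfig = PreprocessConfig(),
                      mask: BrainMask | None = None
                      ) -> tuple[PerfusionSeries, BrainMask]:
    """Full series pipeline: mask -> normalise -> crop.

    Returns the preprocessed series together with the (cropped) mask.
    """
    if mask is None:
        mask = build_brain_mask(series, cfg)
    normed = normalize_series(series, mask)
    cropped = center_crop(normed, cfg)
    mask_c = BrainMask(mask=center_crop(mask.mask, cfg))
    return cropped, mask_c


def preprocess_targets(maps: CollateralMapSet,
                       cfg: PreprocessConfig = PreprocessConfig(),
                       median: bool = True) -> CollateralMapSet:
    """Full target pipeline: scale/clip -> median filter -> crop."""
    out = normalize_targets(maps, cfg)
    if median:
        out = median_filter_targets(out, cfg)
    return center_crop(out, cfg)
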