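"""Preprocessing chain: Gaussian smoothing, brain masking, temporal
interpolation to a uniform 0.5-s grid, and [-1, 1] intensity normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .containers import CTPSeries


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    Kernels are discrete Gaussian window sizes (odd, >= 1): 7 in-plane and
    3 along time.  The Gaussian sigma is kernel/6 so +-3 sigma spans the
    window.  Brain voxels are those in [hu_low, hu_high] = [10, 80] HU;
    series are resampled to ``target_dt`` = 0.5 s; ``norm_low``/``norm_high``
    are the intensity bounds mapped to [-1, +1].
    """

    spatial_kernel: int = 7
    temporal_kernel: int = 3
    hu_low: float = 10.0
    hu_high: float = 80.0
    target_dt: float = 0.5
    norm_low: float = 0.0
    norm_high: float = 100.0

    def __post_init__(self) -> None:
        for k in (self.spatial_kernel, self.temporal_kernel):
            if k < 1 or k % 2 == 0:
                raise ValueError("kernels must be odd and >= 1")
        if self.hu_low >= self.hu_high:
            raise ValueError("hu_low must be < hu_high")
        if self.target_dt <= 0:
            raise ValueError("target_dt must be positive")
        if self.norm_low >= self.norm_high:
            raise ValueError("norm_low must be < norm_high")


def _gauss1d(arr: np.ndarray, kernel: int, axis: int) -> np.ndarray:
    if kernel == 1:
        return arr
    sigma = kernel / 6.0
    radius = (kernel - 1) // 2
    return ndimage.gaussian_filter1d(
        arr, sigma=sigma, axis=axis, truncate=radius / sigma, mode="nearest"
    )


def smooth(series: CTPSeries, cfg: PreprocessConfig | None = None) -> CTPSeries:
    """Separable Gaussian smoothing: spatial in-plane per frame, temporal per voxel."""
    if cfg is None:
        cfg = PreprocessConfig()
    if series.n_frames < cfg.temporal_kernel:
        raise ValueError("series shorter than the temporal kernel")
    out = _gauss1d(series.data, cfg.spatial_kernel, axis=2)
    out = _gauss1d(out, cfg.spatial_kernel, axis=3)
    out = _gauss1d(out, cfg.temporal_kernel, axis=0)
    return CTPSeries(
        data=out,
        frame_times=series.frame_times.copy(),
        voxel_spacing=series.voxel_spacing,
        aif_roi=series.aif_roi,
        vof_roi=series.vof_roi,
        brain_mask=series.brain_mask,
    )


def brain_mask(frame: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """HU-threshold brain segmentation: keep [hu_low, hu_high], then the
    largest connected component.  An empty mask is allowed (e.g. air only)."""
    if cfg is None:
        cfg = PreprocessConfig()
    raw = (frame >= cfg.hu_low) & (frame <= cfg.hu_high)
    if not raw.any():
        return raw
    labels, n = ndimage.label(raw)
    if n == 1:
        return raw
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


def interpolate_time(series: CTPSeries, target_dt: float = 0.5) -> CTPSeries:
    """Per-voxel linear interpolation onto a uniform grid spanning
    [first, last] frame time; output frame count is
    floor((t_last - t_first)/dt) + 1."""
    if series.n_frames < 2:
        raise ValueError("need at least 2 frames to interpolate")
    t = series.frame_times
    n_out = int(np.floor((t[-1] - t[0]) / target_dt)) + 1
    new_t = t[0] + np.arange(n_out) * target_dt
    flat = series.data.reshape(series.n_frames, -1)
    # np.interp per column is slow; use vectorized piecewise-linear weights
    idx = np.clip(np.searchsorted(t, new_t, side="right") - 1, 0, len(t) - 2)
    w = (new_t - t[idx]) / (t[idx + 1] - t[idx])
    out = (1 - w)[:, None] * flat[idx] + w[:, None] * flat[idx + 1]
    return CTPSeries(
        data=out.reshape((n_out,) + series.volume_shape),
        frame_times=new_t,
        voxel_spacing=series.voxel_spacing,
        aif_roi=series.aif_roi,
        vof_roi=series.vof_roi,
        brain_mask=series.brain_mask,
    )


def normalize(image: np.ndarray, norm_low: float, norm_high: float) -> np.ndarray:
    """Clip to [norm_low, norm_high], then map affinely to [-1, +1]."""
    if norm_low >= norm_high:
        raise ValueError("degenerate normalization bounds")
    clipped = np.clip(image, norm_low, norm_high)
    return 2.0 * (clipped - norm_low) / (norm_high - norm_low) - 1.0


def denormalize(image: np.ndarray, norm_low: float, norm_high: float) -> np.ndarray:
    """Inverse of :func:`normalize` on [-1, +1]."""
    if norm_low >= norm_high:
        raise ValueError("degenerate normalization bounds")
    return (np.asarray(image) + 1.0) / 2.0 * (norm_high - norm_low) + norm_low
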