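"""mCTP phase selection and maximum intensity projection.

The three mCTP phases mirror the multiphase CTA protocol: the AIF peak
frame, the VOF peak frame, and a delayed frame 8 s after the VOF peak.  The
phase-composition experiment shifts all three phases jointly by +-1 or +-2
steps of 2 s (labels Pre-2, Pre-1, Peak, Late-1, Late-2).
"""

from __future__ import annotations

import numpy as np

from .containers import SHIFT_LABELS, CTPSeries, MCTPTriplet


def find_peak(curve: np.ndarray, times: np.ndarray) -> tuple[float, int]:
    """Earliest global maximum of ``curve``; returns (peak_time, peak_index)."""
    curve = np.asarray(curve, dtype=float)
    times = np.asarray(times, dtype=float)
    if curve.size == 0:
        raise ValueError("empty curve")
    if curve.shape != times.shape:
        raise ValueError("curve and times must have equal length")
    i = int(np.argmax(curve))  # argmax returns the first maximum
    return float(times[i]), i


def select_phases(
    series: CTPSeries,
    aif_curve: np.ndarray,
    vof_curve: np.ndarray,
    shift_steps: int = 0,
    step_s: float = 2.0,
    venous_delay_s: float = 8.0,
) -> MCTPTriplet:
    """Select the 3 mCTP phase frames from a full series.

    Target times are (t_aif_peak, t_vof_peak, t_vof_peak + venous_delay_s),
    each offset by ``shift_steps * step_s`` and snapped to the nearest
    available frame (earlier frame on ties).  ``shift_steps`` in [-2, 2]
    maps to labels Pre-2 .. Late-2.
    """
    if shift_steps not in SHIFT_LABELS:
        raise ValueError("shift_steps must be an integer in [-2, 2]")
    t = series.frame_times
    t_aif, _ = find_peak(aif_curve, t)
    t_vof, _ = find_peak(vof_curve, t)
    targets = np.array([t_aif, t_vof, t_vof + venous_delay_s]) + shift_steps * step_s
    if targets[0] < t[0] - 1e-9 or targets[-1] > t[-1] + 1e-9:
        raise ValueError(
            f"requested phase times {targets} fall outside the acquisition "
            f"window [{t[0]}, {t[-1]}]"
        )
    # snap to the nearest frame, preferring the earlier one on ties
    dist = np.abs(t[None, :] - targets[:, None])
    idx = dist.argmin(axis=1)
    if len(set(idx.tolist())) < 3 or np.any(np.diff(idx) <= 0):
        raise ValueError("phase times collapse onto non-increasing frames")
    dts = np.diff(t)
    source_dt = float(dts[0]) if np.allclose(dts, dts[0]) else float(np.median(dts))
    return MCTPTriplet(
        phase_images=series.data[idx].copy(),
        phase_times=t[idx].copy(),
        shift_label=SHIFT_LABELS[shift_steps],
        source_dt=source_dt,
    )


def mip(triplet: MCTPTriplet) -> np.ndarray:
    """Maximum intensity projection: per-voxel max across the 3 phases."""
    return triplet.phase_images.max(axis=0)
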