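"""Shared data containers for the mCTP pipeline.

Array axis convention: 4D series are (T, Z, Y, X); 3D volumes are (Z, Y, X).
The left-right (hemisphere) axis is X, the last axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: ml/100 g/min CBF with time in seconds: CBF/kappa has units 1/s.
KAPPA = 100.0 * 60.0

SHIFT_LABELS = {-2: "Pre-2", -1: "Pre-1", 0: "Peak", 1: "Late-1", 2: "Late-2"}


@dataclass
class AIFModel:
    """Gamma-variate arterial input function.

    c(t) = A * ((t - t0)/(alpha*beta))**alpha * exp(alpha - (t - t0)/beta)
    for t >= t0 and 0 before onset; the peak value A is attained at
    t0 + alpha*beta.  An optional recirculation bump adds a delayed, scaled
    copy of the first pass.

    Parameters
    ----------
    t0 : float
        Bolus arrival time (s).
    alpha : float
        Dimensionless shape parameter, > 0.
    beta : float
        Scale parameter (s), > 0.
    amplitude : float
        Peak enhancement (HU).
    recirculation_fraction : float
        Scale of the recirculation copy, >= 0 (0 disables it).
    recirculation_delay : float
        Delay of the recirculation copy relative to the first pass (s).
    """

    t0: float = 8.0
    alpha: float = 3.0
    beta: float = 1.5
    amplitude: float = 150.0
    recirculation_fraction: float = 0.0
    recirculation_delay: float = 12.0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.recirculation_fraction < 0:
            raise ValueError("recirculation_fraction must be >= 0")

    @property
    def peak_time(self) -> float:
        return self.t0 + self.alpha * self.beta


@dataclass
class PerfusionPhantom:
    """Per-voxel perfusion ground truth with lesion label masks.

    CBF is in ml/100 g/min, MTT and delay in seconds.  CBF is zero outside
    ``brain_mask``; ``core_mask`` and ``hypo_mask`` are subsets of the brain.
    """

    cbf_map: np.ndarray
    mtt_map: np.ndarray
    delay_map: np.ndarray
    core_mask: np.ndarray
    hypo_mask: np.ndarray
    brain_mask: np.ndarray
    voxel_spacing: tuple[float, float, float] = (5.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.brain_mask.sum() == 0:
            raise ValueError("brain mask is empty")
        if np.any(self.core_mask & ~self.brain_mask):
            raise ValueError("core_mask must be a subset of brain_mask")
        if np.any(self.hypo_mask & ~self.brain_mask):
            raise ValueError("hypo_mask must be a subset of brain_mask")
        if np.any(self.cbf_map[~self.brain_mask] != 0):
            raise ValueError("cbf_map must be 0 outside brain_mask")
        if np.any(self.cbf_map < 0):
            raise ValueError("cbf_map must be non-negative")
        inside = self.brain_mask & (self.cbf_map > 0)
        if np.any(self.mtt_map[inside] <= 0):
            raise ValueError("mtt_map must be positive where cbf > 0")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.cbf_map.shape


@dataclass
class CTPSeries:
    """4D CT perfusion series in Hounsfield units.

    ``data`` has shape (T, Z, Y, X); ``frame_times`` is strictly increasing
    and may be non-uniform (the 19-frame acquisition grid has 2-s spacing
    around the arterial peak and coarser tails).  ``aif_roi`` / ``vof_roi``
    are (N, 3) integer arrays of (z, y, x) voxel indices.
    """

    data: np.ndarray
    frame_times: np.ndarray
    voxel_spacing: tuple[float, float, float] = (5.0, 1.0, 1.0)
    aif_roi: np.ndarray | None = None
    vof_roi: np.ndarray | None = None
    brain_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (T, Z, Y, X)")
        if self.data.shape[0] != len(self.frame_times):
            raise ValueError("frame_times length must match data time axis")
        if self.data.shape[0] < 4:
            raise ValueError("a CTP series needs at least 4 frames")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def volume_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def roi_curve(self, roi: np.ndarray) -> np.ndarray:
        """Mean enhancement over the ROI voxels, one value per frame."""
        roi = np.asarray(roi)
        if roi.size == 0:
            raise ValueError("empty ROI")
        z, y, x = roi[:, 0], roi[:, 1], roi[:, 2]
        return self.data[:, z, y, x].mean(axis=1)


@dataclass
class PerfusionMaps:
    """CBF (ml/100 g/min) and Tmax (s) volumes with provenance.

    ``provenance`` is one of ``reference-bsvd``, ``gan``, ``baseline-bsvd``.
    CBV (ml/100 g) and MTT (s) are optional.
    """

    cbf: np.ndarray
    tmax: np.ndarray
    brain_mask: np.ndarray
    provenance: str
    voxel_spacing: tuple[float, float, float] = (5.0, 1.0, 1.0)
    cbv: np.ndarray | None = None
    mtt: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.cbf.shape != self.tmax.shape or self.cbf.shape != self.brain_mask.shape:
            raise ValueError("cbf, tmax and brain_mask must share a shape")
        if np.any(self.cbf < 0) or np.any(self.tmax < 0):
            raise ValueError("maps must be non-negative after post-processing")


@dataclass
class MCTPTriplet:
    """The three selected mCTP phase images and their acquisition times.

    ``shift_label`` records the phase-composition experiment arm:
    Pre-2/Pre-1 advance, Late-1/Late-2 delay all three phases by one or two
    2-s steps relative to the Peak composition.
    """

    phase_images: np.ndarray  # (3, Z, Y, X)
    phase_times: np.ndarray  # (3,)
    shift_label: str = "Peak"
    source_dt: float = 0.5

    def __post_init__(self) -> None:
        self.phase_times = np.asarray(self.phase_times, dtype=float)
        if self.phase_images.shape[0] != 3 or len(self.phase_times) != 3:
            raise ValueError("an mCTP triplet has exactly 3 phases")
        if np.any(np.diff(self.phase_times) <= 0):
            raise ValueError("phase times must be strictly increasing")
        if self.shift_label not in SHIFT_LABELS.values():
            raise ValueError(f"unknown shift label {self.shift_label!r}")


@dataclass
class LesionMasks:
    """Core and hypoperfusion segmentations with the thresholds that made them."""

    core: np.ndarray
    hypoperfusion: np.ndarray
    rcbf_frac: float = 0.30
    tmax_s: float = 6.0


@dataclass
class AgreementReport:
    """Per-cohort similarity metrics, volumetrics and agreement statistics.

    ``similarity`` maps the map type (``cbf`` / ``tmax``) to the mean and sd
    over slices of NRMSE, SSIM and perceptual distance; volumes and mismatch
    ratios are (predicted, reference) pairs per case.
    """

    label: str
    similarity: dict = field(default_factory=dict)
    dice_core: float = float("nan")
    dice_hypo: float = float("nan")
    core_volumes_ml: list[tuple[float, float]] = field(default_factory=list)
    hypo_volumes_ml: list[tuple[float, float]] = field(default_factory=list)
    mismatch_ratios: list[tuple[float, float]] = field(default_factory=list)
    bland_altman_core: tuple[float, float, float] | None = None
    bland_altman_hypo: tuple[float, float, float] | None = None
    icc_core: tuple[float, float, float] | None = None
    icc_hypo: tuple[float, float, float] | None = None
    icc_core_band: str | None = None
    icc_hypo_band: str | None = None
    scc_core: tuple[float, float] | None = None
    scc_hypo: tuple[float, float] | None = None
    scc_core_band: str | None = None
    scc_hypo_band: str | None = None

    def to_dict(self) -> dict:
        out = {}
        for k, v in self.__dict__.items():
            if isinstance(v, np.ndarray):
                v = v.tolist()
            out[k] = v
        return out
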