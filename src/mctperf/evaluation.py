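"""Quantitative evaluation: image similarity, lesion volumetrics, and
volume-agreement statistics.

Lesion definitions follow the clinical thresholds: ischemic core is
rCBF < 30% of a healthy-tissue reference and hypoperfusion is Tmax > 6 s,
applied independently.  Agreement between predicted and reference volumes is
summarized by Bland-Altman limits, ICC(2,1) (two-way random effects,
absolute agreement, single rater) and Spearman correlation, each with the
conventional interpretation bands.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats
from skimage.metrics import structural_similarity

from .containers import LesionMasks, PerfusionMaps

# ---------------------------------------------------------------------------
# image similarity


def nrmse(pred: np.ndarray, ref: np.ndarray, mask: np.ndarray | None = None) -> float:
    """RMSE over mask voxels normalized by the reference's in-mask range."""
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape:
        raise ValueError("shape mismatch")
    if mask is None:
        mask = np.ones(ref.shape, dtype=bool)
    r = ref[mask]
    rng = r.max() - r.min()
    if rng == 0:
        raise ValueError("reference is constant in the mask; NRMSE undefined")
    return float(np.sqrt(np.mean((pred[mask] - r) ** 2)) / rng)


def ssim(
    pred: np.ndarray,
    ref: np.ndarray,
    mask: np.ndarray | None = None,
    data_range: float | None = None,
    win_size: int | None = None,
) -> float:
    """Windowed SSIM averaged over the mask (whole image if mask is None)."""
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if data_range is None:
        lo = min(pred.min(), ref.min())
        hi = max(pred.max(), ref.max())
        data_range = hi - lo if hi > lo else 1.0
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    _, smap = structural_similarity(
        ref, pred, data_range=data_range, win_size=win_size, full=True
    )
    if mask is None:
        return float(smap.mean())
    if not mask.any():
        raise ValueError("empty mask")
    return float(smap[mask].mean())


class RandomFilterBank:
    """Fixed-seed multi-scale random filter bank for perceptual distance.

    A no-download stand-in for a pretrained feature extractor: the image is
    compared at several dyadic scales through a bank of random 5x5 filters
    (plus an identity channel so the distance is 0 iff the inputs are
    identical), with channel-normalized features as in deep perceptual
    metrics.  A pretrained backbone exposing the same ``features(img)``
    interface can be plugged in instead.
    """

    def __init__(self, n_filters: int = 12, scales: tuple[int, ...] = (1, 2, 4), seed: int = 0):
        rng = np.random.default_rng(seed)
        self.scales = scales
        self.filters = rng.standard_normal((n_filters, 5, 5))
        self.filters -= self.filters.mean(axis=(1, 2), keepdims=True)
        self.filters /= np.sqrt((self.filters**2).sum(axis=(1, 2), keepdims=True))

    @staticmethod
    def _downsample(img: np.ndarray, f: int) -> np.ndarray:
        if f == 1:
            return img
        h, w = img.shape
        h2, w2 = h - h % f, w - w % f
        return img[:h2, :w2].reshape(h2 // f, f, w2 // f, f).mean(axis=(1, 3))

    def features(self, img: np.ndarray) -> list[np.ndarray]:
        from scipy.signal import fftconvolve

        img = np.asarray(img, dtype=float)
        feats = []
        for s in self.scales:
            d = self._downsample(img, s)
            maps = [d]  # identity channel guarantees distance 0 iff identical
            for f in self.filters:
                maps.append(fftconvolve(d, f, mode="same"))
            stack = np.stack(maps)
            norm = np.sqrt((stack**2).sum(axis=0, keepdims=True)) + 1e-8
            feats.append(stack / norm)
        return feats


_default_extractor: RandomFilterBank | None = None


def perceptual_distance(
    pred: np.ndarray, ref: np.ndarray, extractor=None
) -> float:
    """Normalized feature-difference distance; 0 iff the inputs are identical."""
    global _default_extractor
    if extractor is None:
        if _default_extractor is None:
            _default_extractor = RandomFilterBank()
        extractor = _default_extractor
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape:
        raise ValueError("shape mismatch")
    if np.array_equal(pred, ref):
        return 0.0
    fp = extractor.features(pred)
    fr = extractor.features(ref)
    return float(np.mean([np.mean((a - b) ** 2) for a, b in zip(fp, fr)]))


# ---------------------------------------------------------------------------
# lesion segmentation and volumetrics


def reference_cbf(
    cbf_map: np.ndarray,
    brain_mask: np.ndarray,
    region: np.ndarray | None = None,
    lr_axis: int = -1,
) -> float:
    """Healthy-tissue CBF reference for the rCBF ratio.

    Default: the median CBF of the contralateral hemisphere, chosen as the
    hemisphere (split at the midline of ``lr_axis``) with the higher median
    — an ischemic lesion can only lower CBF.  Falls back to the whole-brain
    median when a hemisphere is empty; an explicit ``region`` mask overrides.
    """
    cbf_map = np.asarray(cbf_map, dtype=float)
    if region is not None:
        if not region.any():
            raise ValueError("empty reference region")
        return float(np.median(cbf_map[region]))
    if not brain_mask.any():
        raise ValueError("empty brain mask")
    n = cbf_map.shape[lr_axis]
    sl_left = [slice(None)] * cbf_map.ndim
    sl_right = [slice(None)] * cbf_map.ndim
    sl_left[lr_axis] = slice(0, n // 2)
    sl_right[lr_axis] = slice(n // 2, n)
    medians = []
    for sl in (sl_left, sl_right):
        m = brain_mask[tuple(sl)]
        if m.any():
            medians.append(np.median(cbf_map[tuple(sl)][m]))
    if not medians:
        return float(np.median(cbf_map[brain_mask]))
    return float(max(medians))


def segment_lesions(
    maps: PerfusionMaps,
    reference_cbf_value: float,
    rcbf_frac: float = 0.30,
    tmax_s: float = 6.0,
) -> LesionMasks:
    """Threshold-based lesion segmentation: core = rCBF < 30%,
    hypoperfusion = Tmax > 6 s, applied independently within the brain."""
    if reference_cbf_value <= 0:
        raise ValueError("reference_cbf must be positive")
    core = (maps.cbf / reference_cbf_value < rcbf_frac) & maps.brain_mask
    hypo = (maps.tmax > tmax_s) & maps.brain_mask
    return LesionMasks(core=core, hypoperfusion=hypo, rcbf_frac=rcbf_frac, tmax_s=tmax_s)


def lesion_volume(mask: np.ndarray, voxel_spacing: tuple[float, float, float]) -> float:
    """Mask volume in ml: voxel count x voxel volume (mm^3) / 1000."""
    voxel_mm3 = float(np.prod(voxel_spacing))
    return float(mask.sum()) * voxel_mm3 / 1000.0


def round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def mismatch_ratio(hypo_vol_ml: float, core_vol_ml: float, rounded: bool = True) -> float:
    """Hypoperfusion / core volume ratio, half-up rounded to one decimal
    (the printed convention) unless ``rounded=False``."""
    if core_vol_ml <= 0:
        raise ValueError("mismatch ratio undefined for zero core volume")
    r = hypo_vol_ml / core_vol_ml
    return round_half_up(r, 1) if rounded else r


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A&B|/(|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (a & b).sum() / denom)


# ---------------------------------------------------------------------------
# agreement statistics


def bland_altman(pred_vols, ref_vols) -> tuple[float, float, float]:
    """Mean difference and 95% limits of agreement (mean +- 1.96 sd, n-1 sd)."""
    pred = np.asarray(pred_vols, dtype=float)
    ref = np.asarray(ref_vols, dtype=float)
    if pred.shape != ref.shape or pred.ndim != 1:
        raise ValueError("paired 1D vectors required")
    if len(pred) < 2:
        raise ValueError("need at least 2 pairs")
    d = pred - ref
    m = float(d.mean())
    sd = float(d.std(ddof=1))
    return m, m - 1.96 * sd, m + 1.96 * sd


def icc(pred_vols, ref_vols, alpha: float = 0.05) -> tuple[float, float, float]:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    Computed from the mean squares of the two-way (case x method) layout:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with the 95% CI from the McGraw & Wong F-distribution construction.
    """
    x = np.asarray(pred_vols, dtype=float)
    y = np.asarray(ref_vols, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired 1D vectors required")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    data = np.column_stack([x, y])
    k = 2
    grand = data.mean()
    if np.allclose(data, grand):
        raise ValueError("zero total variance; ICC undefined")
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((data - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))

    value = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    # confidence interval (McGraw & Wong 1996, ICC(A,1))
    fj = msc / mse if mse > 0 else np.inf
    a_ = (k * value) / (n * (1 - value)) if value < 1 else np.inf
    b_ = 1 + (k * value * (n - 1)) / (n * (1 - value)) if value < 1 else np.inf
    if np.isfinite(a_) and mse > 0:
        v_num = (a_ * msc + b_ * mse) ** 2
        v_den = (a_ * msc) ** 2 / (k - 1) + (b_ * mse) ** 2 / ((n - 1) * (k - 1))
        v = v_num / v_den
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        upper = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )
    else:
        lower = upper = value
    return float(value), float(lower), float(upper)


def band_icc(v: float) -> str:
    """ICC interpretation: <0.50 poor, [0.50, 0.75) moderate,
    [0.75, 0.90] good, >0.90 excellent."""
    if v < 0.50:
        return "poor"
    if v < 0.75:
        return "moderate"
    if v <= 0.90:
        return "good"
    return "excellent"


def scc(pred_vols, ref_vols) -> tuple[float, float]:
    """Spearman rank correlation (tie-corrected) with its p-value."""
    x = np.asarray(pred_vols, dtype=float)
    y = np.asarray(ref_vols, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("paired 1D vectors of length >= 3 required")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input; Spearman correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def band_scc(rho: float) -> str:
    """SCC interpretation: >=0.80 excellent, [0.60, 0.80) strong,
    [0.40, 0.60) moderate, <0.40 weak."""
    if rho >= 0.80:
        return "excellent"
    if rho >= 0.60:
        return "strong"
    if rho >= 0.40:
        return "moderate"
    return "weak"


def plot_bland_altman(pred_vols, ref_vols, ax=None, label: str = "volume (ml)"):
    """Bland-Altman plot: per-case mean vs difference with the mean
    difference and 95% limits of agreement drawn as horizontal lines."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    pred = np.asarray(pred_vols, dtype=float)
    ref = np.asarray(ref_vols, dtype=float)
    m, lo, hi = bland_altman(pred, ref)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter((pred + ref) / 2.0, pred - ref, s=18)
    for y, style in ((m, "-"), (lo, "--"), (hi, "--")):
        ax.axhline(y, linestyle=style, color="gray")
    ax.set_xlabel(f"mean {label}")
    ax.set_ylabel(f"difference {label}")
    return ax


def acquisition_dose_fraction(n_phases: int = 3, n_frames: int = 19) -> float:
    """Radiation-dose fraction (%) of acquiring ``n_phases`` of ``n_frames``
    protocol frames, assuming equal per-frame dose: 3 of 19 -> 15.8%."""
    if n_frames <= 0 or n_phases < 0:
        raise ValueError("invalid frame counts")
    return round_half_up(100.0 * n_phases / n_frames, 1)
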