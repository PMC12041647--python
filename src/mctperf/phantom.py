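"""Digital CTP phantom: indicator-dilution simulation with known ground truth.

Each brain voxel's time-density curve is the convolution of a gamma-variate
arterial input with a scaled, delayed residue function,

    c_t(t) = (CBF / kappa) * (c_a (*) R)(t - delay),

so the deconvolution stage can be tested against exact CBF/MTT/delay maps.
With the default box residue the residue maximum sits at the bolus delay,
which makes Tmax recovery (Tmax == delay) directly checkable.
"""

from __future__ import annotations

import numpy as np

from .containers import KAPPA, AIFModel, CTPSeries, PerfusionPhantom


def gamma_variate(t: np.ndarray, model: AIFModel) -> np.ndarray:
    """Gamma-variate enhancement curve evaluated at times ``t`` (s).

    Zero before onset, peaks at ``model.peak_time`` with value
    ``model.amplitude``; an optional recirculation bump adds a delayed,
    scaled copy of the first pass.
    """
    t = np.asarray(t, dtype=float)
    if t.size == 0:
        raise ValueError("empty time grid")

    def first_pass(tt: np.ndarray) -> np.ndarray:
        tau = tt - model.t0
        c = np.zeros_like(tau)
        pos = tau > 0
        x = tau[pos] / (model.alpha * model.beta)
        c[pos] = model.amplitude * x**model.alpha * np.exp(
            model.alpha - tau[pos] / model.beta
        )
        return c

    curve = first_pass(t)
    if model.recirculation_fraction > 0:
        curve = curve + model.recirculation_fraction * first_pass(
            t - model.recirculation_delay
        )
    return curve


def residue_function(
    t: np.ndarray, mtt: float, delay: float, dt: float, family: str = "box"
) -> np.ndarray:
    """Sampled residue function R(t - delay) on a uniform grid.

    ``box``: R = 1 on [delay, delay + mtt); ``exponential``:
    R = exp(-(t - delay)/mtt) for t >= delay.  Both are sampled as exact
    averages over each grid cell [t_i, t_i + dt) so the discrete sum
    integrates to MTT exactly (the central volume theorem holds on the
    grid, not just in the continuum limit).
    """
    t = np.asarray(t, dtype=float)
    if family == "box":
        lo, hi = delay, delay + mtt
        overlap = np.minimum(t + dt, hi) - np.maximum(t, lo)
        return np.clip(overlap / dt, 0.0, 1.0)
    if family == "exponential":
        a = np.maximum(t, delay)
        b = t + dt
        cell = mtt * (np.exp(-(a - delay) / mtt) - np.exp(-(b - delay) / mtt)) / dt
        return np.where(b > delay, np.maximum(cell, 0.0), 0.0)
    raise ValueError(f"unknown residue family {family!r}")


def tissue_curve(
    aif: np.ndarray,
    cbf: float,
    mtt: float,
    delay: float,
    dt: float,
    residue: str = "box",
    kappa: float = KAPPA,
) -> np.ndarray:
    """Tissue enhancement curve c_t = (CBF/kappa) * (c_a (*) R)(t - delay).

    ``aif`` must be sampled on a uniform grid with spacing ``dt`` starting at
    t = 0 of the convolution clock.  CBF is in ml/100 g/min, MTT and delay in
    seconds; kappa converts CBF to 1/s.
    """
    aif = np.asarray(aif, dtype=float)
    if cbf < 0:
        raise ValueError("cbf must be >= 0")
    if cbf > 0 and mtt <= 0:
        raise ValueError("mtt must be positive where cbf > 0")
    if cbf == 0:
        return np.zeros_like(aif)
    t = np.arange(len(aif)) * dt
    r = residue_function(t, mtt, delay, dt, family=residue)
    full = np.convolve(aif, r)[: len(aif)]
    return (cbf / kappa) * dt * full


def default_frame_times() -> np.ndarray:
    """19-frame non-uniform acquisition grid over 52 s.

    2-s spacing around the arterial/venous peaks, 4-s spacing in the tails —
    one shift step of the phase-composition experiment is 2 s, two steps 4 s.
    """
    return np.array(
        [0, 4, 8, 12, 14, 16, 18, 20, 22, 24, 26, 28, 30, 32, 36, 40, 44, 48, 52],
        dtype=float,
    )


def _ellipse_mask(shape_yx, center, semi, rng=None):
    yy, xx = np.mgrid[0 : shape_yx[0], 0 : shape_yx[1]]
    return ((yy - center[0]) / semi[0]) ** 2 + ((xx - center[1]) / semi[1]) ** 2 <= 1.0


def make_phantom(
    shape: tuple[int, int, int] = (2, 64, 64),
    seed: int = 0,
    cbf_healthy: float = 60.0,
    mtt_healthy: float = 4.0,
    delay_healthy: float = 0.5,
    cbf_core: float = 15.0,
    cbf_hypo: float = 40.0,
    mtt_lesion: float = 6.0,
    delay_lesion: float = 8.0,
    voxel_spacing: tuple[float, float, float] = (5.0, 1.0, 1.0),
    with_lesion: bool = True,
) -> PerfusionPhantom:
    """Seeded elliptical brain phantom with core and hypoperfusion lesions.

    The brain is a concentric ellipse per slice; the hypoperfusion lesion is
    a randomly placed ellipse confined to one hemisphere with the core a
    smaller ellipse inside it.  Core voxels get ``cbf_core`` (rCBF 0.25 at
    the defaults), lesion voxels get ``delay_lesion`` so their Tmax sits
    above the 6-s hypoperfusion threshold.
    """
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    brain2d = _ellipse_mask((ny, nx), (ny / 2, nx / 2), (ny * 0.42, nx * 0.42))
    brain = np.broadcast_to(brain2d, shape).copy()

    cbf = np.where(brain, cbf_healthy, 0.0)
    mtt = np.full(shape, mtt_healthy)
    delay = np.full(shape, delay_healthy)
    core = np.zeros(shape, dtype=bool)
    hypo = np.zeros(shape, dtype=bool)

    if with_lesion:
        # lesion confined to the right half (x > nx/2) so the contralateral
        # hemisphere stays lesion-free for the rCBF reference
        cy = rng.uniform(ny * 0.35, ny * 0.65)
        cx = rng.uniform(nx * 0.62, nx * 0.72)
        hsemi = (rng.uniform(ny * 0.14, ny * 0.20), rng.uniform(nx * 0.12, nx * 0.16))
        csemi = (hsemi[0] * rng.uniform(0.55, 0.7), hsemi[1] * rng.uniform(0.55, 0.7))
        hypo2d = _ellipse_mask((ny, nx), (cy, cx), hsemi) & brain2d
        core2d = _ellipse_mask((ny, nx), (cy, cx), csemi) & brain2d
        hypo = np.broadcast_to(hypo2d, shape).copy()
        core = np.broadcast_to(core2d, shape).copy()
        cbf[hypo] = cbf_hypo
        cbf[core] = cbf_core
        mtt[hypo] = mtt_lesion
        delay[hypo] = delay_lesion

    cbf[~brain] = 0.0
    return PerfusionPhantom(
        cbf_map=cbf,
        mtt_map=mtt,
        delay_map=delay,
        core_mask=core,
        hypo_mask=hypo,
        brain_mask=brain,
        voxel_spacing=voxel_spacing,
    )


def sample_phantom(
    shape: tuple[int, int, int] = (2, 64, 64),
    seed: int = 0,
    with_lesion: bool = True,
    voxel_spacing: tuple[float, float, float] = (5.0, 1.0, 1.0),
) -> PerfusionPhantom:
    """Phantom with inter-subject variability.

    Healthy CBF, MTT and arrival delay, and the lesion's CBF/MTT/delay are
    drawn from physiological ranges (healthy CBF 50-70 ml/100 g/min, MTT
    3.5-5.5 s; core rCBF 0.10-0.22 of healthy; lesion bolus delay 7-10 s so
    lesion Tmax clears the 6-s threshold), on top of the randomized lesion
    geometry of :func:`make_phantom`.
    """
    rng = np.random.default_rng(seed)
    cbf_healthy = rng.uniform(50.0, 70.0)
    return make_phantom(
        shape=shape,
        seed=seed + 1,
        cbf_healthy=cbf_healthy,
        mtt_healthy=rng.uniform(3.5, 5.5),
        delay_healthy=rng.uniform(0.0, 1.0),
        cbf_core=cbf_healthy * rng.uniform(0.10, 0.22),
        cbf_hypo=cbf_healthy * rng.uniform(0.55, 0.8),
        mtt_lesion=rng.uniform(5.0, 7.0),
        delay_lesion=rng.uniform(7.0, 10.0),
        voxel_spacing=voxel_spacing,
        with_lesion=with_lesion,
    )


def _roi_indices(brain2d: np.ndarray, nz: int, at: tuple[int, int]) -> np.ndarray:
    """A small 2x2 in-plane ROI replicated across slices, as (N, 3) indices."""
    y0, x0 = at
    idx = []
    for z in range(nz):
        for dy in range(2):
            for dx in range(2):
                idx.append((z, y0 + dy, x0 + dx))
    return np.array(idx, dtype=int)


def simulate_ctp(
    phantom: PerfusionPhantom,
    aif: AIFModel | None = None,
    vof_delay: float = 6.0,
    frame_times: np.ndarray | None = None,
    noise_sd: float = 2.0,
    seed: int = 0,
    baseline_hu: float = 35.0,
    vessel_baseline_hu: float = 45.0,
    residue: str = "box",
    vof_dispersion_s: float = 1.5,
    vof_scale: float = 1.2,
    internal_dt: float = 0.5,
) -> CTPSeries:
    """Render a 4D CTP series (HU) from the phantom's parameter maps.

    Tissue curves follow ``tissue_curve`` on a fine internal grid and are
    sampled at ``frame_times``; AIF-ROI voxels carry the arterial curve and
    VOF-ROI voxels a delayed, Gaussian-broadened, scaled venous copy.
    Additive i.i.d. Gaussian noise in HU; deterministic for a fixed seed.
    """
    if aif is None:
        aif = AIFModel()
    if frame_times is None:
        frame_times = default_frame_times()
    frame_times = np.asarray(frame_times, dtype=float)
    if np.any(np.diff(frame_times) <= 0):
        raise ValueError("frame_times must be strictly increasing")
    rng = np.random.default_rng(seed)

    t_end = frame_times[-1]
    t_fine = np.arange(0.0, t_end + internal_dt, internal_dt)
    aif_curve = gamma_variate(t_fine, aif)

    # venous output: delayed + broadened + scaled arterial curve
    if vof_dispersion_s > 0:
        sig = vof_dispersion_s / internal_dt
        half = int(np.ceil(3 * sig))
        k = np.exp(-0.5 * (np.arange(-half, half + 1) / sig) ** 2)
        k /= k.sum()
        broadened = np.convolve(aif_curve, k, mode="same")
    else:
        broadened = aif_curve
    shift = int(round(vof_delay / internal_dt))
    vof_curve = np.zeros_like(broadened)
    if shift < len(broadened):
        vof_curve[shift:] = vof_scale * broadened[: len(broadened) - shift]

    # tissue curves: phantom maps are piecewise constant, so compute one
    # curve per unique (cbf, mtt, delay) triple and broadcast
    nz, ny, nx = phantom.shape
    data_fine = np.zeros((len(t_fine), nz, ny, nx))
    params = np.stack(
        [phantom.cbf_map, phantom.mtt_map, phantom.delay_map], axis=-1
    ).reshape(-1, 3)
    brain_flat = phantom.brain_mask.ravel()
    uniq, inverse = np.unique(params, axis=0, return_inverse=True)
    flat = data_fine.reshape(len(t_fine), -1)
    for i, (cbf, mtt, dly) in enumerate(uniq):
        sel = (inverse == i) & brain_flat
        if not sel.any() or cbf == 0:
            continue
        flat[:, sel] = tissue_curve(
            aif_curve, cbf, mtt, dly, internal_dt, residue=residue
        )[:, None]

    # sample the fine grid at the acquisition times
    ti = np.searchsorted(t_fine, frame_times)
    ti = np.clip(ti, 0, len(t_fine) - 1)
    data = flat[ti].reshape(len(frame_times), nz, ny, nx).copy()
    data[:, phantom.brain_mask] += baseline_hu

    aif_roi = _roi_indices(phantom.brain_mask[0], nz, (ny // 2 - 1, nx // 2 - 6))
    vof_roi = _roi_indices(phantom.brain_mask[0], nz, (int(ny * 0.72), nx // 2 - 1))
    az, ay, ax = aif_roi.T
    vz, vy, vx = vof_roi.T
    data[:, az, ay, ax] = vessel_baseline_hu + aif_curve[ti][:, None]
    data[:, vz, vy, vx] = vessel_baseline_hu + vof_curve[ti][:, None]

    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=data.shape)

    return CTPSeries(
        data=data,
        frame_times=frame_times,
        voxel_spacing=phantom.voxel_spacing,
        aif_roi=aif_roi,
        vof_roi=vof_roi,
        brain_mask=phantom.brain_mask,
    )
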