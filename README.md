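# mctperf

A toolkit for studying whether brain perfusion maps can be generated from
**three phases of CT perfusion (mCTP)** instead of the full dynamic series.

Acute-stroke triage relies on CT perfusion (CTP): ~19 volumetric scans over
~50 s yield time–density curves that are deconvolved into cerebral blood
flow (CBF) and time-to-maximum (Tmax) maps, from which the ischemic core
(rCBF < 30 %) and the hypoperfused tissue (Tmax > 6 s) are segmented. The
radiation cost is high. The multiphase-CTA protocol suggests an
alternative: acquire only three frames — the arterial-peak frame, the
venous-peak frame, and a delayed frame 8 s later — about 15.8 % of the
protocol dose — and let a conditional GAN translate that 3-phase stack into
the CBF and Tmax maps a full acquisition would have produced.

`mctperf` implements the full study loop on synthetic data with known
ground truth, for researchers in perfusion imaging and medical image
translation:

- **`phantom`** — digital CTP phantom: per-voxel tissue curves
  `c_t = (CBF/κ)·(c_a ⊛ R)(t − delay)` with a gamma-variate arterial input
  `c_a(t) = A·((t−t₀)/αβ)^α e^{α−(t−t₀)/β}`, box or exponential residue
  `R`, lesion geometry, vessel ROIs, Gaussian noise, and the 19-frame
  non-uniform acquisition grid.
- **`preprocess`** — Gaussian smoothing (kernels 7 in-plane / 3 temporal),
  10–80 HU brain masking, linear resampling to a uniform 0.5-s grid,
  affine normalization to [−1, 1].
- **`deconv`** — block-circulant SVD (bSVD) deconvolution with relative
  singular-value truncation; CBF = κ·max k, Tmax = argmax k; plus the
  sparse baseline that interpolates the 3 phases + unenhanced frame to a
  full sequence and deconvolves that.
- **`mctp`** — phase selection at (t_AIF-peak, t_VOF-peak, t_VOF-peak+8 s),
  the ±2 s / ±4 s shifted compositions (Pre-2 … Late-2), and maximum
  intensity projections.
- **`gan`** — the map generator (temporal 3D-conv block + 2D U-Net,
  tanh-bounded) and conditional PatchGAN discriminator, trained with
  least-squares adversarial + masked L1 + quantile-gated "extreme" losses
  on a small numpy autodiff engine (`nn`), Adam(β₁=0.5, β₂=0.999).
- **`evaluation`** — NRMSE/SSIM/perceptual distance, lesion segmentation
  and volumetrics, mismatch ratio (hypo/core), Bland–Altman limits of
  agreement, ICC(2,1) with F-based confidence intervals, Spearman
  correlation, and the standard interpretation bands.
- **`pipeline` / `cli`** — the end-to-end experiment driver (simulate →
  preprocess → deconvolve → select phases → train → predict → evaluate,
  with the 5-way phase-shift sweep) and a thin `mctperf` command-line
  interface; NIfTI + JSON-sidecar I/O in `io`.

## Worked example

```python
from mctperf.phantom import sample_phantom, simulate_ctp
from mctperf.preprocess import smooth, interpolate_time
from mctperf.deconv import DeconvConfig, reference_maps, extract_global_curve
from mctperf.mctp import select_phases
from mctperf.evaluation import (reference_cbf, segment_lesions,
                                lesion_volume, mismatch_ratio)

phantom = sample_phantom(shape=(2, 64, 64), seed=7)
raw = simulate_ctp(phantom, noise_sd=2.0, seed=7)
series = interpolate_time(smooth(raw), target_dt=0.5)

maps = reference_maps(series, DeconvConfig(), mask=phantom.brain_mask)
aif = extract_global_curve(interpolate_time(raw, 0.5), raw.aif_roi)
vof = extract_global_curve(interpolate_time(raw, 0.5), raw.vof_roi)
triplet = select_phases(series, aif, vof)
print("mCTP phase times (s):", triplet.phase_times)

ref = reference_cbf(maps.cbf, phantom.brain_mask)
lesions = segment_lesions(maps, ref)
core_ml = lesion_volume(lesions.core, phantom.voxel_spacing)
hypo_ml = lesion_volume(lesions.hypoperfusion, phantom.voxel_spacing)
print(f"core {core_ml:.1f} ml, hypo {hypo_ml:.1f} ml,",
      "mismatch", mismatch_ratio(hypo_ml, core_ml))
```

prints

```
mCTP phase times (s): [12. 18. 26.]
core 0.9 ml, hypo 2.9 ml, mismatch 3.4
```

The phases sit at the arterial peak (12 s), the venous peak (18 s) and
8 s after it; the deconvolved maps segment a 0.9 ml core (true extent
1.3 ml — partial-volume blur from the 7-voxel smoothing kernel erodes the
small desk-scale core) inside a 2.9 ml hypoperfused region (truth 3.1 ml),
a mismatch ratio of 3.4 (ratios are rounded half-up to one decimal from the unrounded volumes, so the printed 2.9/0.9 reads 3.4).

A full experiment, including GAN training and the five phase compositions:

```bash
mctperf run-all --seed 1 --out runs/demo
```

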