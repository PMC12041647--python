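# Methods

This note documents the models, numerical choices and limitations behind
`mctperf`. The package simulates multiphase CT perfusion (mCTP) studies,
computes reference perfusion maps by deconvolution, trains a conditional
GAN to generate those maps from three acquisition phases, and quantifies
agreement between generated and reference maps.

## Indicator-dilution phantom

Each brain voxel's time–density curve follows the indicator-dilution
model

    c_t(t) = (CBF / κ) · (c_a ⊛ R)(t − delay),

with `c_a` a gamma-variate arterial input
`c_a(t) = A·((t−t₀)/(αβ))^α·exp(α − (t−t₀)/β)` (zero before onset `t₀`,
peak `A` at `t₀ + αβ`; defaults t₀ = 8 s, α = 3, β = 1.5 s, A = 150 HU —
the canonical simulation AIF shape for perfusion deconvolution studies —
with an optional recirculation bump). The residue function `R` is a box
(`R = 1` on `[0, MTT)`, default) or a decaying exponential; both are
sampled as exact per-cell averages so the central volume theorem
`∫c_t = CBF·MTT/κ·∫c_a` holds on the grid to rounding, not just in the
continuum limit. The unit constant is κ = 100·60, i.e. CBF in
ml/100 g/min with time in seconds; tissue density corrections are omitted
because every threshold the package applies is relative (rCBF) or
temporal (Tmax). With the box residue the true residue maximum is first
attained at `t = delay`, which makes Tmax recovery exactly testable.

The phantom geometry is a concentric-ellipse brain with a randomly placed
elliptical hypoperfusion lesion confined to one hemisphere and a deeper
core ellipse inside it. `sample_phantom` draws per-subject physiology
from realistic ranges: healthy CBF 50–70 ml/100 g/min, healthy MTT
3.5–5.5 s, arrival delay 0–1 s; lesion bolus delay 7–10 s (so lesion Tmax
clears the clinical 6-s threshold), lesion MTT 5–7 s, penumbral CBF
0.55–0.8 and core CBF 0.10–0.22 of the subject's healthy CBF. The core is
drawn deep and relatively large (55–70 % of the lesion semi-axes) because
at the desk-scale 64×64 matrix the 7-voxel smoothing kernel is coarse
relative to lesion size, and partial-volume blur would otherwise erase a
thin core from the rCBF segmentation — a deliberate scale correction so
lesion-to-PSF proportions resemble clinical 512×512 data.

Acquisition uses a 19-frame non-uniform grid over 52 s (2-s spacing
around the arterial/venous peaks, 4-s tails), matching the 2 s / 4 s
steps of the phase-composition experiment. AIF/VOF regions are small 2×2
in-plane vessel ROIs carrying the arterial curve and a delayed (6 s),
Gaussian-broadened (σ = 1.5 s), scaled (1.2×) venous copy. Noise is
i.i.d. Gaussian in HU, default σ = 2 HU (the scanners' noise level is a
free parameter; 2 HU after the protocol's heavy spatial smoothing is a
realistic effective level). Everything is deterministic given a seed.

## Preprocessing

Spatial smoothing uses a discrete Gaussian window of 7 voxels in-plane
and 3 frames along time. The Gaussian σ is kernel/6 (±3σ spans the
window) and the filter is truncated to the window radius, so a kernel of
1 is the identity. Brain masking keeps [10, 80] HU and the largest
connected component. Temporal resampling is per-voxel linear
interpolation to a uniform 0.5-s grid spanning the acquisition window.
Intensities are clipped then affinely mapped to [−1, 1]; CTP inputs use
fixed [0, 100] HU bounds.

Arterial and venous global curves are extracted from the **unsmoothed**
(but temporally resampled) series: vessel curves are high-SNR, and the
7-voxel kernel would dilute a 2×2 vessel ROI with surrounding tissue,
deflating the AIF and inflating every CBF value by the same factor.
Frame-to-frame registration is not simulated and therefore not
implemented; the interfaces accept pre-registered series.

## Block-circulant SVD deconvolution

The AIF is zero-padded to `L = 2T` (padding factor 2 avoids wrap-around
of late residue mass), embedded as a circulant matrix
`A[i,j] = dt·c_a[(i−j) mod L]`, and inverted through its SVD with
singular values below `λ_svd·σ_max` zeroed. The circulant embedding makes
the estimate delay-insensitive in amplitude: a bolus delay appears as a
shift of the recovered `k(t) = (CBF/κ)·R(t−delay)`, so
`Tmax = argmax k` tracks the delay while `CBF = κ·max k` is preserved.
`CBV = 100·∫c_t/∫c_a` (ml/100 g) and `MTT = 60·CBV/CBF` (s) are computed
for completeness; the generation pipeline uses only CBF and Tmax.

Two numerical choices matter:

* **Truncation level.** Truncation exists to regularize measurement
  noise. The default `λ_svd = 0.1` is standard practice for noisy data,
  but at that level only ~15 % of the AIF spectrum survives, so a
  noiseless inversion is visibly band-limited: deconvolving a curve by
  itself yields a smeared bump rather than a discrete delta, and a box
  residue's argmax is biased toward `delay + MTT/2`. The noiseless
  oracle-recovery suite therefore runs at `DeconvConfig.NOISELESS_LAMBDA
  = 1e-4` (essentially exact inversion — there is nothing to
  regularize), while all noisy-data processing keeps 0.1.
* **Tmax tie-break.** An exactly recovered box residue is flat on its
  plateau up to float rounding; Tmax is read as the earliest sample
  within a relative tolerance of 1e-6 of the maximum. Under noise this
  reduces to the plain earliest argmax.

On the noiseless 20-voxel grid (CBF ∈ {10…80} ml/100 g/min × delay ∈
{0…6} s, box residue, MTT 4 s, dt 0.5 s) the inversion recovers delay and
flow to machine precision; the test suite asserts the median Tmax error
≤ 0.5 s and median relative CBF error ≤ 10 %.

### The interpolated-mCTP baseline

The deconvolution baseline joins the first unenhanced frame with the 3
mCTP phases, linearly interpolates each voxel onto the uniform grid —
truncated at the delayed phase, since linear interpolation is undefined
beyond the last acquired point — and applies the same bSVD. Its AIF is,
by default, extracted from the interpolated 4-phase volume; the pipeline
instead passes the full-series arterial curve seen through the same
4-point sampling, so reference and baseline share AIF provenance and
differ *only* in temporal sampling density. On cohorts of long-delay
lesions this baseline systematically inflates the hypoperfused
(Tmax > 6 s) volume relative to the full-series reference: the sparse
triangular AIF carries apparent early mass, shifting apparent tissue
delays upward. The per-voxel lesion Tmax bias is small (a few tenths of a
second either way depending on processing details), so the package's
direction check is stated on the hypoperfusion **volume**, the statistic
with the robust and clinically reported direction.

## mCTP phase selection

Phases sit at (t_AIF-peak, t_VOF-peak, t_VOF-peak + 8 s) — the venous
delay is configurable (multiphase CTA uses 4 s between table moves; the
mCTP protocol default is 8 s) — snapped to the nearest frame of the
uniform grid, earlier frame on ties. Peak finding returns the earliest
global maximum. The composition experiment shifts **all three phases
jointly** by ±1 or ±2 steps of 2 s (the protocol text is ambiguous on
whether only the arterial phase moves; joint shifts are this package's
interpretation, labelled Pre-2 … Late-2).

## The map-generation GAN

The generator consumes the 3 normalized phase images as an N×N×3 stack:
two 3×3×3 convolutions act along the depth/phase axis (the first
depth-padded, the second valid, collapsing 3 → 1 channel stack) to
extract temporal contrast, followed by a 2D U-Net (stride-2 4×4
downsampling convolutions, nearest-neighbour upsampling with skip
concatenation) and a tanh-bounded single-channel head. The discriminator
is a conditional PatchGAN over the concatenated (phases, map) stack with
two stride-2 convolutions (patch grid = input/4). One model is trained
per target map (CBF or Tmax).

The generator objective is

    L = w_pix·L1(pred, true | brain) + w_adv·L_LSGAN + w_ext·L1(pred, true | extreme)

with least-squares adversarial loss (chosen for stability at small batch
counts), masked L1 pixel loss, and an "extreme" term restricted to brain
voxels whose target value lies below the 0.10 or above the 0.90 in-mask
quantile — steering capacity toward infarcted (low-CBF) and high-flow /
long-Tmax tissue. Defaults w_pix = 100, w_adv = 1, w_ext = 50. An empty
extreme region contributes zero.

Training uses Adam(β₁ = 0.5, β₂ = 0.999). The full-scale defaults follow
the clinical protocol scale (N = 512, batch 15, learning rate 1e-4,
85 epochs for CBF / 80 for Tmax). The networks are built on `mctperf.nn`,
a small reverse-mode autodiff engine over numpy arrays written for this
package (strided im2col convolution, upsampling, concatenation,
LeakyReLU/tanh, Adam), gradient-checked against central finite
differences in the test suite.

### Desk-scale benchmark conditions

The standing benchmark (`mctperf.benchmark.scaled_gan_benchmark`) uses
200 synthetic 64×64 slices (100 two-slice phantoms; 75 % train / 25 %
validation split by case) and 30 epochs per model. At this scale the
configuration is adapted to the optimizer-step budget: base width 8,
2 U-Net levels, batch 5 and learning rate 2e-3 (≈ 900 Adam steps; the
full-scale 1e-4 would leave the model far from convergence inside
30 epochs). Target maps are normalized with fixed bounds persisted from
training-set statistics: [0, 97.5th percentile] of in-brain values for
CBF (in-brain vessel voxels and their smoothing halo deconvolve an order
of magnitude above parenchyma) and [0, 99.5th percentile] for Tmax (the
top decile of Tmax *is* the lesion signal, so the robust bound must sit
above it). The benchmark reports validation SSIM of generated CBF against
a mean-training-image predictor, and NRMSE of generated vs reference Tmax
inside the reference hypoperfusion region against the interpolated-mCTP
deconvolution baseline.

## Evaluation

* **NRMSE** — RMSE over mask voxels divided by the reference's in-mask
  range (asymmetric by construction; constant references are an error).
* **SSIM** — scikit-image's windowed SSIM averaged over the mask.
* **Perceptual distance** — by default a fixed-seed multi-scale random
  filter bank (12 zero-mean unit-norm 5×5 filters at dyadic scales 1/2/4,
  plus an identity channel guaranteeing distance 0 iff inputs are
  identical, with channel-normalized features); any extractor exposing
  `features(img)` — e.g. a pretrained backbone — can be plugged in to
  reproduce published deep perceptual metrics.
* **Lesion segmentation** — core: rCBF < 0.30; hypoperfusion:
  Tmax > 6 s; applied independently (a voxel can be core without being
  hypoperfused; clinically reported cases show core volumes exceeding
  hypoperfusion volumes). The rCBF denominator is the median CBF of the
  contralateral hemisphere, chosen as the midline-split half with the
  higher median (ischemia only lowers CBF); whole-brain median is the
  fallback, and an explicit region mask overrides.
* **Volumetrics** — volumes in ml from voxel counts × spacing; mismatch
  ratio = hypoperfusion/core volume, half-up rounded to one decimal (the
  printed convention); Dice with the both-empty = 1 convention.
* **Agreement** — Bland–Altman mean difference with 1.96·sd (n−1) limits;
  ICC(2,1) (two-way random effects, absolute agreement, single rater)
  from the two-way ANOVA mean squares with the McGraw–Wong F-construction
  CI; Spearman rank correlation. Interpretation bands: ICC < 0.50 poor,
  [0.50, 0.75) moderate, [0.75, 0.90] good, > 0.90 excellent; SCC ≥ 0.80
  excellent, [0.60, 0.80) strong, [0.40, 0.60) moderate, < 0.40 weak.
  Published band boundaries overlap ambiguously; boundaries here are
  lower-inclusive, matching every reported label.

## What the synthetic cohort does and does not show

The phantom reproduces the *mechanisms* the pipeline must handle —
indicator-dilution kinetics, delayed/dispersed venous outflow, lesions
defined by the clinical thresholds, acquisition-grid sparsity, additive
noise — with exact ground truth. It does not emulate patient motion,
beam hardening, contrast pharmacokinetics beyond the gamma-variate bolus,
correlated noise, anatomical texture, or registration error. Passing
tests therefore demonstrate correctness of the algorithms and the
direction of sampling-induced biases, not clinical-grade performance;
the headline clinical similarity levels depend on hospital data and
full-scale training outside this package's scope.

## Known limitations

* The exact published "extreme loss" formula is unavailable; the
  quantile-gated L1 documented above is this package's stand-in honoring
  its stated intent.
* The discriminator is assumed conditional (scores (phases, map) pairs);
  an unconditional variant is not provided.
* Desk-scale maps are 64×64; clinical-scale 512×512 settings exist in the
  configs but are not exercised by the test suite.
* bSVD recovery accuracy at the noisy-data truncation level (λ = 0.1)
  carries the documented band-limiting biases; quantitative recovery
  claims are made only for the noiseless setting.
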