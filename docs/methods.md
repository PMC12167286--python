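# Methods

## Problem setting

Surgical hyperspectral imaging (HSI) records a reflectance spectrum
(here 100 bands, 500–1000 nm at full scale) at every pixel, but annotated
surgical HSI datasets are scarce and cannot be pooled with data from other
modalities. This package implements cross-modality *geometric* knowledge
transfer: a latent diffusion model (LDM) converts a semantic segmentation
mask — obtainable from any modality — into a realistic labeled
hyperspectral image, and the synthesized pairs are used as generative
augmentation for training segmentation models.

Because no suitable public surgical HSI dataset exists, everything is
exercised end-to-end on synthetic hyperspectral phantoms whose statistical
structure mirrors the real setting (see "Phantom generator" below).

## Autoencoder

A KL-regularized variational autoencoder compresses cubes both spatially
(strided convolutions, factor `f`, a power of two) and spectrally
(C bands → `latent_channels`). The training loss is

    L = recon(x, x̂) + λ_KL · KL(q(z|x) ‖ N(0, I))

with a pixelwise L1 reconstruction term by default and a diagonal-Gaussian
posterior. There is intentionally **no perceptual loss** (ImageNet feature
extractors do not apply to 25–100-band reflectance data) and **no
adversarial loss** (it adds instability without measurable reconstruction
benefit here). `λ_KL` defaults to 1e-6: the latent is used as a compression
code for the diffusion stage, not as a generative prior, so only a weak pull
toward unit scale is wanted; lower values consistently favor reconstruction
quality.

Numerical conventions:

* posterior `logvar` is clamped to [−30, 20];
* after training, the global standard deviation of sampled training latents
  is computed once and `scale_factor = 1/std` is stored with the model; the
  diffusion model operates on `z · scale_factor`, so its variance-preserving
  schedule sees approximately unit-scale data;
* encoder/decoder are deterministic at inference (posterior mean is used
  for reconstruction).

The desk-scale architecture is a strided-conv encoder and nearest-neighbour
upsample + conv decoder (width 16 by default) with an extra full-resolution
convolution at each end: reconstruction error concentrates at class
boundaries (the familiar autoencoder blur), and sub-patch boundary position
must survive the spatial compression. Training uses Adam with cosine
learning-rate decay and optional EMA weight averaging (neutral for the AE;
see "Design choices" for why the diffusion model does not use it).

## Conditional diffusion model

A standard variance-preserving diffusion model in the autoencoder's latent
space: T = 200 steps at phantom scale (1000 at full scale), linear β
schedule from 1e-4 to 2e-2, ε-prediction U-Net trained with MSE on
uniformly sampled timesteps. Domain-specific pieces:

* **Conditioning.** The one-hot segmentation mask is rescaled to the
  (padded) latent resolution with nearest-neighbour sampling — labels are
  identities and must never be interpolated — then passed through a single
  learned 3×3 convolution to `cond_channels` channels. The resulting
  condition tensor is concatenated to `z_t` at **every** denoising step; it
  is computed once per sampling run since it is time-independent.
* **Classifier-free guidance.** During training the condition tensor is
  replaced by the all-zeros tensor with probability `p_drop = 0.1`, so the
  network also learns the unconditional score. At sampling time
  `ε̂ = ε_u + λ·(ε_c − ε_u)` with guidance scale λ = 2 by default. The null
  condition is defined as the zero tensor (not a learned embedding): the
  simplest contract consistent with concatenation conditioning, and one
  that tests can target exactly.
* **Padding.** Non-square latents are zero-padded to the next multiple of
  2^d (d = number of U-Net downsamplings) so every downsampling level sees
  even resolutions; the crop box is recorded and applied after sampling.
* **Sampling.** Accelerated deterministic reverse process (η = 0) over a
  uniformly spaced decreasing timestep subsequence that always includes T;
  50 steps at phantom scale, 100 at full scale. At η = 0 the whole sampler
  is a pure function of (weights, mask, seed). At guidance scale exactly 1
  the unconditional pass is skipped (the combination is the identity).
  The predicted clean latent x̂₀ is clamped to ±2 before re-noising
  (latents are standardized to unit scale): guidance otherwise pushes the
  trajectory off the latent manifold, which showed up as a systematic
  spectral bias in decoded cubes.
* **Schedule scaling.** The linear β range (1e-4 → 2e-2) is calibrated for
  T = 1000; at other T the recipe scales β by 1000/T so the continuous-time
  schedule — in particular terminal ᾱ_T ≈ 0, i.e. the pure-noise start the
  sampler assumes — is preserved.

The U-Net is compact: width 32, two downsamplings, residual blocks with
GroupNorm and a sinusoidal-time-embedding bias, and a zero-initialized
output convolution (an untrained model predicts exactly zero noise). Depth
mattered more than width in development: two downsamplings at 16×16 latents
gave markedly better conditional fidelity than one downsampling at larger
width for the same compute.

## Mask augmentation and OoD conditioning

`masks_augment` implements the geometric pipeline used when training the
synthesis model on few labeled images: rescaling (0.9–1.1), rotation
(±15°), random crop, random horizontal flip, and label dropout (whole class
regions replaced, not random pixels — region-level dropout keeps the mask a
plausible segmentation). The identical geometric transform is applied to
cube (bilinear) and mask (nearest-neighbour); resampling voids get a fresh
**fill label** (max legend id + 1, guaranteed outside the legend) in the
mask and zero reflectance in the cube.

For cross-modality conditioning, `reassign_ood_labels` maps every label the
synthesis model was not trained on to the background class; the operation
is idempotent. This is how occlusion-style masks (hands, instruments) from
another modality become usable conditioning.

In the desk-scale diffusion recipe, training-time augmentation is **off by
default**: at the fixed 3000-step budget the 4×-enlarged augmented problem
is undertrained and conditional fidelity drops; the pipeline is available
(`n_augment` in the recipe, `masks_augment` in general) and becomes
appropriate with proportionally longer training.

## Phantom generator

The generator produces labeled scenes with the statistical structure the
method assumes:

* **Spectra.** Each class has a smooth reference spectrum on a 500–1000 nm
  axis: a sigmoidal reflectance edge (randomized position/width/levels)
  with 1–3 multiplicative Gaussian absorption dips. Multiplicative dips
  keep reflectance positive and band-to-band relative change bounded.
  Class 0 is a flat-ish background cloth. Libraries are regenerated until
  all pairwise ℓ1 distances between ℓ1-normalized spectra exceed 0.05
  (bounded retries).
* **Geometry.** Organs are random smooth blobs: ellipses with low-order
  Fourier boundary perturbation — plausible silhouettes with controllable
  area and no external atlas.
* **Hierarchy.** Each subject carries one shared multiplicative gain
  (log-normal, σ = 0.1), giving multiple images per subject the
  within-subject correlation that hierarchical aggregation and
  subject-level bootstrapping exist for.
* **Noise model.** Pixel spectrum = class reference × subject gain × smooth
  illumination field × (1 + N(0, σ_m²)) + N(0, σ_a²), clipped at zero;
  defaults σ_m = 0.05, σ_a = 0.01, illumination amplitude 0.1.
* **OoD variants.** `occlusion` overlays a multi-lobed hand or elongated
  instrument shape carrying a reserved occluder class (always the last
  library entry, never sampled as an organ); `isolation` renders a single
  organ surrounded by background; `blur` convolves the cube spatially with
  a Gaussian (σ = 1.5 px).

What the phantoms do **not** emulate: physically based tissue optics
(hemoglobin/water absorption), specular highlights, camera spatial
covariance, organ-internal texture, or anatomical layout. Passing tests on
phantoms therefore demonstrates that the pipeline's machinery — compression,
conditional synthesis, guidance, metrics, statistics — works as specified,
not that synthesis quality transfers to real surgical scenes.

## Evaluation conventions

* **Spectral agreement** (synthesis realism): per image the median
  ℓ1-normalized pixel spectrum over a class's pixels; per subject the mean
  of its image spectra; across subjects mean and std (std is zero by
  convention with a single subject). Agreement between datasets is the ℓ1
  distance between aggregated class spectra.
* **DSC** = 2|P∩G| / (|P|+|G|); undefined (NaN) when both masks lack the
  class. **NSD**: boundary = region pixel with an 8-connected neighbour
  outside the region, image-border pixels count as boundary; Euclidean
  pixel distances; tolerance τ = 2 px at phantom scale. These conventions
  are fixed because NSD values are meaningless across differing boundary
  definitions.
* **Hierarchical aggregation**: mean over subjects of per-subject means;
  undefined records are excluded before averaging, never zero-filled
  (zero-filling biases per-class means).
* **Bootstrap CIs** on model differences: subjects resampled with
  replacement (paired across models), percentile interval (the simplest
  auditable variant), 1000 resamples, 95% level. Coverage is verified
  empirically in the test suite (20 subjects, known difference 0.1, noise
  0.05 → ~94% coverage).
* **RGB reconstruction** for visual inspection integrates fixed wavelength
  windows (R 620–650, G 540–570, B 500–520 nm), jointly max-normalizes and
  gamma-encodes (1/2.2). The sensor starts at 500 nm, so there is no true
  blue band; the rendering is a documented non-colorimetric stand-in.

## Downstream study design

The reproducible phantom study (in `hsisynth.recipes`, shared by the test
suite and `scripts/acceptance.py`) uses:

* a 200-scene corpus (10 subjects × 20 images, 32×32×25 bands, 3 organ
  classes) — nine subjects train the VAE and diffusion model, the tenth is
  held out for reconstruction error;
* synthesis fidelity measured on 50 freshly rendered masks (ℓ1 distance of
  synthesized vs. library class spectra);
* a 3-arm experiment (Baseline / Synthetic / Enhanced) on occlusion
  phantoms. The Baseline uses 8 real occlusion-free images from 2 subjects:
  generative augmentation targets the scarce-annotation regime, and the
  effect scales inversely with baseline data (with 16+ real images the
  baseline saturates at this problem size and the augmentation difference
  falls below CI resolution). Enhanced adds 48 synthetic images conditioned
  on occlusion-style masks (guidance 3.0 — stronger conditioning adherence
  measurably sharpens mask-following geometry) whose occluder labels were
  reassigned to background; the Synthetic arm uses exactly as many
  synthetic images as the Baseline has real ones. Testing uses 8 fresh
  subjects × 6 occlusion scenes; DSC/NSD are aggregated hierarchically and
  compared with subject-level bootstrap CIs across 5 segmenter seeds.

An upper bound for this design: adding 16 *real* occlusion scenes instead
of synthetic ones raises occlusion-set DSC by ≈ +0.09 consistently — the
geometric deficit is learnable, and the gap between that oracle and the
synthetic-augmentation gain is the cost of synthesis imperfection
(principally autoencoder blur, a known limitation of latent synthesis).

The segmenter is a compact U-Net (width 12, two downsamplings) over all
bands with per-pixel ℓ1 spectral normalization (standard HSI preprocessing;
removes brightness nuisance), GroupNorm, and a cross-entropy + soft-Dice
loss (the Dice term counteracts background/organ imbalance). All arms share
seeds, architecture and schedule so differences reflect training data only.

## Design choices and numerical notes

* EMA weight averaging is on for the VAE (neutral) but **off** for the
  diffusion model: at 3000 steps the averaging window spans a
  still-improving trajectory and measurably degrades sampling quality.
* Adam (β₁ = 0.9, β₂ = 0.999) with cosine decay to 5–10% of the base rate
  everywhere; training aborts on non-finite loss.
* Convolutions run on a small numpy reverse-mode autodiff engine
  (`hsisynth.nn`) written for this package; forward and backward are one
  tensordot per kernel offset (no im2col buffer). Gradients are verified
  against finite differences in the test suite.
* Sigmoid/SiLU use the sign-split stable form; log-softmax uses the
  max-shift form with the shift treated as a constant.
* ENVI I/O is fixed to one dialect (BSQ, float32, nm) to avoid silent
  unit/interleave drift; masks are 8-bit PNG with a JSON legend sidecar so
  they remain viewable in image tools.

## Known limitations

* Phantom realism as above; absolute metric values on phantoms do not
  transfer to surgical data.
* The numpy engine is single-threaded and desk-scale; paper-scale training
  (10⁴ images at 640×480×100) is out of scope.
* The synthesized images inherit autoencoder blur; the downstream gain from
  synthetic augmentation is correspondingly smaller than the real-data
  oracle bound.
* DSC/NSD are the only segmentation metrics; generative-model scores of the
  FID family are deliberately not implemented (their feature extractors are
  undefined for HSI and their pitfalls are well documented).
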