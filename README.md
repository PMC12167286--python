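# hsisynth

Semantic hyperspectral image synthesis with latent diffusion models, and a
complete evaluation harness for using such synthesis as **generative
augmentation** in surgical scene segmentation.

## The problem

Surgical hyperspectral imaging (HSI) records a reflectance spectrum at every
pixel (≈100 bands, 500–1000 nm), enabling tissue discrimination beyond RGB —
but annotated surgical HSI data is scarce, and annotations made on *other*
modalities cannot be used directly because the pixel data is incompatible.
The geometry in a segmentation mask, however, is modality-agnostic. This
package implements cross-modality geometric knowledge transfer: a
mask-conditioned latent diffusion model (LDM) turns any semantic
segmentation mask into a realistic labeled hyperspectral cube, and the
synthesized pairs augment the training set of a segmentation model.

It is aimed at surgical data-science researchers who want to study
mask-to-HSI synthesis, its spectral fidelity, and its downstream value,
without access to proprietary clinical data: a phantom generator produces
labeled hyperspectral scenes with the relevant statistical structure
(per-class smooth reflectance spectra, subject-level gain hierarchy, sensor
noise, and geometric out-of-distribution variants — occlusion, isolation,
blur), so the entire pipeline runs end-to-end on a laptop.

## The method

1. **Spatio-spectral KL-VAE.** A variational autoencoder compresses a cube
   H×W×C → (H/f)×(W/f)×c latents (f = 2, c = 4 at phantom scale; f = 4,
   c = 8 at full scale), trained with a pixelwise L1 loss plus a tiny KL
   term λ_KL‖·‖ (default 1e-6); no perceptual or adversarial losses.
   Latents are standardized by a stored global scale factor.
2. **Conditional diffusion in latent space.** A variance-preserving
   diffusion model (linear β schedule, ε-prediction U-Net, T = 200 at
   phantom scale) is trained on the frozen VAE's latents. The one-hot mask
   is nearest-neighbour rescaled to latent resolution, passed through a
   single learned convolution, and concatenated to z_t at every denoising
   step; condition dropout (p = 0.1) also teaches the unconditional score.
3. **Guided sampling.** Deterministic DDIM (η = 0, 50–100 steps) with
   classifier-free guidance ε̂ = ε_u + λ_CFG (ε_c − ε_u), λ_CFG = 2, and
   x̂₀ clipping on the standardized latents. Non-square latents are
   zero-padded to U-Net-friendly sizes and cropped back after sampling.
4. **Validation.** ℓ1-normalized class spectra with hierarchical
   (image → subject → population) aggregation; Dice similarity coefficient
   and normalized surface distance with documented boundary conventions;
   subject-level percentile-bootstrap confidence intervals on model
   differences; and a 3-arm downstream experiment (Baseline / Synthetic /
   Enhanced) testing whether occlusion-conditioned synthetic images improve
   segmentation on occlusion scenes the baseline never saw.

See `docs/methods.md` for assumptions, parameter choices, and limitations.

## Worked example

```python
import numpy as np
from hsisynth import recipes

# 200 labeled phantom scenes: 10 subjects x 20 images, 32x32x25 bands
config, library, train, heldout = recipes.phantom_corpus(seed=1)

ae = recipes.train_study_ae(train, seed=1)          # KL-VAE, f=2, c=4
err = recipes.reconstruction_error(ae, heldout)
print(f"held-out median relative reconstruction error: {100*err:.2f}%")

dm = recipes.train_study_dm(ae, train, seed=1)      # conditional LDM, T=200
masks = recipes.heldout_masks(config, library, seed=1, n=50)
synth = recipes.synthesize(dm, ae, masks, library, seed=8)
dists = recipes.spectral_recovery_distances(synth, library)
for cls, d in sorted(dists.items()):
    print(f"class {cls} ({library.class_names[cls]}): "
          f"synthetic-vs-reference spectral l1 distance = {d:.4f}")
```

Output from this exact snippet (about 15 minutes on one CPU core):

```
held-out median relative reconstruction error: 4.45%
class 0 (background): synthetic-vs-reference spectral l1 distance = 0.0009
class 1 (organ_1): synthetic-vs-reference spectral l1 distance = 0.0171
class 2 (organ_2): synthetic-vs-reference spectral l1 distance = 0.0154
class 3 (organ_3): synthetic-vs-reference spectral l1 distance = 0.0061
```

Reading it: the autoencoder reconstructs held-out cubes to within ~4.5% per
pixel (the phantom's own noise floor is ≈4.1%, so the model itself adds
little); and images synthesized from masks the model never saw reproduce
every class's normalized reflectance spectrum to within ≈0.02 in ℓ1 — the
synthesis is spectrally faithful, not just visually plausible.

The command-line interface exposes the same pipeline as subcommands
(`hsisynth phantom`, `train-ae`, `train-dm`, `synth`, `eval-spectra`,
`eval-seg`, `downstream`); every run writes a `manifest.json` with the
resolved configuration and seeds.

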