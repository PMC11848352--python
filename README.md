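# pseudopet

Conditional diffusion synthesis of a functional (FDG-PET-like) brain view
from a structural (T1-weighted-MRI-like) view, with the two deterministic
synthesis strategies — **one-way** and **two-way** — an image-similarity
evaluation suite, and an atlas-feature MLP ensemble that tests whether the
synthesized view improves multi-view disease-stage (NC/MCI/AD)
classification.

## Why

FDG PET reflects cerebral glucose metabolism and is valuable for staging
neurodegeneration, but it is expensive and often inaccessible, while
structural MRI is routine. If a model can synthesize a faithful pseudo-PET
view from MRI, a classifier can exploit both views at MRI-only cost. This
package implements that idea end to end on synthetic phantom cohorts that
emulate preprocessed (skull-stripped, co-registered, tissue-segmented)
scan pairs, so every component is testable on a laptop CPU.

## The model

A denoising diffusion model corrupts the functional channel over `T` steps,

    x_t = sqrt(ᾱ_t) x_0 + sqrt(1 − ᾱ_t) ε,      ᾱ_t = Π_{s≤t} (1 − β_s),

while the structural image rides along as a clean condition channel.
A U-Net `Diff(x_t ‖ x_MRI, emb)` predicts the noise ε and is trained with a
brain-masked MSE,

    L = mean( Mask_brain ⊙ (ε − Diff(...))² ).

Conditioning enters through one *final embedding*: a 512-dimensional
sin-cos time-step embedding (first half sine, second half cosine, maximum
period 10,000), deepened by a two-layer fully connected stack, plus a
learnable per-modality **class embedding** that steers whether the network
denoises toward the structural or the functional modality.

Sampling uses the generalized update with stochasticity σ_t set to 0
(deterministic, strided over a sub-sequence of steps):

* **one-way** — denoise fresh Gaussian noise conditioned on the MRI with
  the PET class embedding (seeded; different seeds give different
  outputs);
* **two-way** — deterministically *invert* the MRI into its latent noise
  with the MRI class embedding, then decode that latent with the PET class
  embedding; bit-reproducible, zero random draws.

Synthesized volumes are scored against ground truth with MAE, MSE, ZNCC,
global-statistics SSIM (k1 = 0.01, k2 = 0.03, L = 1) and PSNR, all on
0–1-normalized images. Downstream, per-atlas-region features (non-zero
voxel counts for structural, regional sums for functional) feed one small
MLP per (modality, tissue-segment) branch; branch probabilities are
averaged into the final prediction, and subject-level k-fold
cross-validation compares view combinations.

The network, its embedding machinery, and the training loop are
implemented in numpy with hand-written backpropagation (`pseudopet.nn`);
no deep-learning framework is required.

## Worked example

```python
from pseudopet.benchmark import synthesis_benchmark

r = synthesis_benchmark(seed=1, n_train=60, n_test=6, epochs=30,
                        base_width=8, learning_rate=2e-3)
print(f"two-way SSIM  {r.mean('two_way', 'ssim'):.3f}")
print(f"one-way SSIM  {r.mean('one_way', 'ssim'):.3f}")
print(f"baseline SSIM {r.mean_baseline_ssim:.3f}")
```

which prints (about two minutes on one CPU core):

```
two-way SSIM  0.991
one-way SSIM  0.991
baseline SSIM 0.668
```

This trains the noise predictor on 60 phantom pairs and scores 6 held-out
subjects. The `two-way`/`one-way` numbers are the mean structural
similarity between synthesized and true functional images; `baseline` is
the SSIM of the structural image itself against the true functional image
— the score synthesis must beat for the pseudo-view to add information
beyond the input. Here both strategies reconstruct the held-out
functional images almost perfectly (SSIM ≈ 0.99) while the raw structural
image only reaches 0.67.

The full pipeline (generate → train → synthesize → evaluate →
cross-validate) also runs from the command line:

```bash
pseudopet generate-data --n-subjects 30 --shape 64,64 --seed 1 --out-dir runs/demo/data
pseudopet run-all --seed 1 --out-dir runs/demo
```

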