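# Methods

This note documents the models, numerical choices, and study conditions
behind `pseudopet`: a conditional diffusion model that synthesizes a
functional (FDG-PET-like) brain view from a structural (T1-MRI-like) view,
the similarity criteria used to evaluate the synthesis, and the
atlas-feature MLP ensemble used to test whether the synthesized view helps
multi-view disease-stage classification.

## Conditional diffusion model

### Forward process and training objective

The forward process corrupts the target channel over `T` discrete steps
with a linear variance schedule `β_1 … β_T`:

    x_t = sqrt(ᾱ_t) x_0 + sqrt(1 − ᾱ_t) ε,   ᾱ_t = Π_{s≤t} (1 − β_s),  ε ~ N(0, I).

The structural image is never corrupted: it is stacked as a clean second
channel, so the network always sees (noisy target ‖ clean condition).
Both channels are affinely normalized per volume to [−1, 1] before
training or sampling (each volume's own min/max; the formula references
the volume's own range, and per-volume normalization also removes
inter-scan intensity scale differences).

Training draws, per example, a modality class (functional with probability
`modality_mix`, default 0.5; the structural class uses the structural
volume in *both* channels), a uniform time step `t ∈ {1..T}`, and fresh
Gaussian noise, and minimizes a **brain-masked MSE**: the binary brain
mask zeroes out-of-brain residuals before an unrestricted mean over all
voxels (a flag selects an in-mask-only mean instead). Out-of-brain
voxels therefore receive no training signal at all — see *Sampling
stabilization* below for the consequence.

### Network and embeddings

The noise predictor is a small U-Net: double-conv blocks (3×3 same-padded
convolutions, SiLU), 2× average pooling on the contracting path, nearest
upsampling plus skip-concatenation on the expanding path, and a
zero-initialized output convolution. Default: 3 levels, base width 32;
the CPU-scale benchmarks use 2 levels, base width 12 (see *Problem
sizes*). It supports 2-D and 3-D grids (spatial sizes must divide
`2^depth`).

Conditioning enters through one vector per example:

* **time-step embedding** — `seq_i = exp(−log(mp)·i/(dim/2))·t` for
  `i = 0..dim/2−1`, embedding `concat(sin(seq), cos(seq))`; `dim = 512`
  and maximum period `mp = 10,000` by default (the benchmarks use
  `dim = 128` for speed — the embedding is far from the bottleneck at
  these model sizes);
* a two-layer fully connected stack (Linear–SiLU–Linear) deepens it;
* a **learnable class embedding** per modality (`MRI`/`PET`, length
  `dim`, small-variance Gaussian init) is added to the deep time
  embedding.  The sum is injected into every down/up block by a per-block
  linear projection broadcast-added to the feature maps (the standard
  embedding-injection pattern).

The class embedding is what makes one trained network serve both
directions: adding the functional class vector makes the sampler denoise
toward the functional modality, the structural vector toward the
structural one.

Everything is implemented in numpy (float32) with hand-written
backpropagation and an Adam optimizer; gradients are verified against
central finite differences in the test suite.

### Head parametrization

The predictor's *contract* is noise prediction: `predict_noise` returns an
estimate of ε. Internally, two head parametrizations are implemented:

* `"eps"` — the convolutional head regresses ε directly;
* `"x0"` (default) — the head regresses the clean target and the noise
  estimate is derived algebraically,
  `ε̂ = (x_t − sqrt(ᾱ_t) x̂_0) / sqrt(1 − ᾱ_t)` (with ε̂ ≡ 0 at t = 0,
  where the state is clean by definition).

The two are equivalent in function space but not in optimization: for the
sampler, the accuracy that matters is that of the implied clean-image
estimate, and with an eps head its error is amplified by
`sqrt((1−ᾱ_t)/ᾱ_t)` — a factor ≈ 180 at `t = T` under the benchmark
schedule. A CPU-scale training budget (hundreds to a few thousand Adam
steps) cannot reach that precision, and in pilot runs sampling quality
stagnated near the structural baseline while the eps loss kept improving.
With the `x0` head, the regressed function is nearly independent of `t`
for this strongly conditioned task, and the same budget yields high-quality
samples.

Under the `x0` head the training loss regresses the clean target under the
same brain-masked MSE form — i.e. the noise-space MSE with its per-`t`
signal-to-noise weight dropped. This is the standard "simple loss"
reweighting of diffusion training (the noise-space objective weights the
clean-image error by `ᾱ/(1−ᾱ)`, which both destabilizes float32 training
at small `t` — coefficient ≈ 45 — and starves the large-`t` regime the
sampler depends on). The reported loss trace is the masked MSE of the
regressed quantity. With the `"eps"` parametrization the printed
noise-space objective is optimized literally.

### Sampling, inversion, and the two strategies

The generalized reverse transition from `t` to `t_prev` is

    x̂_0 = (x_t − sqrt(1−ᾱ_t) ε̂) / sqrt(ᾱ_t)
    x_{t_prev} = sqrt(ᾱ_{t_prev}) x̂_0 + sqrt(1 − ᾱ_{t_prev} − σ_t²) ε̂ + σ_t ε_new

with `σ_t = η sqrt((1−ᾱ_{t_prev})/(1−ᾱ_t)) sqrt(1 − ᾱ_t/ᾱ_{t_prev})`.
Setting η = 0 removes all stochasticity, which permits evaluating the
update only on a strided subsequence of steps (`sample_steps`, default 50
of `T = 200`, evenly strided and ending at `T`; the final transition ends
at `t = 0`). Deterministic **inversion** is the same update run in the
increasing-noise direction, using the model's own noise predictions
evaluated at the current (lower) step.

* **One-way synthesis**: start from seeded `N(0, I)`, iterate reverse
  steps with the functional class embedding, conditioned on the
  structural image. A missing seed is drawn fresh and recorded in the
  result — never silent.
* **Two-way synthesis**: phase 1 inverts the structural image from
  `t = 0` to `T` with the *structural* class embedding (encoding it into
  latent noise); phase 2 decodes that latent with the *functional* class
  embedding. No random numbers are consumed at any point; repeated
  invocations are bit-identical. The inversion visits the same strided
  steps as sampling, keeping the two trajectories symmetric.

Outputs are mapped from [−1, 1] to a nonnegative [0, 1] activity scale;
the evaluation criteria renormalize to [0, 1] anyway, so this affine is
presentational.

**Sampling stabilization.** Because the loss is brain-masked, out-of-brain
voxels are untrained, and the `1/sqrt(ᾱ_t)` amplification at high `t`
would blow them up mid-chain. The synthesis chains therefore clamp the
implied clean-image estimate to [−1, 1] at every step (the usual
`clip_denoised` practice). The step primitives keep clamping off by
default so their algebraic contracts (round-trip identities, oracle
agreement) hold exactly. When a brain mask is supplied to a synthesis
call, out-of-brain voxels are zeroed in the output, consistent with the
mask's role in training.

**Schedule.** `make_schedule` defaults to the usual convention (β linear
from 1e-4 to 0.02, meant for `T ≈ 1000`). The CPU-scale benchmarks use
`T = 200` with the β range rescaled 5× (5e-4 to 0.1) so the terminal
`ᾱ_T ≈ 3e-5` — without this, a shortened chain does not end in noise
(`ᾱ_200 ≈ 0.13` under the 1e-4..0.02 range) and sampling from `N(0, I)`
is mismatched at its very first step.

## Similarity criteria

`metrics.compare` normalizes both images to [0, 1] (optionally within a
mask; moments then range over in-mask voxels only) and reports:

* MAE and MSE (means over voxels);
* ZNCC with population moments (`1/n`); undefined on a constant image —
  flagged, not raised, so the other criteria still come back;
* SSIM as the single global-statistics formula with `c1 = (k1 L)²`,
  `c2 = (k2 L)²`, `k1 = 0.01`, `k2 = 0.03`, `L = 1`. A locally windowed
  SSIM (scikit-image) is available behind a flag, but the global formula
  is the reference implementation. The third stabilizer `c3 = c2/2` from
  the three-term SSIM decomposition is stored as a constant and unused by
  the combined formula — kept as defined, not "fixed";
* PSNR with `MAX = 1`; at `MSE = 0` it is reported as the sentinel
  `math.inf` rather than an error.

Metrics default to whole-volume computation (matching the bare formulas);
masked computation is available for users who prefer tissue-restricted
scores.

## Phantom cohorts

The generator emits already-"preprocessed" co-registered pairs: an
elliptical brain with three concentric shells standing in for CSF / GM /
WM (outer to inner), wedge-shaped atlas parcels (default 12) rotated per
subject, per-subject geometric jitter (centre ±1 voxel, radii ±2 voxels)
applied identically to both channels, per-parcel intensity offsets
(±12 a.u.), a smooth linear bias field, and fine Gaussian texture on the
structural channel (σ = 8 a.u., spatially smoothed). Structural
intensities live on a [0, 255]-like arbitrary scale (CSF ≈ 60, GM ≈ 160,
WM ≈ 230) so the [−1, 1] normalization stage stays meaningful.

The functional channel is a fixed monotone nonlinearity of the smoothed
structural image — a logistic centred at 190 a.u. with width 12 —
multiplied by a class-dependent modulation in the two highest-index atlas
parcels (the designated "disease regions", recorded in the manifest), plus
additive Gaussian noise (σ = 0.02 on the [0, 1] tissue-signal scale) and
clipping to nonnegative values inside the brain mask. The default class
effect is NC 1.0, MCI 0.85, AD 0.7 — progressive regional hypometabolism
with preserved anatomy (the structural image is identical across classes
for a given subject).

The logistic's steepness is a deliberate choice: it makes the functional
channel's contrast genuinely different from the structural one (deep
tissue saturates, CSF-like signal vanishes), so the direct
structural-vs-functional similarity — the baseline any synthesis must beat
— is moderate (global SSIM ≈ 0.66 at the benchmark conditions) while the
voxelwise coupling remains strong (in-mask correlation ≈ 0.8). A gentler
coupling makes the two channels so similar that "synthesis beats the
structural baseline" would be unmeasurable.

What the phantoms do *not* model: MRI physics and artifacts, partial
volume effects, scanner harmonization, mis-registration, skull or
non-brain tissue, class-dependent atrophy of the structural channel, and
the non-monotone tissue-specific uptake of real FDG (where GM uptake
exceeds WM). Passing benchmarks on phantoms therefore demonstrates that
the machinery — conditional training, deterministic inversion, class
steering, feature extraction, fold-clean evaluation — works end to end,
not that real cross-modality synthesis reaches these scores.

## Features and classifier

Per subject, per (modality, tissue segment), a feature vector holds one
scalar per atlas region: non-zero voxel counts for structural volumes (a
tissue-volume proxy) and regional sums for functional volumes (an
activity proxy). Synthesized functional views reuse the structural
image's segment masks — a synthesized volume has no segmentation of its
own. A shared region list aligns features across subjects; a region
absent from an atlas yields a zero feature with a warning.

Each branch is a scikit-learn pipeline: per-subject L1 normalization of
the feature vector (regional fractions — removes inter-subject global
scale, the usual step before comparing regional uptake), per-feature
z-scoring fit on training folds only, and an MLP with one hidden layer
(width 64, α = 0.1, `lbfgs`). `lbfgs` is used because the cohort sizes
this package targets (tens of training subjects) are far below what
stochastic optimizers need; early stopping is available but off by
default for the same reason — a held-out validation split of a few
subjects is too noisy to stop on. Branch probabilities are averaged —
per modality and then across modalities, which with a full branch grid
equals the flat mean over all branches — and the argmax gives the
predicted class.

Cross-validation is stratified k-fold at the subject level (no subject on
both sides of any fold; asserted at runtime by id). When a view requires
a synthesized volume, the synthesis model is trained on that fold's
training subjects only, then generates the view for all fold subjects
(training subjects' synthetic features are produced by the model that saw
them — that affects only the classifier's training inputs, never test
isolation). Probability vectors are validated (nonnegative, sum to 1) at
every level.

## Problem sizes and determinism

The CPU-scale study conditions, used by the benchmarks, the acceptance
script and the heavy tests:

* **Synthesis benchmark** — 200 training pairs + 30 held-out pairs at
  64×64; `T = 200`, 50 sampling steps, β 5e-4..0.1; U-Net depth 2, base
  width 12, embedding dim 128; 16 epochs, batch 8, Adam lr 2e-3
  (≈ 400 optimizer steps). Runs in ≈ 4–5 minutes on one CPU core.
* **Classification benchmark** — 90 subjects (30 per class) at 32×32,
  5-fold subject-level CV; per fold, the synthesis model is retrained on
  the 72 training subjects with the same settings. ≈ 5–6 minutes.

Every stochastic component is seeded: phantom geometry from
(cohort seed, subject index), functional noise from (cohort seed, subject
index, class), training from its config seed, one-way synthesis from its
recorded seed. Two-way synthesis and η = 0 sampling consume no
randomness at all. Training is bit-reproducible for a fixed seed.

## Known limitations

* The global-statistics SSIM is more permissive than windowed SSIM;
  both are available, and the windowed variant is the better choice for
  method comparisons on real data.
* Deterministic inversion evaluates the predictor at the lower step of
  each transition; with a strongly non-uniform prediction field the
  encode/decode round trip is approximate (on the benchmark it recovers
  the structural image to SSIM ≈ 0.96, not exactly).
* The numpy U-Net is single-threaded matmul-bound; it is sized for
  method validation, not for full-resolution 3-D cohorts.
* At these cohort sizes the classifier margins between view combinations
  carry few-percent noise; conclusions about view usefulness should rest
  on the directional pattern, not single-run differences.
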