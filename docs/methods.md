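# Methods

## The model

`retseg` implements a multi-decoder U-Net for pixel-level segmentation of
the four diabetic-retinopathy lesion families visible in colour fundus
photographs — microaneurysms (MA), hemorrhages (HE), hard exudates (EX) and
soft exudates (SE) — trained semi-supervisedly so that a large pool of
*unlabeled* photographs can improve a model fitted on a small annotated set.

A single convolutional encoder E_θ is shared by five decoders: four
segmentation decoders D_Seg^k (one per lesion) and one reconstruction
decoder D_Rec. Each encoder level is a double 3×3-convolution block with
batch normalisation placed before the ReLU nonlinearity, followed by 2×2
max-pooling; level *l* carries `base_channels · 2^l` feature maps. Each
decoder mirrors the encoder, upsampling with kernel-2 stride-2 transposed
convolutions and concatenating the matching encoder level's features (skip
connections; an additive variant is available via `skip_mode="add"`).
Segmentation heads are 1×1 convolutions emitting logits — the sigmoid is
applied inside losses and metrics so raw scores remain available — while
the reconstruction head is sigmoid-activated to land in [0, 1].

## Objective

Training minimises

```
L_total = α · L_rec + L_seg
L_seg   = β · L_primary + (1 − β) · (L_aux1 + L_aux2 + L_aux3)
```

where `L_rec` is the mean squared error between the input image and its
reconstruction, and each segmentation term is a soft dice loss on sigmoid
probabilities,

```
L_dice = 1 − (2·Σ p·g + ε) / (Σ p + Σ g + ε).
```

The dice denominator is the *sum* of the two masses, not a set union: a
union denominator would score two identical non-empty masks at 2, which is
incompatible with a dice coefficient ranging over [0, 1]. ε (default 1e-6)
is applied to numerator and denominator alike so an empty prediction
against an empty mask contributes zero loss. The MSE is a mean rather than
a sum, making α independent of image resolution.

One model is trained per lesion: its decoder is the *primary* task (weight
β, default 0.7) and the other three lesions plus reconstruction act as
auxiliary regularisers of the shared encoder. β = 1 provably reduces a
training step to single-task U-Net training (asserted bitwise in the test
suite), and α = 0 removes the reconstruction term exactly.

## Two-phase training

1. **Unsupervised phase** — only E_θ and D_Rec are optimised, minimising
   `L_rec` over the unlabeled pool. The segmentation decoders' parameters
   are untouched (asserted bit-identically).
2. **Supervised phase** — E_θ and the segmentation decoders are optimised
   for `L_seg` (plus `α·L_rec` when `supervised_recon=True`, the default,
   since the combined objective includes the reconstruction term; setting
   it to `False` freezes D_Rec entirely during this phase — both behaviours
   are tested).

The optimiser is plain SGD. Full-scale defaults follow the original
training recipe (learning rate 1e-4, batch 16); the desk-scale preset
(`TrainConfig.desk_scale`) uses lr 0.2 with momentum 0.9 and batch 8,
because a ~20k-parameter network on small synthetic images needs far fewer,
larger steps to converge. Batch assembly drops the final incomplete batch
during training and keeps everything during evaluation. The best-validation
parameter snapshot (primary-lesion dice at threshold 0.5) is retained and
restored at the end of the supervised phase.

**Batch-norm recalibration.** With few large steps, the exponentially
averaged batch-norm statistics lag far behind the current parameters, so
evaluation-mode forwards would misrepresent the model. Before each
validation pass the running buffers are recomputed from one reference batch
of training images under the current parameters ("precise BN"). Decoders
outside the phase's update set are excluded so their buffers stay
bit-identical.

`train_all_primaries` pretrains once and fine-tunes four models from the
same pretrained snapshot — pretraining is a single shared investment, which
is also the cheaper reading of the published procedure.

## Dataset splitting

The labeled pool is split 70/5/25 into train/val/test by a PCG64-seeded
shuffle followed by contiguous slicing. Sizes are computed as
`n_val = round(N·f_val)`, `n_test = round(N·f_test)` (numpy half-to-even)
with the remainder to train; for N = 1842 this reproduces exactly the
published cohort sizes (1290, 92, 460), which rounding the train fraction
first would not (round(1289.4) = 1289). The split is unstratified; whether
the original split was stratified by lesion burden is unknown.

## Synthetic data generator

The generator emulates the *structure* of fundus photographs, not their
appearance: a circular orange-brown field on black background with a radial
shading gradient, curved dark vessel strokes (quadratic Béziers from the
optic disc), a bright optic-disc ellipse, and the four lesion families
painted as star-convex blobs whose exact support becomes the ground-truth
mask. Additive Gaussian pixel noise (σ = 0.02) is applied after the masks
are recorded. Distinguishing features mirror the clinical ones: MA are
1-3 px dark-red dots (deliberately the smallest and hardest class), HE are
irregular dark-red blots, EX are vivid yellow patches (the most prevalent
class — expected pixel area orders EX > HE > SE > MA), and SE are pale
low-contrast blobs. Lesions are placed without mutual overlap and entirely
inside the field of view; a fixed seed reproduces a bit-identical dataset.

What the generator does *not* emulate: real lesion textures, illumination
artefacts, camera variation, inter-grader annotation noise, and the extreme
class imbalance of real MA maps. Passing tests therefore demonstrate that
the pipeline's mechanics (losses, phase isolation, optimisation,
evaluation) are correct and that the architecture can learn colour/shape
cues — not that clinical-grade accuracy is attainable.

The lesion contrast parameter (default 0.9) was calibrated once during
development so that a tiny network reaches validation dice ≥ 0.6 within
desk-scale training — detectability is a design dial of the benchmark, and
the default makes the task neither trivial nor impossible.

## Preprocessing

Crop the tight bounding box of pixels whose max-channel intensity exceeds
0.02 (blank fundus borders are near-black in every channel); equalize each
channel's histogram globally *within* the retinal field (equalising over
the black surround would skew the CDF — hence crop first); rescale with
bicubic interpolation so the longer side hits the target (512 default),
padding symmetrically to a square rather than stretching, since distortion
would corrupt shape-dependent masks; min-max normalise to [0, 1]. Masks
ride through crop and resize only, with nearest-neighbour interpolation and
re-binarisation.

## Evaluation

Per lesion: dice and sensitivity are computed per image on masks
thresholded at 0.5 (threshold exposed) and averaged; MAE is the mean
absolute difference between the probability map and the binary ground
truth, averaged per image; AUC-ROC and AUC-PR rank pixels pooled across
the split (pooling keeps the minority class's prevalence represented,
which is the reason PR is the more informative curve here). Two empty
masks score dice 1; sensitivity is undefined for an empty ground truth and
excluded from aggregation with a logged note; AUCs are undefined on
single-class pixel pools. All five metrics are checked exactly against
confusion-count and pairwise-ranking oracles.

## Experiment harnesses and problem sizes

The desk-scale benchmark (`desk_benchmark`) uses 128×128 images, 40
labeled + 200 unlabeled samples, a depth-3 / base-4 network (~19k
parameters), 2 unsupervised and 10 supervised epochs — chosen as the
smallest configuration that trains to a clearly non-trivial validation
dice (≈ 0.9 for EX). The multi-seed trend grid (`desk_benchmark_grid`)
runs 64×64 images so that five-seed sweeps of the auxiliary-task ablation
and the unlabeled-data sweep complete quickly; its epoch counts are sized
so each cell trains to convergence rather than stopping in the
high-variance early regime. Trend assertions are deliberately one-sided
non-inferiority checks (mean dice within 0.02) rather than effect-size
claims: published effect sizes are dataset- and scale-specific and are not
reproducible from synthetic data, so only the direction of the claims is
checked.

The auxiliary-task ablation fixes the inclusion order EX, SE, MA, HE
(minus the primary) so cells at different k are comparable. The
cross-dataset protocol shifts the target domain by contrast ×0.7 and noise
×1.5, evaluates on a target pool drawn from an independent seed stream
(leakage-free by construction), and mixes `round(f·N)` target images into
training only (never validation).

## Numerical choices

* All network arithmetic is float32; the autodiff engine (`retseg.nn`) is
  a compact reverse-mode implementation over numpy arrays whose every
  operator is gradient-checked against central differences in float64.
* Convolutions are stride-1 with "same" padding, computed as k² shifted
  channel contractions (no im2col materialisation); upsampling is a
  kernel-2 stride-2 transposed convolution whose non-overlapping taps make
  both passes exact tensor contractions.
* Max-pool ties route the gradient to the first maximum.
* The logistic is computed via `exp(-|x|)` only, so saturated logits give
  exactly 0 or 1 without overflow.
* Checkpoints store parameters and batch-norm buffers unmodified (`.npz` +
  YAML config); a round trip restores bit-identical forward behaviour.
* Degenerate inputs fail loudly: fully blank images, empty pools, unknown
  primary tasks, non-finite losses (with a learning-rate hint), fractions
  that do not sum to one.

## Known limitations

* CPU-only: full-scale (512×512, depth-5, base-32) training is supported
  by the code but impractical without an accelerated backend; the package
  is exercised and validated at desk scale.
* Plain SGD only (no schedules, weight decay, or early stopping beyond
  best-val checkpointing), matching the published recipe's simplicity.
* The generator's lesions are colour/shape caricatures; results on it do
  not transfer quantitatively to clinical data.
* Neovascularisation (NV) and IRMA lesions, DR severity grading, and
  baseline comparison architectures are out of scope.
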