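# Methods

## Problem and models

`virtustain` translates label-free bright-field z-stacks of cultured
adipocytes into three virtual fluorescence stains — Hoechst-like nuclei,
Bodipy-like lipid droplets and a CellTracker-like cytoplasm channel — and
scores the translations on extracted cell-level features rather than raw
pixels. Each channel is handled by a model tailored to what makes that
channel hard:

* **Nuclei.** Nuclei are often barely visible in transmitted light. The
  generator is a dense U-Net with two decoders sharing one encoder: an
  *image* decoder predicting the stain and a *segmentation* decoder trained
  on binary nuclear masks — privileged information available only at
  training time (LUPI). Segmentation features are injected into the image
  decoder by pixel-wise summation of corresponding blocks. The loss is

      L = L1_reg + α_LWM · L_LWM + α_seg · L_BCE

  where `L1_reg` is an L1 reconstruction loss weighted per pixel by the
  *segmentation weight mask* (SWM): weight η where the current thresholded
  segmentation disagrees with the ground-truth mask, 1 elsewhere. The SWM
  is computed from detached segmentation probabilities each step — it is a
  weighting, not a differentiable objective. `L_LWM` (the loss weight
  module) applies the same weighted L1 to the predictions emitted by every
  intermediate image-decoder block through a 1×1 convolution, against
  ground truth downscaled by area averaging and the SWM downscaled by
  nearest neighbour (which preserves the {1, η} values). Defaults:
  η = 2, α_LWM = 0.1, α_seg = 0.05.

* **Lipid droplets.** Droplets are high-contrast but their internal defects
  (dark cave-ins marking metabolically active cells) are easily smoothed
  away. The base dense U-Net is trained adversarially against a
  conditional patch discriminator (input: stack + real/fake image; output:
  a spatial map of least-squares scores) with the relativistic average
  least-squares (raLSGAN) objective

      L_G = E[(D(y) − E[D(G(x))] + 1)²] + E[(D(G(x)) − E[D(y)] − 1)²]
      L_D = E[(D(y) − E[D(G(x))] − 1)²] + E[(D(G(x)) − E[D(y)] + 1)²]

  plus an image-gradient loss (L1 distance between unnormalized forward
  differences, horizontal on H×(W−1), vertical on (H−1)×W), which is
  invariant to constant offsets and sensitive to edges. Total:
  `α_L1·L1 + α_grad·L_grad + α_adv·L_G` with α_L1 = 1, α_grad = 5,
  α_adv = 0.01. The generator trains alone for the first 1500 iterations
  (100 in the tiny profile); afterwards generator and discriminator
  alternate 1:1 (the update ratio is our choice; the source material does
  not state one).

* **Cytoplasm.** The stain is weak with high, largely unpredictable
  intensity variation; gradient or adversarial terms produce artifacts, so
  the base model trains with plain L1.

## Architecture

The dense U-Net encoder/decoder uses dense blocks — batch-norm → ReLU →
3×3 convolution → dropout quartets with intra-block dense connectivity —
plus a skip over each encoder block; transitions down are 2×2 max pooling,
transitions up pixel-shuffle followed by a fixed normalized 2×2 averaging
blur (anti-checkerboard; the blur kernel is our choice, cited work gives no
parameters). Depth is 5 blocks per path for nuclei, 4 for lipids and
cytoplasm; growth rate 12, dropout 0.2. Layers per block (default 4) and
the 3×3 kernel are our defaults where the source is silent. The number of
LWM scales is `depth − 1`: every image-decoder block except the final
full-resolution output, which is supervised by the full-resolution loss.
The discriminator is a conventional strided-convolution patch critic
(4×4 kernels, LeakyReLU 0.2, batch norm except on the first layer; default
receptive field ≈ 70 px, below the 512 px training crop); no final sigmoid,
as required by the least-squares objective. Generator outputs pass through
a sigmoid so predictions live in [0, 1]; the segmentation head emits logits
and the BCE uses a numerically stable logits form.

All networks run on a small reverse-mode automatic-differentiation engine
(`virtustain.nn`) written for this package: NumPy arrays on a gradient
tape, with conv2d as im2col + GEMM (the stride-1 input gradient is computed
as a full correlation with the flipped kernel, again via GEMM), fused
batch-norm, max-pool, pixel-shuffle and dropout primitives. Analytic
gradients are verified against central finite differences in the test
suite. Everything is CPU, float32 in the layers, deterministic given a
seed.

## Training

AdamW (decoupled weight decay 0.01) with constant learning rates: 1e-3 for
nuclei, 1e-4 for the lipid/cytoplasm generators, 1e-5 for the
discriminator. Batch sizes 12/4/4 and 51,400 / 30,000 / 75,000 iterations
in the full configuration. Crops of 512×512 are sampled with probability
0.8 around a uniformly chosen nucleus centre plus a uniform offset up to
256 px (guaranteeing a nucleus in the crop) and uniformly otherwise;
augmentation is horizontal/vertical flips plus continuous rotation up to
±180° for nuclei (bilinear, reflect padding; masks nearest-neighbour) and
90° multiples for lipids/cytoplasm. The best checkpoint minimizes the
validation loss, defined as the composite loss without adversarial terms
(a discriminator score is not comparable across steps); validation uses
fixed centre crops only, so it never touches the crop/augmentation stream.
Data splits are grouped by well (the acquisition unit): wells are never
shared between train, validation and test.

Losses written as sums over pixels are implemented as means (with a
`reduction="sum"` switch) so learning rates are portable across crop
sizes.

### Desk-scale (tiny) profile

CPU-scale runs use depth 2, 2 layers per block, growth 4, 8 stem features,
64×64 crops, batch 4, ≤500 iterations, warm-up 100, validation every 25
steps. These problem sizes are the package's scaled-down study conditions:
large enough for the mechanisms (loss decrease, segmentation decoder
accuracy, GAN scheduling) to be observable, small enough to run in
minutes.

## Tiled inference

Full frames (~2156×2556 px) are processed as overlapping 512×512 tiles
with a 256×256 stride. Each tile output is weighted by a separable pyramid
`w(i,j) = (1 − |i−c_i|/(c_i+1)) · (1 − |j−c_j|/(c_j+1))` — strictly
positive, maximal at the centre, linearly decaying — and the weighted
outputs are summed and normalized by the accumulated weight, making every
output pixel a convex combination of tile outputs. Borders are
reflect-padded so each pixel is covered by at least one full tile. The
exact pyramid form and border policy are our choices; the qualitative
shape (centre-heavy, pyramidal decay) is prescribed.

## Feature extraction and evaluation

A lightweight counterpart of a CellProfiler-style pipeline (bit-exact
parity is explicitly out of scope): nuclei by local-mean adaptive
threshold + hole filling + wide diameter range + solidity shape filter;
lipids by a global threshold over small and large diameter ranges, with
clumps split by intensity structure (h-maxima markers → watershed, then a
merge of adjacent regions whose saddle is within h of the dimmer peak, so
only genuine intensity dips split objects); droplet defects by
reconstruction-by-erosion (fill minus image above a depth threshold,
intersected with droplets); cells by watershed from nuclear seeds over the
averaged cytoplasm/lipid image, masked by an adaptive threshold with a
window larger than the nuclear one. Per object: area, perimeter (Crofton
4-direction estimator — low rasterization bias; a weighted-edge estimator
overestimates a disc's perimeter by ~5%), form factor `4πA/P²`,
compactness `P²/(4πA)` (1 for a filled circle, > 1 for irregular or holed
objects), mean radius (mean interior distance-transform value), solidity,
granularity spectrum (fraction of object intensity removed by grayscale
openings at increasing scales; anti-extensivity enforced across scales),
and integrated/mean/std intensity. Per-image values are object means;
counts pass through. All thresholds live in `FeatureConfig`; the defaults
were chosen against the synthetic generator.

Image-level scores: MAE normalized by the median intensity of the
ground-truth image (per image, not per dataset — the wording of the source
is ambiguous and per-image is the scale-free choice), and SSIM with a 7×7
uniform window at data range 1.0. Feature-level scores: per feature,
`MAE_median = mean(|y − ŷ|)/median(y)` over images plus the Spearman
correlation of per-image values; correlations across splits are averaged
via the Fisher transform `tanh(mean(arctanh ρ))`. The feature-group score
is the mean over member features, the total the mean over groups
(morphology / intensity / count). The MAE_median formula is printed in the
source without absolute-value bars but named MAE; we implement the
absolute form and expose the literal signed form behind a flag.
Configurations are compared with a one-sided Mann-Whitney U test on
per-image scores ("a better than b" = lower); all-tied degenerate samples
return p = 0.5 with a warning.

## Synthetic data

The generator emulates the qualitative structure of the real assay with
exact ground truth: non-overlapping nuclear ellipses (bright in the nuclei
channel, faint — contrast 0.03 — in bright-field), lipid discs clustered
near nuclei with bright rims and dark interiors in bright-field, a
`defect_fraction` of droplets carrying interior dents of depth 0.3–0.45,
weak cytoplasm (≈0.16) with strong multiplicative low-frequency variation,
and a 7-plane stack blurred per plane with σ ∝ |plane − focus| plus
Gaussian read noise (σ = 0.01). Default scenes are 128×128 px with 5
nuclei (radius 7–11 px) and 12 droplets (radius 4–9 px, 30% defective) —
a scaled-down analogue of the 60× frames. One seeded generator drives all
randomness; scene *i* of a dataset uses `seed + i`, so datasets are
bit-reproducible. What the generator does **not** model: real optics
(diffraction, phase effects), texture within organelles, staining
spill-over, or the density and size statistics of the competition data.
Passing tests therefore demonstrate that the mechanisms work — losses
optimize, privileged information trains the segmentation decoder, tiling
is exact, features are recovered — not that the models reach the published
feature fidelity on real adipocyte images.

## Numerical and design notes

* Quantization only at TIFF write time (`round(v·65535)`); round-trip
  error ≤ 1/65535 per pixel. Dynamic-range scaling is per image.
* Degenerate inputs: constant images rescale to zeros; an empty
  segmentation yields an empty feature table flagged as missing; a zero
  ground-truth median raises rather than returning an unbounded score.
* Max-pool gradients split ties evenly; |x| uses subgradient 0 at 0.
* `h_maxima` declumping depends on a single dip parameter h = 0.08, below
  the dent depth and above the noise floor.
* Known limitations: no GPU path, no mixed precision, no test-time
  augmentation; the discriminator architecture and LWM scale placement are
  conventional choices, not reproductions; full-scale training
  configurations are provided but not exercised on CPU.
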