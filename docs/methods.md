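# Methods

## Model

The core model is a masked autoencoder over single-channel nucleus crops.
A crop of side `H` (square, `H` divisible by the patch side `P`) is split
into `N = H²/P²` non-overlapping patches in row-major order; each flattened
patch is linearly projected to a `d`-dimensional token. A learnable
representation token occupies sequence position 0 and, after encoding, is
the image's global embedding; all downstream tasks read only this token.

Masking samples exactly `round(ratio·N)` patch indices uniformly without
replacement (at least one patch is always left visible). Only the
representation token and the visible tokens enter the encoder — the standard
asymmetric design that makes a 75% mask ratio cheap. The decoder first
projects encoder outputs to its own width `d_dec`, drops the representation
token, places the projected visible tokens back at their original sequence
positions with a learnable mask token filling every masked position, adds
decoder positional encodings, and applies its own transformer stack followed
by a linear head mapping each token to `P²` pixel values. The loss is the
mean over masked patches of the per-patch squared error summed over pixels;
visible patches contribute nothing.

Transformer blocks are pre-norm: `x + Attn(LN(x))` then `x + MLP(LN(x))`,
with multi-head softmax attention, a 2-layer feed-forward of width `4d` and
GELU (tanh approximation), and a final LayerNorm after each stack. Attention
probabilities of every layer are retained for interpretability.

Design choices made where the architecture was genuinely open:

- **Positional encodings** are fixed 2-D sin-cos tables over the patch grid
  for both encoder and decoder, plus a dedicated learnable row for the
  representation token. Fixed tables add no parameters and are standard in
  masked-autoencoder practice.
- **Decoder capacity**: `d_dec = 512` with 8 blocks / 16 heads in the default
  profile; the decoder is discarded after pretraining, so its width is a
  speed/quality trade-off, not part of the representation.
- **Reconstruction targets** are the stored normalized pixel values; no
  per-patch re-normalization of targets.
- **Profiles**: default 112×112 / P=8 / d=768 / 12×12 encoder; `tiny`
  56×56 / P=8 / d=64 / 2 blocks × 4 heads for both encoder and decoder.
  The tiny profile exists so the full pipeline (pretraining included) runs
  in minutes on one CPU core.

The whole network, including backpropagation and AdamW, is implemented
directly in numpy (float32 compute by default; a module-level dtype switch
enables float64 for finite-difference gradient verification, which the test
suite performs on a microscopic configuration). Exact bit-reproducibility
across BLAS builds is not promised; all sampling (weight init, data order,
masks) is seeded.

## Training

Pretraining uses AdamW (β = 0.9/0.999, weight decay 0.01) at base learning
rate 1e-4 with a 10-epoch linear warm-up and a step schedule that halves the
rate every 20 epochs. Warm-up is evaluated per epoch, from `base_lr/warmup`
at epoch 0 to `base_lr` at the warm-up boundary; step decay counts from
epoch 0, so with the default settings epochs 10–19 run at the base rate and
epoch 20 takes the first halving. The best model is selected by validation
loss; validation masks are held fixed across epochs so the curve is
comparable epoch to epoch.

Fine-tuning disables masking entirely (`M_i = 0` for all `i`) and trains a
task head on the representation token. Full mode updates encoder and head;
partial mode freezes the encoder — implemented by embedding every image once
and training the head on cached embeddings, which is mathematically
identical and much faster. Task defaults: cross-entropy at lr 1e-4
(5-epoch warm-up, 30 epochs, batch 300) for classification and MSE with the
same schedule for gene-expression regression; focal loss (α = 0.25, γ = 2)
at lr 1e-5 (5-epoch warm-up, 20 epochs, batch 200) for TLS scoring; MSE at
lr 1e-4 (3-epoch warm-up, 20 epochs, batch 256) for infiltration
regression. Class-imbalanced classification supports seeded equal-size
subsampling per class.

## Interpretability

Attention rollout averages each layer's attention over heads, folds in the
residual connection as `A' = (A + I)/2` with row re-normalization, and
multiplies the layers in order. The representation-token row of the product,
restricted to patch positions and renormalized to sum 1, is the relevance
map. If no attention mass reaches the patches (identity attention), the map
is reported as uniform rather than zero.

## Perturbation screening

Each perturbation group's embeddings are compared to a negative control with
squared MMD under an RBF kernel. The pipeline follows a fixed order:
(1) subsample the control (default 10% of its cells); (2) derive the kernel
bandwidth from the subsampled control by the median heuristic,
`gamma = 1/median(pairwise squared distances)` — the bandwidth must be
data-derived and the median heuristic is the standard choice; (3) balance
every group to the control size (downsample without replacement /
oversample with replacement); (4) compute the biased V-statistic estimator
`mean k(A,A) + mean k(B,B) − 2 mean k(A,B)`, which is exactly 0 for
identical multisets and non-negative in general (the unbiased U-statistic is
available as an option but can go negative, which complicates outlier
flagging); (5) flag groups whose MMD strictly exceeds `Q3 + 1.5·IQR`, with
quartiles by linear interpolation (numpy's default, the common "type 7"
rule). Change vectors are group mean minus control mean on the full
(unbalanced) groups; cosine similarity between change vectors matches
perturbations with similar morphological responses. Zero-norm change
vectors yield undefined (missing) similarities, never 0.

## Corpus construction

Crops are defined physically: the pixel side is `round(window_um /
pixel_size)`, and pixel size is required slide metadata with no default —
a 20 µm window is meaningless without it. Windows are half-open, 0-based
(row, col); regions beyond the slide edge are zero-padded so every centroid
yields a usable crop. QC is a configurable band on mean crop intensity.
Normalization clips to the 1st/99th percentile band then rescales to [0, 1];
constant crops map to zeros (division guard). Re-normalizing an already
normalized crop re-estimates percentiles on clipped data and can move values
by up to roughly the inter-pixel quantile spacing (sub-percent); with a
(0, 100) band the operation is exactly idempotent. Corpora are stored in a
single HDF5 file: `/images` (n × S × S float32, chunked per image), `/meta`
(cell id, centroid, window, source), optional `/labels` and `/splits`, and
a format-version attribute. Split sizes are `round(fraction·n)` for val/test
with the remainder to train, reproducing 800/200 and 800/100/100 exactly at
n = 1000.

## Spatial workflow

Slides are tiled by a sliding window (row-major; windows past the edge are
dropped). TLS labeling needs CD3 and CD20 channels: entirely black patches
are discarded; a patch is TLS iff it contains at least `min_cells`
marker-positive cells in *both* channels (connected components above an
intensity threshold, minimum 3 px) and its mean marker intensity clears a
floor. The thresholds are configurable; the defaults (3 cells, intensity
floor 0.01, marker threshold 0.2) are calibrated to the synthetic slides'
rendering scale. Training sets keep all positives and subsample negatives to
10× the positives. FOV records aggregate member-patch TLS scores by mean
(max available); guided acquisition orders FOVs by descending score with
ties broken by ascending scan id, and the captured proportion is the
cumulative fraction of T+B cells covered by the first k FOVs. Infiltration
targets are lymphocyte density (count/area) per patch by default so scores
are comparable across patch sizes; raw counts are available.

## Synthetic data

The generators exist so every stage has ground truth. Nuclei are oriented
ellipses with controlled area, aspect ratio and mean intensity, modulated by
a smooth multiplicative texture field (Gaussian-filtered noise), softened at
the rim, plus additive noise — the minimal model covering the morphology
axes the representation should capture (size, shape, intensity, texture).
Per-cell log-normal jitter (sd 0.1) keeps cohorts from being degenerate.
Screens can be generated directly in representation space (control and null
groups N(0, I); planted groups mean-shifted along stored unit directions, so
shift magnitudes are in SD units) or as images with shifts mapped to area
and intensity. Tissue slides place dense small T/B nuclei (50/50) uniformly
inside planted circular aggregates and sparse larger "other" nuclei outside,
render soft-disk DAPI/CD3/CD20 channels, and return the aggregate mask as
ground truth.

What the synthetic data does *not* emulate: optics (PSF, aberrations),
staining artifacts, touching/overlapping nuclei, chromatin substructure,
batch effects, or realistic class overlap. Passing tests therefore show the
machinery is correct and that the pipeline recovers planted structure under
controlled conditions — not that any particular real-data performance level
will be reached.

## Problem sizes and numerical notes

The shipped acceptance run pretrains the tiny profile on 5,000 synthetic
nuclei for 30 epochs (batch 128), a deliberate desk-scale choice that keeps
the whole pipeline reproducible in minutes on a single core; screening runs
50 groups × 200 cells over 10 seeds; slides are 896 px with 56-px patches.
Quantile loss defaults to τ = 0.5 and adjusted R² to p = 1 predictor (both
configurable and recorded in outputs). Two-cluster evaluation aligns cluster
ids to the truth by the permutation maximizing F1 before computing metrics.
Degenerate inputs are handled explicitly: identical control points fall back
to `gamma = 1/d` with a warning; all-equal MMD values flag nothing (strict
inequality); empty foregrounds and constant images raise rather than return
silent zeros.

## Known limitations

- Single-channel (DAPI) encoders only; no multi-channel variant.
- No GPU path; the default (d = 768) profile is constructed and exercised at
  toy batch sizes in tests, but full-scale pretraining of it is out of scope.
- Nucleus segmentation is not included: centroid tables are inputs.
- FOV repositioning (re-centering acquisition windows on high-score regions)
  is limited to reporting scores per FOV; no geometric re-layout search.
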