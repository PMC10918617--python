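# Methods

## Problem setting

Mass spectrometry imaging (MSI) acquires a full mass spectrum at every
pixel of a tissue section, yielding a datacube `X` of shape `M x N x H`:
one 2-D "ion image" per m/z channel. Two retrieval problems drive this
package:

* **Colocalization** — find ions whose spatial distributions match (they
  likely co-distribute biologically).
* **Isotope pairing** — find isotopologue partners: channels offset by
  `k x 1.00336` Da that share the monoisotope's spatial pattern at a
  dimmer, noisier intensity.

Both reduce to measuring similarity between ion images. Raw pixel-space
metrics are fragile on MSI because the data are low-SNR: per-pixel ion
counts are small (Poisson statistics), missing values are pervasive
(often half of a channel's pixels; the hardest ions lose 70–90%), and
matrix effects superimpose diffuse haze and smooth multiplicative
heterogeneity. The package therefore learns a representation: an encoder
is trained, without labels, to map corrupted views of the same ion image
to nearby vectors, and retrieval happens by Euclidean distance in a
reduced 20-d embedding space.

## Preprocessing

Each channel is processed independently. Pixels above 99% of the
per-image maximum are hotspots and are truncated to that threshold
(`fraction-of-max` rule; a 99th-percentile alternative is available).
The image is then min-max scaled to [0, 1]:

    x_norm = (x - min x) / (max x - min x).

Off-mask (non-acquired) pixels participate as zeros. Constant (blank)
channels normalize to all zeros with a warning rather than aborting a
batch — blank channels occur in real peak lists.

A subtlety worth recording: truncation under the `fraction-of-max` rule
is not exactly idempotent (after clipping, the maximum drops, so a
recomputed threshold is 1% lower); the percentile rule is idempotent up
to interpolation between order statistics. In practice preprocessing is
applied once.

## Self-supervised training

### Views

Each training step draws two stochastic views of every ion image in the
batch. The corruption operators model MSI acquisition physics:

| operator | default | models |
|---|---|---|
| color jitter | brightness, contrast each U(0.8, 1.2) | detector gain / global intensity drift |
| Gaussian filter | sigma U(0, 1.5) px | spatial spread (median filter optional) |
| Poisson noise | `x -> k/lambda, k ~ Poisson(lambda x)`, lambda = 50 | ion counting statistics (mean-preserving) |
| random missing | fraction U(0, 0.3) of nonzero pixels | missing values |
| intensity-dependent missing (ISO only) | `p_i = m (1 - x_i)` | dim pixels vanish first |

COL mode composes jitter → filter → Poisson → random missing. ISO mode
appends a global scale `s ~ U(0.1, 1.0)` and intensity-dependent dropout
with `m = 0.5 (1 - s)/(1 - 0.1)` — the dimmer the view, the more pixels
it loses, which is exactly the mono → isotope transformation, so
ISO-trained encoders place isotopologue partners close together.

The direction of intensity-dependent dropout is ambiguous in principle
(one could drop bright pixels first); the physics-consistent direction
(dim pixels drop first) is the default, the flipped one is behind a
flag. Geometric augmentations (flips, crops) are deliberately absent:
ion images of one section are pixel-registered, and registration between
views must stay exact.

Stronger missing-value augmentation (up to 0.5) was evaluated and
degraded phantom retrieval quality; the defaults above are kept.

### Architecture

The twin branches share all parameters:

* **Encoder f** — a compact residual CNN: a stride-2 3x3 stem (batch
  norm, ReLU, 2x2 max pool) and four residual blocks of widths
  64/128/256/512 (strides 1, 2, 2, 2), global-average-pooled to a 512-d
  representation `r`. Two deliberate choices at the output: the last
  block omits its final rectifier, so pooled features are sign-symmetric
  instead of confined to the positive orthant, and a final batch norm
  equalizes per-dimension scales — both standard for features consumed
  by cosine/Euclidean machinery. Single-channel ion images are
  replicated to 3 channels and reflect-padded to a multiple of 32 per
  side. Depth and widths are configuration; external encoder weights can
  be loaded from a checkpoint when available, otherwise all parameters
  are drawn N(0, 0.02).
* **Projector g** — 3 fully connected layers 512→512→512→512 with batch
  norm + ReLU between layers and batch norm on the output (no output
  rectifier). The output normalization follows the twin-network ancestor
  design and materially improves phantom retrieval.
* **Predictor q** — 2 fully connected layers through a 128-d bottleneck,
  512→128→512, batch norm + ReLU in between.

### Loss and optimization

With `(p, h)` the predictor/projector outputs of the two views,

    L = 1/2 D(p1, stopgrad(h2)) + 1/2 D(p2, stopgrad(h1)),
    D(a, b) = -(a·b)/(||a|| ||b||),

bounded in [-1, 1]. Gradients flow only through the predictions; the
projector targets are constants. Optimization is Adam with learning rate
3e-4 and momentum parameters beta1 = 0.5, beta2 = 0.99; "iterations"
(default 100) count epochs over the ion-image set; batch size defaults
to 64 images (both views of a batch are concatenated, so batch-norm
statistics span 2B rows). Everything is float64 NumPy; convolutions run
through im2col so the arithmetic lands in BLAS, and gradients of every
layer are verified against central finite differences in the test suite.

### Collapse

The collapse monitor is the standard deviation across images of the
L2-normalized representations — the square root of the trace of their
covariance. Spread-out representations score near 1; the degenerate
encoder that maps everything to one point scores 0. After training at
the phantom study conditions the monitor sits at 0.1–0.25.

Two empirical notes. First, at very small scale (a few dozen tiny
images, a narrow encoder) the monitor collapses for stop-gradient
training too; the mechanism needs the study-scale conditions to behave
as advertised, which is why training-quality assertions live at that
scale. Second, the textbook negative control — remove predictor and
stop-gradient, observe collapse — does not produce collapse here: batch
normalization in the projector (and at the encoder output) is an
implicit collapse preventer, so the ablation drives the loss to -0.99
(views aligned) while cross-image dispersion stays high. The ablation
remains runnable (`train(..., ablation="no_stop_gradient")`); the
stop-gradient contract is instead verified directly by finite-difference
gradient tests.

## Embedding and retrieval

After training, each channel is encoded in evaluation mode (no
augmentation) and the `H x 512` matrix is reduced with UMAP (Euclidean
metric, 20 output dimensions, `n_neighbors = 15`, `min_dist = 0.1`,
fixed seed), then each output dimension is min-max scaled to [0, 1].
UMAP beyond the output dimension is left at library defaults; note that
UMAP's repulsion separates even duplicated rows slightly, so duplicate
channels land near — not exactly on — each other in the 20-d space
(they are exactly equal at the 512-d stage).

* **Colocalization**: candidates ranked by ascending Euclidean distance
  to the query embedding, ties broken by m/z.
* **Isotope discovery**: candidate pairs must satisfy
  `|mz_j - mz_m - k·1.00336| <= 0.02` Da for some `k <= 3` (all three
  constants configurable — without an m/z gate, isotope identification
  would collapse into plain colocalization). Candidates at embedding
  distance below a threshold are emitted, each isotope assigned to its
  closest monoisotope. When no threshold is supplied, half the median
  all-pairs embedding distance is used; on phantoms the true-pair
  distance mode sits far below this gate.
* **Linear probe**: representation quality is scored by leave-one-out
  accuracy of a multinomial logistic classifier (scikit-learn defaults,
  fixed untuned L2 regularization) on frozen features.

## Baselines

SIM baselines flatten channels (on-mask pixels) and compute pairwise
Euclidean, cosine, Pearson correlation, R² and SSIM matrices. SSIM uses
the standard windowed form (7x7 uniform window, K1 = 0.01, K2 = 0.03,
data range 1). R² is the coefficient of determination of the
least-squares fit of the candidate on the query **through the origin**:
`R² = 1 - SS_res/SS_tot` with `yhat = a x`, `a = sum(xy)/sum(x²)`. This
convention is chosen because it can be negative (a proportional fit can
explain less than the mean), which an intercepted OLS fit on its own
training data cannot, and it satisfies `R² <= PCC²`. It is directional,
so the R² matrix is not symmetric. DR baselines are PCA, t-SNE and UMAP
on the flattened channels, min-max scaled; t-SNE runs at 2 output
dimensions (exact t-SNE beyond 3 is nonstandard) and is zero-padded into
the common 20-column container.

## Synthetic phantoms

The generator produces cubes with exact ground truth so every stage is
testable offline. Ions in a colocalization group share one smooth
spatial template (blurred disk / annulus / stripe / blob union; group
templates are rejection-sampled to pairwise PCC < 0.5, mirroring
distinct anatomical regions). Each member ion then differs the way real
co-distributed ions do:

* per-ion gain U(0.5, 2) and contrast warp `template^gamma`,
  gamma U(0.6, 1.67);
* diffuse background haze (smooth random field, amplitude U(0, 0.5) of
  the template peak) — matrix chemical background;
* smooth multiplicative speckle `exp(sig Z - sig²/2)` with
  sigma U(0, 0.5), correlation length side/8 — matrix crystallization
  heterogeneity;
* Poisson counts at `count_scale = 8` expected counts at the template
  peak — MALDI per-pixel ion counts are single digits to low tens;
* per-ion uniform missingness, fraction U(0.25, 0.75) — real MSI
  channels commonly lose half their pixels.

Isotope pairs share the monoisotope's full value map (same molecule),
scaled by `s ~ U(0.2, 0.6)`, with independent Poisson noise, uniform
missingness, and extra intensity-dependent dropout scaled by `(1-s)`;
their m/z values sit at `k` neutron masses (k ∈ {1, 2, 3}, weighted
toward 1) plus sub-tolerance jitter. m/z values live on a synthetic
100–2000 Da axis.

At these frozen defaults the within-group mean pairwise PCC exceeds the
between-group mean by ≈ 0.2 (averaged over 10 seeds) — groups are
clearly separated in pixel space, as the generator's contract requires.
A consequence worth stating: with 5 well-separated groups of 10 ions, a
leave-one-out linear probe on raw pixels is near-ceiling (0.96–1.0), so
at this phantom scale the learned embeddings match rather than beat the
raw-pixel probe. The regime where pixel-space methods genuinely fail —
many categories with few members on real anatomy — requires real
annotated MSI data, not phantoms of this size. What the phantom suite
does show: embeddings retain ≥ 0.9 probe accuracy and ≥ 0.8 k-means ARI
from heavily corrupted inputs, and ISO-mode embeddings recover the
isotope pairing that pixel-space correlation misses at high missingness.

## Problem sizes and numerics

The default test/acceptance profile trains on 50–60 ion images of
64x64 pixels for 20 epochs at batch 32 — chosen as the package's
desk-scale study conditions; full-scale runs (thousands of ions,
hundreds of epochs) use the same code paths via configuration.
Tolerances: exact-formula oracles at 1e-8 (float64), Monte-Carlo checks
at 3–4 sigma, finite-difference gradient checks at 1e-6 with eps = 1e-7.
Degenerate inputs: constant channels normalize to zero and report NaN
correlations (excluded from calls); zero-norm vectors are rejected by
the cosine with the offending branch named; training on a single-channel
cube is refused (batch norm needs ≥ 2 rows).

## Known limitations

* The phantom emulates corruption statistics, not anatomy; conclusions
  about absolute accuracy on real tissue do not follow.
* imzML reading materializes the dense cube in memory; very large
  acquisitions need chunking that is not implemented.
* Processed-dialect binning uses a fixed-width grid (default 0.01 Da),
  not adaptive peak pooling.
* The isotope gate assumes centroided, well-calibrated m/z values;
  tolerance and `k_max` must be widened for lower-resolution data.
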