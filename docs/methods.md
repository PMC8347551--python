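# Methods

## The model

FAC-Net is a binary segmentation network for dermoscopy images built on a
CE-Net-style encoder/decoder. For an input of size H×W (divisible by 32)
and base width C the encoder is a stride-4 stem (7×7 stride-2 convolution,
batch norm, rectifier, 2×2 max pool) followed by four residual stages of
two blocks each, doubling channels and halving resolution:
C×H/4, 2C×H/8, 4C×H/16, 8C×H/32. The deepest feature passes through a
context block — a cascaded dense-atrous module (dilation rates 1, 3, 5,
branches added residually) and a residual multi-kernel max-pooling module
(kernels 2/3/5/6, each pooled grid projected to one channel, bilinearly
upsampled and concatenated; a 1×1 convolution restores the channel count,
a small departure from the original block that keeps every decoder stage
uniformly sized). The decoder mirrors the encoder with three
squeeze/transposed-conv/expand blocks; each output is concatenated with
the matching skip feature and fused by a 3×3 convolution. A two-step
transposed-convolution tail restores full resolution and a 1×1 convolution
with logistic squashing emits the lesion probability map.

Two plug-in modules define the method:

**Feedback Fusion Block (FFB).** Placed on the encoder pairs (E1,E2),
(E2,E3), (E3,E4); its output replaces the raw shallow feature on the skip
connection. The deep feature N (2C×H/2×W/2) is reduced by global **max**
pooling, projected by a 1×1 convolution to C channels and squashed to
[0,1], giving a per-channel weight N′ that gates a 3×3-convolved copy of
the shallow feature M; the gated map is concatenated with the original M,
then with the bilinearly upsampled N, and a 1×1 convolution restores C
channels. Max pooling is the documented reduction; average pooling and an
unbounded linear gate are exposed as configuration for sensitivity checks.
The logistic squashing of N′ is our choice — the weight map is described
only as a weight matrix, and an unbounded multiplicative gate destabilises
training.

**Attention Mechanism Block (AMB).** Applied after each of the three
decoder skip fusions: squeeze-excite channel attention (global average
pool, C→C/r→C bottleneck with rectifier, logistic gate; r = 16 by
default), then a spatial attention built from across-channel statistics.
Besides the conventional per-position maximum and mean, the statistic set
includes the per-position **mode**: at each pixel the C channel values are
quantised into `mode_bins` equal-width intervals spanning that pixel's own
[min, max] range (32 bins by default; a degenerate range returns the
common value) and the midpoint of the most populated interval is taken,
ties resolved toward the smaller midpoint. The selected statistic maps are
summed and normalised — softmax over all H·W positions by default (the
documented choice), or an independent per-position logistic, which avoids
the tiny weights a softmax over thousands of positions produces. The
output is the gated residual A′′ = A′ + WP⊙A′, which preserves the C×H×W
shape; a channel concatenation would not. The mode statistic is piecewise
constant, hence excluded from gradient flow; gradients reach the input
through the max/mean branches and the residual path.

## Loss and metrics

Training minimises the soft Dice loss
L = 1 − (2·Σᵢyᵢpᵢ + ε)/(Σᵢyᵢ + Σᵢpᵢ + ε) over all pixels of the batch,
with ε = 1 defining the all-empty case (a perfect empty prediction scores
0). Metrics are the literal confusion-count ratios — sensitivity,
specificity, precision, Jaccard, Dice, accuracy — with no smoothing; a
zero denominator marks the metric undefined and it is skipped in
averages. Set-level results are per-image means (the ISIC-challenge
convention), with the pooled-counts variant reported alongside because
either aggregation is defensible. Predictions are binarised at 0.5.

## Training protocol

Kaiming-normal initialisation (fan-in, rectifier gain), the
adaptive-moment optimiser, and defaults of learning rate 1e-4, batch size
12, 200 epochs, no augmentation and no learning-rate schedule. Model
selection keeps the best-validation-Jaccard checkpoint (the alternative,
last-epoch weights, is not clearly specified anywhere; best-validation is
the safer convention and is recorded in the checkpoint metadata). All
randomness — initialisation, shuffling, the synthetic generator — derives
from a single integer seed, and runs are bit-reproducible.

## Dataset protocol

ISIC-layout folders (`images/*.jpg`, `masks/*_segmentation.png`), resized
to 256×256 — bilinear for images, nearest-neighbour for masks (preserving
binarity) with a 128/255 threshold. Splits: the 2594 annotated ISIC2018
training images are shuffled and partitioned 70/10/20 % into
train/val/test; for ISBI2017 (2000 train / 600 test) and ISBI2016
(900 / 379) the training pool is used whole and the test pool is split 1:4
into validation:test. Earlier partitions round down, the remainder goes to
the last; the split seed (default 42) is written into the manifest.
Identifier counts that differ from the published sizes warn rather than
fail, since the challenge archives have been re-released over time.

## Synthetic data

The generator emulates the documented challenge modes of dermoscopy:
star-convex lesion blobs whose radius is modulated by a random cosine
series of orders 2–8 (total relative amplitude ≤ 0.22) for irregular
contours; a lesion fill equal to the local skin colour darkened by
0.65·contrast, so `contrast` is a monotone difficulty knob (verified via
Otsu between-class variance); Gaussian-blurred blending for fuzzy edges;
dark quadratic-curve hair strokes of width 1–3 px; bright ring bubbles;
low-frequency illumination shading (±0.06 around a 0.75 skin luminance);
and additive Gaussian noise. The mask is the unblurred blob, so boundary
blur creates genuine label ambiguity. What it does **not** model:
photographic colour statistics, multi-lesion images, vignetting, ruler
markers, or the hierarchical internal texture of real lesions — so passing
tests demonstrate that the architecture, losses and harness work, not that
the network reaches clinical-grade accuracy on real dermoscopy.

## Numerical backend

The network runs on a small reverse-mode autodiff engine over NumPy:
convolutions by kernel-offset slicing and GEMM, transposed convolution as
an exact non-overlapping 2×2 expansion, bilinear resampling as a cached
sparse matrix (half-pixel centres, clamped edges), batch norm with running
statistics, softmax in max-shifted form. Every primitive is checked
against central-difference gradients in the test suite; the feedback block
is additionally checked against a hand-composed pipeline built from
scipy.ndimage correlation and explicit interpolation formulas. Parameters
are float32; the mode statistic bins in float64 so its histogram is
well-defined to the last ulp.

## Scaled study sizes

Full-scale training (width 64, 256×256, 200 epochs) is a GPU-scale
undertaking; the package's own end-to-end study runs at reduced size as a
deliberate design point: width 16, 64×64 images, 200 training / 10
validation / 50 test synthetic samples at contrast 0.5, learning rate 1e-3
(appropriate for the short schedule), batch 12, at most 30 epochs with
early stop once validation Jaccard reaches 0.9. Under these conditions the
full model converges in well under 30 epochs and reaches test Jaccard near
0.9. The two-epoch ablation grid exercises all four module combinations
and all five spatial-statistic combinations; at that length its ranking is
noisy and is reported as a harness demonstration, not as evidence of
module superiority.

## Known limitations

* Single CPU only; no GPU, mixed precision or data augmentation.
* With small widths, reduction 16 leaves the decoder-level channel
  attention a one-unit bottleneck whose rectifier can die at
  initialisation; lower `reduction` when `base_width` < 32.
* `pretrained_encoder` is reserved: no pretrained weights are distributed,
  so enabling it raises a configuration error.
* The softmax spatial normalisation yields weights of order 1/(H·W);
  the residual formulation keeps the block useful regardless, and the
  per-position logistic is available as an alternative.
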