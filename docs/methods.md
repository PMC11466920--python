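# Methods

## Model

`duoseg` segments single-channel square images (side divisible by 32, values
in [0, 1]) into binary lesion masks with a U-shaped encoder–decoder.

**Resolution plan.**  The CNN branch uses a stride-1 residual stem and four
stride-2 residual stages, so its maps sit at H, H/2, H/4, H/8, H/16.  The
attention branch's overlapping patch embedding is two (stride-2 conv,
stride-1 conv, GELU, token-wise LayerNorm) sets, landing at H/4 with the
width of CNN stage 3; its three stages therefore pair exactly with CNN
stages 3–5, which is what makes per-stage fusion well-defined.  The config
validator enforces `swin_dims[i] == cnn_channels[i+2]`.

**Windowed attention.**  Each attention stage applies `depth` block pairs:
a window multi-head self-attention (W-MSA) block and its shifted twin
(SW-MSA), each wrapped as pre-norm residuals with a GELU MLP.  SW-MSA rolls
the token grid by ⌊M/2⌋ and masks attention between tokens that wrapped
around from non-adjacent regions (additive −1e9 logits).  When a single
window covers the whole grid the shift is clamped to zero, the standard
convention, since rolling a single fully-connected window only partitions it
needlessly.  A learned relative-position bias table ((2M−1)² entries per
head) is added to the logits; it can be disabled, and the oracle-equivalence
tests run with it off so the comparison is against plain dense attention.

**Cross-attention fusion.**  Both directions of cross attention are computed
over all N = H·W tokens exactly — the fused stages sit at H/4 and below, so
N ≤ 4096 at the 256-px default and ≤ 256 at the 64-px desk scale.  A config
flag enables stride-2 key/value pooling for larger inputs (off by default).
The logit scale is 1/√d_head in both directions, matching the bottleneck's
spatial attention.  No positional encoding is used inside fusion, making the
operator token-permutation equivariant (tested).  The ablation stand-in for
fusion is channel concatenation followed by a 1×1 convolution.

**Bottleneck.**  The deepest attention map, CNN map, and fusion map are
concatenated (3C channels), linearly embedded at patch size 1 (the grid is
already H/16; keeping the grid lets the four decoder stages restore exactly
H), LayerNorm-ed, and passed through `num_blocks` dual-attention blocks.
Each block runs a GSA sub-block then a GCA sub-block (order configurable),
each a pre-norm residual attention plus a pre-norm residual MLP.  GCA's
logit scale is 1/√C by default (consistent with the √d convention) and can
be switched to 1/C; GCA is single-head over channels.  The analytic
multiplication counts exposed by `flops_wmsa/gsa/gca` are the polynomials
`4hwC² + 2M²hwC`, `4hwC² + 2(hw)²C`, and `2hwC² + 2(hw)²C`; an instrumented
single-head GSA forward reproduces its polynomial exactly under the
one-multiplication-per-product-term counting convention.  Note the GCA
polynomial describes a two-projection accounting of channel attention; the
implemented module uses four projections like its spatial counterpart, so
the polynomial is an analytic complexity statement, not an instruction count
of this implementation (the GSA polynomial is both).

**Decoder and ablations.**  Deconvolutions use kernel 2 = stride 2 so
extents double exactly (5 → 10, never 9 or 11).  Skips: decoder stages 1–2
take the stage-2 and stage-1 fusion outputs; stages 3–4 take CNN stages 2
and 1.  The deepest fusion output feeds only the bottleneck.  With the CNN
branch disabled, the two high-resolution skips come from two lightweight
conv-BN-ReLU stems (stride 1 at H, stride 2 to H/2) — the attention branch
alone has nothing above H/4, and this is the smallest addition that keeps
the decoder intact; it is the largest interpolation in the design.  With the
attention branch disabled the model reduces to a residual CNN U-Net.  GSA
and GCA sub-blocks can be dropped independently.  The prediction head is a
1×1 convolution and sigmoid; masks binarise at threshold 0.5 with strict
`>` (ties to background).

## Defaults

| parameter | default | tiny preset | note |
| --- | --- | --- | --- |
| cnn_channels | 32…512 | 8…128 | doubling per stage |
| swin_dims / heads | 128,256,512 / 4,8,16 | 32,64,128 / 4,8,16 | head dim 32 (8 tiny) |
| swin_depths | 1,1,1 | 1,1,1 | one W-MSA+SW-MSA pair per stage |
| window M | 8 | 4 | stage grids must divide by M |
| bottleneck | 512 dim, 2 blocks | 128 dim, 2 blocks | |
| decoder_channels | 256,128,64,32 | 64,32,16,8 | |
| training | 200 epochs, batch 8, Adam 1e-4→1e-5 cosine, 256 px | — | β₁ = 0.9, β₂ = 0.999 |

The architecture widths/depths follow compact hierarchical-attention
conventions sized so the tiny preset (≈1.9 M parameters) trains on one CPU.
The cosine schedule anneals per epoch from `lr` at epoch 0 to exactly
`min_lr` at the last epoch.  "Momentum 0.9" is read as Adam's β₁.  No data
augmentation by default; horizontal flips are available behind a flag.
Batch norm uses batch statistics in training and running statistics in
evaluation.  Weight init is truncated normal (std 0.02) for linear/attention
weights and Kaiming-normal for convolutions, all drawn from one seeded
generator so model construction is reproducible.

## Numerical core

The network runs on a small reverse-mode autodiff engine over float64 NumPy
arrays (`duoseg.nn`).  Convolutions use an im2col/strided-view forward with
explicit col2im adjoints; transposed convolutions are restricted to
kernel = stride (the only case the decoder needs, and the case with no
output-window overlap).  Softmax and LayerNorm are compositions of
primitives; every primitive adjoint is checked against central finite
differences, and the attention operators against dense brute-force oracles
(relative error < 1e-5; observed ≈ 1e-15).  Shape-moving ops return
C-contiguous arrays, which keeps elementwise kernels stride-friendly — on
one CPU a tiny-preset training step at batch 8 on 64-px images takes ≈ 1.4 s.

## Synthetic phantoms

The generator emulates the ultrasound failure modes the model targets:
1–3 elliptical lesions (rasterised by the exact ellipse inequality, axes and
rotation randomised, overlap allowed, fully inside the frame), darkened by a
per-image contrast drawn from [0.1, 0.35]; a smooth background field (base
0.6 plus a low-frequency Gaussian random field of amplitude 0.05); Gaussian
blur (σ = 1 px) of the clean field before noise, so boundaries are blurred
but the noise is not; an optional vertical shadow band below a lesion
(probability 0.3, fading 0.75→0.5); and multiplicative gamma speckle with
mean 1 and shape 4 (variance 0.25), then clipping to [0, 1].  One
`numpy.random.Generator` drives everything, so datasets are byte-identical
per seed.  Images and {0, 255} masks are written as 8-bit PNG with a CSV
manifest and 80/10/10 splits.

What the phantoms do *not* model: beam-forming physics, depth-dependent
attenuation and focus, anatomical texture, operator variability, or
inter-device differences.  Passing tests on phantoms therefore demonstrates
that the architecture, losses, metrics, and training loop are correct and
that the model can learn low-contrast speckled lesions — not clinical-grade
performance; real-dataset training uses the same manifest format but is out
of scope here.

## Metrics

IoU, Dice and accuracy come from integer confusion counts; when both masks
are empty the overlap metrics are 1.0 by convention (logged).  HD95 uses
boundary pixels (mask minus its one-pixel 8-connected erosion, with the
frame border counting as background) and pools the two directed
nearest-neighbour distance sets before taking the 95th percentile — the
common convention in medical-segmentation tooling; a max-of-directed variant
and an all-pixel variant exist behind flags since conventions differ across
tools.  Distances are in pixels unless a physical spacing is supplied.
Dataset aggregation is the mean of per-image metrics, with NaN (empty-mask)
HD95 values excluded.  The loss reads the 0.5 weight as binding to the
cross-entropy term only, and the soft-Dice term uses smoothing constant 1.

## Problem sizes used by tests and the acceptance script

Training-based checks run the tiny preset on 64-px phantoms: the overfit
smoke test uses 16 phantoms with an aggressive recipe (Adam 1e-3 annealed to
1e-5, batch 4, early stop at train Dice 0.95, cap 300 steps); the ablation
benchmark uses 200 phantoms (160/20/20 split) and 8 epochs at batch 8 per
variant — enough to rank the full model against the single-branch variants,
not to converge any of them.  These sizes are the package's desk-scale
defaults for self-verification; larger runs only change the schedule and the
manifest.

## Known limitations

- CPU-only and float64: fine at desk scale, not for 256-px training runs of
  realistic width.
- Single-class sigmoid head only; no deep supervision, no pretrained
  initialisation.
- Exact N×N fusion attention is quadratic in token count; enable the K/V
  pooling flag beyond ~96-px inputs if memory matters.
- The single-branch decoder stems are an interpolation where the design
  space was genuinely open; ablation numbers for those variants depend on it.
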