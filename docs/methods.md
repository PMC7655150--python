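# Methods

## Problem and pipeline

Camera-based (non-contact) vital-sign monitoring estimates heart rate and
respiratory rate from subtle color and shape changes of a patient's skin in
ordinary video. In a neonatal intensive-care setting this only works during
periods when the infant is actually in front of the camera and nobody is
interacting with it, and only over pixels that really are skin. The package
therefore chains three stages:

1. **Patient detection + skin segmentation.** A single multi-task
   convolutional network per frame: a shared convolutional core feeds (a) a
   detection stream — 1×1 convolution with two outputs on the last pooling
   stage, global average pooling, softmax over {absent, present} — and (b)
   a segmentation stream in the FCN-8s pattern: 1×1 score convolutions on
   pooling stages 3, 4 and the coarsest stage, transpose-convolution
   upsampling ×2, ×2 and ×8 with skip additions, and a per-pixel softmax
   producing a skin-confidence map in [0, 1]. Segmentation is evaluated
   only when the detection stream finds the patient (conditional
   execution); thresholding the confidence map (default θ = 0.5) yields a
   binary skin label.
2. **Intervention detection.** A sliding window of length T = 5 s, step
   τ = 1 s, samples 6 frames one second apart. Two convolutional streams
   process the window: the context stream over the 6 stacked
   skin-confidence maps and the motion stream over the 10 stacked optical
   flow components (5 consecutive-pair flows × u, v), encoded through an
   8-bit codec that clips each component at ±40 px and maps it linearly to
   [0, 255]. The streams' final feature maps are concatenated, fused by a
   1×1 convolution (512 outputs by default), globally average-pooled and
   classified into intervention / non-intervention. Per-second states come
   from averaging the intervention probability of every window covering
   that second (threshold 0.5); a second whose sampled frame is classified
   patient-absent is `absent`, which overrides everything else. The three
   states partition the recording.
3. **Signal extraction.** During `valid` seconds, the PPGi (cardiac)
   waveform is the spatial mean of the green channel over the skin mask
   per frame; the respiratory waveform is the skin-area series (centroid
   and perimeter series are also computed). Both are detrended with a
   moving-average baseline (window = 2× the slowest period in the
   physiologic band), peaks are counted with a minimum separation of one
   period at the band's maximum rate, and rate = peaks × 60 / duration
   over sliding 30 s analysis segments.

## Training recipes

The skin network trains in two stages with SGD + momentum 0.90, batch 20:
stage 1 fits the core and segmentation stream on patient-present images
only (lr 10⁻², tenfold drop every 2 epochs); stage 2 fits everything
jointly on positives and negatives with the detection and segmentation
losses weighted equally (lr 10⁻⁴, same decay). The detection loss is the
multinomial logistic loss; the segmentation loss is the per-pixel logistic
loss weighted by 1/(2·class frequency) and normalized so any uniform
predictor scores ln 2 regardless of class imbalance (single-class truths
fall back to a plain mean). Log-loss probabilities are clamped at 10⁻¹².

The intervention network trains its two streams individually first (lr
10⁻³, tenfold drop every 12 000 iterations, batch 24) under a temporary
global-pool + fully-connected head, sampling every batch uniformly across
the two classes, then trains only the post-fusion layers (lr 10⁻⁵, drop
every 6000 iterations, batch 12). A window is labeled intervention iff
strictly more than half of its labeled seconds are intervention; windows
touching absence are excluded from training.

**From-scratch schedules.** The published stage-2/fusion learning rates
(10⁻⁴, 10⁻⁵) assume streams initialized from large pretrained backbones,
where late stages only fine-tune. The desk-scale `tiny` backbones here are
trained from random weights, and at those rates the freshly initialized
detection head and fusion layers receive steps far too small to converge
before the decay extinguishes the rate. `from_scratch_schedules()` and
`from_scratch_fusion_schedule()` therefore keep the stage-1 rate (10⁻²
resp. 10⁻³) for those stages while preserving the decay law, batch sizes
and momentum. The published values remain the defaults.

## Architectural parameters

- **Backbones.** `vgg16` reproduces the 13-conv topology with
  fully-connected layers converted to convolutions (7×7/4096, 1×1/4096)
  and batch normalization inserted between each convolution and its ReLU;
  `tiny` is the test-scale stand-in with five single-conv pooling stages
  (8–32 filters) so the input is still subsampled by 32. Input sizes must
  be divisible by 32 (512 for the full model, 64–128 for tiny). Transpose
  convolutions are initialized as bilinear interpolation filters with no
  bias; score convolutions use Xavier initialization with zero bias.
- **Streams.** `resnet50` builds the bottleneck topology ([3,4,6,3],
  output 2048 channels) headless; `tiny` uses three stride-2
  convolutions. The first convolution of each stream is extended to 6 or
  10 input channels by averaging the 3-channel kernels over the input axis
  and replicating — the standard cross-modality initialization — so the
  channel-summed response is preserved up to the 6/3 or 10/3 factor.
- **Flow.** Dense flow uses the variational TV-L1 solver by default
  (`ilk`, iterative Lucas–Kanade, is the fast backend used for bulk window
  extraction). The codec clips symmetric magnitude at 40 px — displacement
  above 40 px/s is rare in an incubator scene — and quantizes with
  round-half-up, so 0 px codes to 128 and the lossless-container
  round-trip error is at most (80/255)/2 ≈ 0.157 px per component. JPEG
  storage (quality 90) adds its own bounded error; a YAML sidecar carries
  the clip limit for bit-exact decoding.

## Annotation module

The semi-automatic annotation loop is segment → fit → propose → segment.
`gsc_segment` minimizes unary (negative log-likelihood under per-class
Gaussian mixtures fitted to the brush-stroke pixels) plus a
contrast-sensitive boundary term λ·exp(−‖ΔI‖²/2β)/dist on the 8-connected
grid, solved as an s–t min-cut (capacities scaled to integers for
`scipy.sparse.csgraph.maximum_flow`; seeds get effectively infinite
terminal capacities). Geodesic star convexity is enforced with the
infinite-cost arc construction: every pixel gets an infinite-capacity arc
to its geodesic parent on a gradient-magnitude-weighted grid (multi-source
Dijkstra from the star centers), which forbids a skin pixel with a
non-skin parent. With λ = 0 and the shape prior off, the cut provably
degenerates to per-pixel maximum likelihood, which the tests verify. GMMs
default to 5 components per class with a covariance floor of 4
(intensity²) — brush strokes can be a handful of pixels, so covariances
need a sensor-noise-scale floor to generalize. Seed proposal places
points inside regions with posterior ≥ 0.9 using Mitchell's best-candidate
(farthest-point) sampling, 10 candidates per placement. Consensus uses
2-of-3 quorums at both the image and pixel level; the agreement score is
|pixels with ≥2 votes| / |pixels with ≥1 vote| (defined as 1 on an empty
union).

## Synthetic scenes

The simulator renders the study conditions at desk scale: one
skin-colored ellipse (semi-axes 0.35 W × 0.27 H) on a dark incubator
background, green channel modulated by 1% at the cardiac frequency
(default 150 beats/min), ellipse area modulated by 5% at the respiratory
frequency (default 50 breaths/min), a 5% multiplicative lightness drift
with a 20 s period, additive Gaussian sensor noise (σ = 1 intensity
unit), nominal 20 fps. `occluder` events sweep a block of distinct chroma
across the scene at 60 px/s (> 40 px/s, so encoded flow saturates);
`absence` events remove the ellipse. The default frame size is 128×128:
at the segmentation stream's stride-8 skip resolution this leaves enough
boundary detail for meaningful overlap scores, while keeping one-CPU
training runs in minutes. Deliberately not modeled: specular reflection,
shadows cast by staff, phototherapy lighting, camera pose changes, and
realistic infant texture/pose — so passing tests demonstrate that the
pipeline's machinery (conditional execution, window bookkeeping, codec,
training dynamics, rate estimation) is correct, not that the tiny
networks would segment real NICU video.

## Problem sizes used by the test suite

Chosen as the smallest sizes at which each recovery check is meaningful:
the segmentation network trains on 200 frames (20 s at 10 fps, one
absence stretch) for 6 + 6 epochs and is evaluated on a held-out
recording (different seed); the intervention network trains on ~448
windows from eight 60 s recordings at 2 fps (balanced occluder/quiet) for
300 + 300 iterations and is evaluated on 56 held-out windows; end-to-end
rate recovery uses a clean 30 s recording at 20 fps through the trained
segmenter. Flow for window stacks uses the `ilk` backend at 64×64.

## Numerical choices and edge cases

- Letterboxing: bilinear content resize onto a square canvas; landscape
  sources pad top/bottom, portrait pad left/right; an odd padding
  remainder goes to the bottom/right; padding is black and applied before
  mean subtraction. Masks letterbox with nearest-neighbour so labels stay
  binary. The 1620×1236 camera frame onto 512 gives a 512×391 content box
  with 60/61 px bars.
- Channel means are computed once from the training corpus (positives for
  the skin net) and stored with the checkpoint, never recomputed at
  inference.
- Lighting augmentation scales the HSL lightness channel multiplicatively
  with clipping to [0, 1]; the four histogram intervals are uniform
  between the corpus minimum and maximum average lightness, and an empty
  interval falls back to its center. Rotations fill exposed corners with
  black; masks rotate nearest-neighbour.
- Max pooling breaks ties toward the first maximum. Batch normalization
  uses running statistics (momentum 0.1) at evaluation.
- Peak detection runs separately on each contiguous valid run, so peaks
  never straddle masked-out intervals; the prominence floor is 0.2× the
  valid-sample standard deviation.
- The per-second window aggregation (mean probability, threshold 0.5) and
  the absence-precedence rule are this package's choices where several
  readings are defensible; both are isolated behind `predict_timeline`.

## Known limitations

- The numpy layer engine is single-threaded BLAS-bound; the full `vgg16`
  and `resnet50` topologies are built and forwardable but impractical to
  train here, and no pretrained weights are shipped.
- The flow backends are generic variational/Lucas–Kanade solvers; very
  large displacements beyond the codec clip are only represented as
  saturation.
- Respiratory extraction assumes segmentation quality is stable across
  frames; systematic boundary bias cancels, but frame-to-frame mask
  jitter adds broadband noise to the area series.
- The annotation min-cut scales to roughly 10⁴–10⁵-pixel images; full
  1620×1236 frames would need a hierarchical or banded solver.
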