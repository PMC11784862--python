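# Methods

## Task and model

The package estimates left-ventricular ejection fraction (EF, in percent)
directly from grayscale echocardiogram video. EF is defined from the
end-diastolic and end-systolic volumes as EF = (EDV − ESV)/EDV × 100; the
network never sees volumes, only pixels, and is trained with mean squared
error on the EF percent scale.

The regressor is a 3D ResNet-18 adapted to single-channel video input
(3×7×7/64 stem, stride 1×2×2, no temporal downsampling in the stem; four
stages of two basic blocks at 64/128/256/512 channels; stride-2
projection-shortcut downsampling at the conv3/conv4/conv5 transitions; global
average pooling; fully connected 512→1 head). Convolutions carry no bias —
the affine pair of the batch norm that follows each one supplies the shift —
and the plain backbone in this configuration has exactly 33,147,969 trainable
scalars, which the acceptance script recounts from the instantiated arrays.

In stages conv3 and conv5 the second basic block is replaced by a Residual
Transformer Module,

    y = BN( MHSA( ReLU(BN(Conv(x))) + x ) ),

taken literally: one channel-preserving 3×3×3 convolution, batch norm, ReLU,
the residual addition *before* the attention, attention, and a final batch
norm with no trailing ReLU. This is a deliberate deviation from the standard
post-activation residual block; the composition above is the module's
defining equation and the test suite checks the block equals the
hand-composed chain. The stage's first block performs the downsampling, so
the conv3 attention runs on a (T₀/2, H₀/4, W₀/4) grid at D=128 and the conv5
attention on (T₀/8, H₀/16, W₀/16) at D=512.

### 3D attention with decomposed relative position encoding

Attention flattens the feature map to N = T·H·W positions. Q, K, V are 1×1×1
convolutions (channel-wise linear maps with bias, D→D); per head i (head dim
d = D/n_heads) the logits are

    ( QᵢKᵢᵀ + Qᵢrᵀ + rKᵢᵀ ) / √d,

row-softmaxed, applied to Vᵢ, and the head outputs are concatenated — there
is no output projection. The position term r = R_t + R_h + R_w is the
broadcast sum of three learned tables (T×D×1×1, 1×D×H×1, 1×D×1×W), applied
identically on the query and key sides (one shared r, sliced per head).
Without r the operation is permutation-equivariant over positions; with it,
attention becomes sensitive to a frame's phase within the cardiac cycle and
to image geometry — the property the permutation test in the suite
demonstrates directly.

Open design points resolved here: the head count is not architecturally
constrained (Q/K/V are full D→D maps, so the parameter count is
head-invariant); the default is 4, which divides both 128 and 512. RPE tables
initialize from N(0, 0.02²). A guard refuses attention over more than 50,000
flattened positions unless explicitly overridden (full-resolution conv3
attention at 16×28×28 = 12,544 positions is well inside).

### Parameter counts

Two totals are meaningful and both are exposed: the plain backbone
(33,147,969) and the RTM-substituted network (26,481,601 for the default
input size — smaller, because each RTM trades a 27·D² convolution for three
(D²+D) projections plus (T+H+W)·D position tables). The tests verify both
against an independent closed-form per-layer summation.

## Numerical implementation

All layers (3D convolution via im2col, batch norm, ReLU, linear, global
average pooling, the attention module) and Adam are implemented in NumPy with
explicit, hand-written backward passes. Correctness is established by
independent oracles rather than by construction:

- the vectorized attention is tested against a scalar, loop-per-query/key
  reference implementation that shares no code with it (≤1e-5 max abs over
  100 random instances);
- convolution forward is tested against scipy correlation;
- every backward pass is tested against central finite differences in
  float64 (layer-wise and through composite blocks).

Training arithmetic is float32. The convolution input gradient is computed
as a col2im fold (one strided in-place add per kernel offset), which keeps
peak memory at the size of the im2col matrix. Softmax subtracts the row
maximum before exponentiation. Batch norm uses eps=1e-5 and running-stat
momentum 0.1 (biased batch variance for normalization, unbiased for the
running estimate); evaluation mode uses running statistics. Convolution
weights use He initialization; the FC head initializes its weights at
N(0, 1/512) and its bias at 50 — the midpoint of the percent scale — so the
regressor starts from a neutral EF prior instead of spending early updates
dragging a scalar bias across ~50 points.

Checkpoints are zip archives of named parameter and running-stat arrays plus
the serialized model configuration, written with fixed timestamps so that
identical seeded runs produce byte-identical files.

## Data pipeline

A dataset root holds `Videos/<id>.avi`, a `FileList.csv`
(FileName, EF, ESV, EDV, FPS, NumberOfFrames, Split) and an ED/ES annotation
CSV (FileName, ED_Frame, ES_Frame); frame indices are 0-based. Records
missing an ED/ES annotation are dropped with a warning (they cannot supply
training windows); invariant violations (ESV > EDV, EF outside [0,100], EF
inconsistent with the stated volumes beyond 0.5 points, out-of-range frame
indices) are hard errors naming the offending videos. AVI I/O is a minimal
uncompressed RIFF reader/writer (24-bit DIB frames, grayscale replicated
across channels, ITU-R 601 luma on read), so fixture round trips are
bit-exact; lossy codecs are out of scope.

Training clips are clip_len consecutive frames drawn uniformly inside the
inclusive [min(ED,ES), max(ED,ES)] window — the systolic sweep that carries
the EF signal. Windows shorter than the clip are extended symmetrically into
the video; a video shorter than the clip repeats its final frame. One clip is
drawn per video per epoch, keeping epochs patient-balanced and comparable
across clip lengths. Inference uses *all* frames: non-overlapping clip_len
segments (trailing remainder dropped; repeat-padding only when the whole
video is shorter than one segment), forwarded independently and averaged.
Validation during training uses the same segment-averaged procedure, and the
best-validation-MAE epoch is the model retained.

Augmentation (training split only) draws one parameter set per clip and
applies it to every frame, preserving temporal coherence: rotation uniform in
±25° (bilinear, padding with the normalized black level −1 to match the cone
background), horizontal flip p=0.5, brightness/contrast on the [0,1] gray
scale (delta ±0.2, factor 0.8–1.2), Gaussian blur p=0.5 (σ ∈ [0.3, 1.5]),
and JPEG-style compression p=0.1 (quality 30–90). Only the probabilities and
the rotation range are prescribed by the reference recipe; the magnitudes are
this package's declared defaults.

Splits are 80/10/10 by seeded shuffle with contiguous partition; sizes are
floor(n·f) with remainders assigned to TRAIN (10,030 videos → 8,024/1,003/
1,003). The training loop never touches TEST-split videos, which the suite
asserts with an access-auditing dataset wrapper.

## Synthetic phantoms

The generator emulates the statistical shape of a real echocardiography
cohort without modeling ultrasound physics. Each phantom draws a target EF ~
U(15, 80) % and EDV ~ N(91, 45.7) mL truncated to [40, 250] (cohort-scale
moments), and renders `cycle_frames × n_cycles` frames (defaults 16 × 2 at
50 fps) of a dark elliptical blood pool inside a bright myocardial ring,
embedded in an ultrasound cone mask with multiplicative speckle
(pixel·(1+σg), σ = 0.15 by default). The per-frame volume follows a raised
cosine between EDV and ESV; `cycle_frames` must be even so the trace attains
ESV exactly, making the labeled EF exact rather than approximate. The pool's
pixel area scales as volume^(2/3) — a single cross-section of a 3D volume —
so appearance is strictly monotone in volume without pretending to model
true ventricular geometry. ED is the frame of maximal volume (cycle start)
and ES the first minimum after it.

What the phantoms do *not* contain: real speckle statistics or point-spread
functions, anatomical variability, valve/atrial structures, probe motion,
view-angle variation, or annotation noise. Passing the phantom-recovery test
therefore shows the architecture and pipeline can extract a volume-motion
signal end to end; it says nothing about clinical accuracy on real loops.

## Reduced-scale demonstration

The self-contained learning check trains a reduced network (stem 8, stages
8/16/32/64, two heads) on 300 phantoms at 32×32 with 8-frame clips for 15
epochs at batch 16 — 225 gradient steps, about two minutes on one CPU. Two
training-recipe choices differ from the full-scale defaults, deliberately:
Adam starts at 1e-3 with the step decay moved to epoch 8 (a 45-epoch/1e-4
schedule barely moves a small network in 225 steps), and augmentation is
disabled (a quarter-rotation/compression pipeline is a regularizer sized for
10⁴ real videos; at 225 steps it dominates the signal — with it on, held-out
MAE degrades from ~9.8 to ~12). Architecture, epoch count, batch size, clip
geometry and the generator's cohort parameters are not touched. On the
held-out 30 phantoms this run reaches MAE ≈ 9.8 EF points and R² ≈ 0.66.
Results at this scale are visibly seed-sensitive (different init seeds move
held-out MAE by several points); the pinned-seed run is a reproducible
existence proof, not a performance estimate.

## Known limitations

- NumPy-only training is single-threaded-CPU bound; the full 112×112,
  16-frame configuration is practical for forward passes and shape/count
  verification, not for full-scale training.
- Only uncompressed AVI containers are read; real clinical exports are
  usually lossy-compressed and would need transcoding.
- The EF < 40 % F1 score is reported as NaN when neither truth nor
  prediction contains a positive (the binary task is vacuous); R² is NaN for
  zero-variance truth, with a warning in both cases.
- Whole-video inference vs ED–ES-restricted training is an asymmetry
  inherited from the method description: segments covering diastole are
  out-of-distribution relative to training clips. Segment averaging
  mitigates but does not remove this.
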