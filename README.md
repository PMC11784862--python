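# efnet

Automatic estimation of left-ventricular ejection fraction (LVEF) from
echocardiogram cine loops, using a 3D ResNet-18 video-regression network whose
residual blocks at two stages are replaced by **Residual Transformer Modules**
(RTM): residual blocks whose second convolution is swapped for 3D multi-head
self-attention with a decomposed relative positional encoding.

The package is aimed at researchers working on video-based cardiac function
assessment: it contains the full pipeline — dataset I/O in the standard
echocardiography layout (AVI videos plus CSV manifests), a synthetic phantom
generator with analytically known EF, training-time augmentation, the network
itself with hand-verified gradients, the training loop, and segment-averaged
patient-level evaluation — with no GPU or external data required.

## The model

Ejection fraction is the fraction of end-diastolic blood volume ejected per
beat,

    EF = (EDV − ESV) / EDV × 100 ,

where EDV and ESV are the left-ventricular volumes at end-diastole and
end-systole. The network regresses EF directly from pixel data: a clip of
T₀ = 16 consecutive grayscale 112×112 frames, normalized per pixel by

    x ↦ (x − mean·max_pixel_value) / (std·max_pixel_value),  mean = std = 0.5,

so 8-bit gray levels land on [−1, 1].

The backbone is a 3D ResNet-18: a 3×7×7/64 stem with stride 1×2×2, then four
stages of two basic blocks at 64/128/256/512 channels (each basic block is
conv–BN–ReLU–conv–BN plus a shortcut, with 1×1×1 projection shortcuts at the
stride-2 stage transitions), global average pooling, and a 512→1 fully
connected head. In stages conv3 and conv5 the second basic block is an RTM:

    y = BN( MHSA( ReLU(BN(Conv(x))) + x ) ) ,

a single 3×3×3 convolution followed by attention over all T·H·W positions of
the feature map. Attention logits for head i are

    ( Qᵢ Kᵢᵀ + Qᵢ rᵀ + r Kᵢᵀ ) / √d ,   d = D / n_heads ,

where Q, K, V come from 1×1×1 convolutions and the position term
r = R_t + R_h + R_w is the broadcast sum of three learned tables indexed by
frame, row and column — this is what makes the otherwise permutation-invariant
attention sensitive to where in the cardiac cycle a frame sits. At inference,
all frames of a video are split into non-overlapping 16-frame segments and the
per-segment predictions are averaged into one EF per patient.

Everything numerical (3D convolution, batch norm, attention, Adam, backprop)
is implemented in NumPy inside the package and verified against independent
oracles: a loop-based attention reference, scipy correlation for the
convolutions, and central finite differences for every gradient.

## Worked example

Real echocardiography collections are access-gated, so the package ships a
phantom generator: cone-masked, speckled cine loops of a pulsating elliptical
blood pool whose volume follows a raised-cosine cardiac cycle between a drawn
EDV and ESV — hence every video has an exactly known EF, ED frame and ES
frame, written in the same on-disk layout as the real data.

```bash
efnet phantom-gen --n 300 --seed 11 --out demo/ds --size 32 --cycle-frames 16
efnet inspect --data demo/ds
```

```
Number of videos        300
Ejection fraction (%)   45.3 (18.5)
End systolic volume (mL)        56.4 (27.9)
End diastolic volume (mL)       103.2 (36.5)
TRAIN   240
VAL     30
TEST    30
```

Train a reduced network (8/16/32/64-channel stages, 8-frame clips at 32×32 —
about two minutes on one CPU) and evaluate the held-out split:

```bash
efnet train --data demo/ds --config run.yaml --out demo/ckpt
efnet eval  --data demo/ds --ckpt demo/ckpt/best.npz --split test
```

with `run.yaml`:

```yaml
seed: 5
model: {clip_len: 8, height: 32, width: 32, stem_channels: 8,
        stage_channels: [8, 16, 32, 64], n_heads: 2}
train: {epochs: 15, batch_size: 16, lr0: 0.001, lr_step: 8,
        clip_len: 8, augment: false}
```

Training logs one line per epoch (learning rate, train MSE, validation
MSE/MAE, all on the EF percent scale):

```
epoch 0  lr 1.00e-03 train_mse 304.784 val_mse 343.344 val_mae 16.277
epoch 7  lr 1.00e-03 train_mse 65.201  val_mse 117.224 val_mae 8.603
epoch 14 lr 1.00e-04 train_mse 50.827  val_mse 98.873  val_mae 7.747
```

and the evaluation prints

```
mse: 137.4461
rmse: 11.7237
mae: 9.7869
mape: 0.2434
r2: 0.6597
f1_lt40: 0.7333
```

i.e., on 30 held-out phantoms the reduced network recovers EF to within ~10
points on average and explains two thirds of the EF variance — evidence that
the architecture learns EF from wall/pool motion, not a clinical benchmark.
`f1_lt40` is the F1 score of the binary "EF below 40 %" screen (the clinically
relevant reduced-EF flag), and `mape` is the mean absolute percentage error as
a fraction. A single video can be scored with
`efnet predict --video demo/ds/Videos/phantom00000.avi --ckpt demo/ckpt/best.npz`
(here: `29.91` against a true EF of 23.36).

With no config file, `efnet train` uses the full-scale recipe: 16-frame clips,
batch 28, 45 epochs, Adam at 1e-4 with a ×0.1 step decay every 16 epochs,
weight decay 1e-4, and training-clip augmentation (±25° rotation, horizontal
flip p=0.5, brightness/contrast, blur p=0.5, compression p=0.1), with training
clips drawn from the annotated ED–ES window of each video.

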