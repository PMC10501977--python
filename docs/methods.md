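# Methods

## The measurement model

Positioning quality of a knee radiograph is summarized by three numbers
derived from nine landmarks (`A`–`I`). Landmarks `A`/`B` lie on the fibular
diaphysis axis, `C`/`D` are the fibular-head points closest to and furthest
from the tibia, `E` is where the tibial edge crosses the head; on lateral
views `F`/`G` and `H`/`I` lie on the femoral and tibial diaphysis axes.

**Overlap ratio.** With `L1` the line through `A` and `B`, let `Sc`, `Sd`,
`Se` be signed perpendicular distances of `C`, `D`, `E` to `L1`, the sign
fixed so that `C`'s side is positive. The ratio is

```
overlap = clamp( (Sc − Se) / (Sc − Sd), 0, 1 )
```

The signed-distance convention makes one formula cover both the case where
`E` lies between `C` and the axis and the case where it lies beyond the
axis on `D`'s side: `Se` simply turns negative and the ratio keeps growing
continuously. The result is clamped to its defined range [0, 1] and a
`clamped_ratio` flag is raised when clamping fired, since an out-of-range
raw value indicates `E` outside the head. The ratio is invariant under
translation, rotation and uniform scaling of the landmark set, and the
geometry layer guards degeneracies: coincident axis points and a
zero-transverse-width head (|Sc − Sd| below 1e-9 px) raise typed errors.
The 1e-9 px tolerance is far below any annotation precision.

**Flexion angle.** The angle between the directed shaft vectors `F − G`
(femur, distal→proximal) and `I − H` (tibia, proximal→distal), in degrees.
With this orientation convention a fully extended, collinear limb measures
180° and flexion reduces the angle, matching the 0–180 range and the
normalization by 180 used for reporting. Whether the underlying clinical
convention uses directed vectors or undirected lines is not fully
determined by the 0–180 range alone; directed vectors were chosen because
undirected lines cannot distinguish 170° from 10°, which clinically are
opposite extremes. The convention is a module constant, not scattered
logic, so it can be swapped if a site uses the complementary convention.

## Landmark detection

Landmarks are regressed as heatmaps: each landmark owns one channel holding
an amplitude-1 isotropic Gaussian (sigma 2 heatmap pixels) centered at its
position divided by the output stride. Channels of absent landmarks are
identically zero — on AP images the four LAT-only channels (`F`–`I`)
regress to zero rather than being masked. This lets a single network serve
both projections, and lets the projection be identified afterwards from
how many landmarks were detected: the view is called LAT iff at least 3 of
the 4 LAT-only channels have a peak above the detection threshold τ
(default 0.1). The ≥3-of-4 majority rule tolerates one missed landmark.

The network follows the high-resolution (HR-Net) design: a stem of two
stride-2 3×3 convolutions (output stride 4), four stages running parallel
branches at 1/4, 1/8, 1/16, 1/32 resolution with channel widths C, 2C, 4C,
8C, and exchange blocks that fuse every branch into every other (stride-2
3×3 convolutions downward; 1×1 convolution plus nearest-neighbor upsampling
upward, bilinear available via config). Stages 2–4 contain 1, 4 and 3
exchange blocks in the `full` preset. The head maps each branch to C
channels with a 1×1 convolution, upsamples to branch-1 resolution,
concatenates and projects to 9 channels. Every convolution is a
conv–batch-norm–ReLU block, as in the reference architecture; fused branch
sums are averaged to keep activation variance flat, and the final output
convolution is zero-initialized so training starts from the all-zero
heatmap. Fusion takes the standard form: every output branch is the
(averaged) sum of resolution-matched transforms of every input branch.

The network is implemented on a small numpy reverse-mode autodiff core
(convolution, ReLU, batch norm, nearest/bilinear upsampling, concatenation,
MSE). Everything is single-threaded, float32 and bit-deterministic under a
fixed seed. Two presets exist:

* `full`: C=32, input short side 288, exchange repeats (1, 4, 3) — the
  full-scale architecture (≈12.7 M parameters). Provided and tested for
  shape/contract, but no full-scale training is attempted: large-scale
  pretraining and GPU recipes are out of scope.
* `tiny`: C=8, input 64, exchange repeats capped at 2, ≈0.5 M parameters —
  the default experimental configuration; it trains in well under a minute
  per 30-epoch run on one CPU.

**Training.** SGD with momentum 0.9 and weight decay 1e-4 on the mean
per-pixel squared error over all nine channels; batch size 4.
Augmentation: horizontal flip with p=0.5 (x-coordinates remapped; the nine
labels have no left/right pairs, so no label swapping) and intensity
inversion (v → 1−v) with p=0.5, included because radiographic polarity
varies between vendors and viewers.
Full-scale defaults are lr 0.002, 60 epochs with ×0.1 decay at epochs 50
and 56. The tiny preset uses lr 1.0 with ×0.1 decay at 2/3 and 5/6 of the
run: mean-reduced MSE gradients at this scale are tiny, and the value was
chosen by a pilot sweep on synthetic validation phantoms (seeds disjoint
from all held-out evaluation seeds). Training from seeded He-style random
initialization; loss divergence raises a typed error. The MSE is averaged
(not summed) over pixels and channels — this only rescales the effective
learning rate.

**Decoding.** The landmark is the per-channel argmax times the stride, its
score the peak value; ties resolve to the lexicographically smallest
(row, col). Optional sub-pixel refinement (`refine=True`, off by default)
applies a distribution-aware log-space Taylor step: the channel is lightly
smoothed (Gaussian, sd 0.9 cells), and since the training targets are
Gaussians the log-heatmap is locally quadratic, so the mode offset is
`−H⁻¹g` from the gradient and Hessian at the peak cell, clipped to ±1 cell.
At the tiny preset's geometry (16×16 heatmap, stride 4) plain argmax
quantization alone contributes ±2 px per axis, which dominates every other
error source; the scaled-down end-to-end experiments therefore decode with
refinement on, while the default stays off to match the plain
maximum-activation contract.

## The phantom generator

Phantoms are deliberately stylized — bright capsules, slabs and an
elliptical fibular head on a dark background — because the quantities under
test are geometric and algorithmic, not radiographic. What is exact is the
bookkeeping: landmark coordinates are constructed analytically (the tibial
edge is placed so that the signed-distance formula recovers the requested
overlap ratio to machine precision; femoral and tibial axes meet at the
requested flexion angle), and corruptions (Gaussian noise, Gaussian blur,
an occlusion band emulating casts/markers) are applied after landmark
placement, so ground truth never moves. Layouts are built in a local frame
and rigidly centered on the canvas — translation changes neither
criterion — and any landmark within 8 px of a border raises an
infeasible-layout error. Every case derives its random stream from
(dataset seed, case index), so datasets are reproducible case-by-case.

Defaults: 64×64 px canvas, fibular-head radius 9% and shaft width 6% of the
short side, bone-on-dark intensity in [0, 1], 16-bit PNG on disk, CSV
manifest, JSON ground truth. Dataset sampling is uniform over configurable
ranges (overlap 0–1, flexion 90–180°, noise sd 0.005–0.02, blur 0.3–0.8 px,
AP:LAT mix 0.5). The "easy" conditions used by the learning experiments
are LAT-only, overlap 0.2–0.8, flexion 140–175°, noise 0.003–0.008, blur
0.3–0.5, no occlusion.

What the phantoms do *not* emulate: soft tissue, trabecular texture,
exposure variation, pathology such as fractures or osteophytes, projection-specific condyle
anatomy, and realistic fibula–tibia–femur proportions. In particular the
LAT fibular shaft segment `A`–`B` is compressed (~0.09 of the short side)
to fit the canvas; on real lateral radiographs the mid- and distal fibula
are much further apart, which makes the real shaft axis far better
conditioned than the phantom's. Passing tests on phantoms therefore
demonstrate correctness of the geometry, codec, training loop and metrics —
not clinical-grade detection accuracy.

## Evaluation stack

**OKS.** `OKS = Σ_i exp(−d_i²/(2 s² k_i²))·[v_i>0] / Σ_i [v_i>0]`, with
`s²` the area of the smallest axis-aligned box containing all visible
ground-truth landmarks and `k_i = 2σ_i` with σ = 0.083 for the six shaft
landmarks and 0.029 for the three head landmarks (the shaft landmarks are
not unique along the diaphysis, so they get a looser standard). A visible
ground-truth landmark with no prediction contributes 0 (d = ∞). A
zero-area box is a typed error.

**AP/AR.** One ground-truth instance and at most one detection per image;
detection confidence is the mean decoded peak score. At each OKS threshold
detections are ranked by confidence (stable ties), a detection is a true
positive iff OKS ≥ t, AP is the 101-point interpolated area under the
precision-recall curve (COCO convention), AP50/AP75 at t = 0.50/0.75, and
mAP/mAR average over t ∈ {0.50, 0.55, …, 0.95}.

**Agreement.** ICC(2,1) — two-way random effects, absolute agreement,
single rater — computed directly from the ANOVA mean squares
`(MSR − MSE) / (MSR + (k−1)MSE + (k/n)(MSC − MSE))`, with the McGraw–Wong
F-based 95% interval (the interval degenerates to a point at exact
agreement). The implementation is cross-checked in the tests against an
explicit ANOVA decomposition (to 1e-10) and against `pingouin`'s ICC(A,1).
Deviation summaries report mean, sample SD and max of absolute
differences, optionally normalized by a range width (180 for angles) and
rounded to 3 decimals for display. Group comparisons use the pooled-
variance (Student) two-sample t-test via `scipy`.

## Scaled-down study conditions

No clinical images are available, so the learning experiment runs at desk
scale with conditions fixed up front: the tiny preset trained on **64 easy
LAT phantoms** (dataset seed 1, init seed 0, training seed 0) for **30
epochs**, evaluated on **48 held-out easy LAT phantoms** (dataset seed 2)
with refined decoding. Under these conditions training loss falls to 0.06×
its initial value, held-out AP50 reaches 1.0 and AP75 ≈ 0.96, and mAP sits
at ≈ 0.78–0.80 depending on the evaluation seed (0.796 at the frozen one).

The mAP level is resolution-limited, not optimization-limited: on a 64-px
phantom the landmark bounding box spans only ~6×11 heatmap cells, so the
residual ~1.4 px error on the tight-sigma head landmarks costs per-landmark
OKS terms of ~0.75 that no amount of tuning removed (learning-rate,
schedule, batch-size, momentum, weight-averaging and decoding variants were
all evaluated on separate validation seeds). At the full 288-px input scale
the same box spans ~30×50 cells and this floor vanishes. The end-to-end
machine-vs-truth agreement numbers the acceptance script reports inherit
the same limit, amplified for the LAT overlap ratio: a ~6 px head radius
against ~1.5 px landmark noise makes that ratio intrinsically noisy at this
scale (the flexion angle, which depends on long shaft axes, is far more
stable — mean absolute deviation ≈ 5°, ≈ 0.027 normalized). These numbers
are reported as diagnostics of the scaled-down setting, not as estimates of
clinical performance.

## Numerical and design notes

* Coordinates are 0-based pixel centers, x = column, y = row, everywhere.
* Degeneracy tolerance 1e-9 px for coincident points and zero-width heads.
* Heatmap encoding places Gaussians at the exact (float) strided position;
  decoding at stride 1 on integer landmarks is an exact identity.
* Checkpoints are single-file zip archives embedding the config JSON, the
  weights and the training log; QC reports carry provenance (model
  checksum, settings, seed).
* CLAHE parameters default to clip limit 0.01 with an 8×8 tile grid; the
  technique is specified for the preprocessing but its parameters are not,
  so the skimage defaults-adjacent values are exposed as arguments.
  Constant (zero-contrast) images pass through unchanged.
* DICOM reading applies rescale slope/intercept and inverts MONOCHROME1 so
  bone is always bright; multi-frame and color inputs are rejected.
* No pass/fail cutoffs are applied to the three criteria — none are
  clinically standardized — so reports carry raw values plus flags.
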