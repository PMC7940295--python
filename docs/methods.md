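# Methods

## Problem and data model

The package segments renal cysts in coronal T2-weighted MR volumes of ADPKD
patients. The unit of input is a `VoxelVolume` (a 3-D intensity grid with
per-axis spacing in mm, nominally 1.5 mm in-plane and 3.0 mm between slices)
paired with binary masks: a kidney mask (given; kidney segmentation is a
separate, solved task) and one or more cyst masks (manual tracings, ground
truth, or the automated prediction). All grids use one axis convention,
(row, column, slice), with coronal slices along the third axis; orientation
matrices in NIfTI headers are preserved on write but all processing happens
in voxel index space. Masks are stored as uint8 {0,1}; any nonzero value
binarizes to 1 on read.

TKV and TCV are voxel count × voxel volume; the cystic index is TCV/TKV.
Exclusion of the renal pelvis from the kidney mask is a labeling convention
of the tracing protocol, not something the code computes.

## Preprocessing

Each scan is normalized as a whole volume: intensities are rescaled so the
95th percentile over all voxels equals a common level (default 1000
arbitrary units), then standardized to zero mean and unit standard
deviation. Because standardization follows, the common level is immaterial —
normalization is invariant to positive rescaling of the input, and applying
it twice is a no-op up to float error; both properties are asserted by
tests. Percentile and moments are computed over all voxels (not
body-masked, not per-slice): normalization is per-scan, so volume-level
statistics are the natural reading. Normalization precedes slice resampling;
the order only matters through interpolation error.

Slices are resampled to the processing matrix (256×256 at full scale, 64×64
in tests) with cubic interpolation for images — not clipped to the input
range, since standardization follows — and nearest neighbor for masks, which
preserves binarity. Training uses only slices that intersect the kidney
mask: all-background slices carry no gradient signal for a target confined
to the kidneys. Inference keeps every slice so volumes reassemble
completely.

## Network

A 2-D two-channel encoder–decoder. Encoder blocks apply convolution → ReLU →
dropout (rate 0.1) → batch normalization → convolution → ReLU, then 2×2 max
pooling; kernel sizes are 7×7, 5×5, 3×3 down the three encoder levels (large
kernels at high resolution), reversed up the decoder. Channel widths double
per level from `base_filters` (32 at full scale, 8 at test scale) to a 3×3
bottleneck block. Decoder stages upsample 2× (nearest), convolve at that
level's kernel size, and add the 1×1-projected encoder feature map
(additive, ResNet-like skips; the projection guarantees channel agreement
and adds a learnable mixing), followed by a mirrored block. The head is a
1×1 convolution with sigmoid. Where the block recipe leaves details open we
chose: ReLU activations between convolutions; batch normalization once per
block (between the convolutions, as ordered in the recipe); nearest-neighbor
upsampling; "same" padding throughout (required for additive skips at equal
resolution).

The network, batch norm, dropout, pooling, upsampling and Adam are
implemented directly on numpy arrays. Convolutions run as im2col GEMMs in
float32 with analytic backward passes (the input gradient is the full
correlation with the 180°-rotated kernel, also one GEMM). Correctness of
backpropagation is verified by directional-derivative finite-difference
tests; everything is seeded, so training is bit-reproducible on CPU.

## Training

Loss is soft Dice, `1 − (2Σpt + s)/(Σp + Σt + s)` summed over all pixels of
the batch, smoothing `s = 1.0` (the smoothing constant is a free choice; it
defines the empty–empty case as zero loss). Optimizer is Adam with initial
learning rate 1e-3 and additive decay 1e-5, applied as
`lr_t = lr0 / (1 + decay·t)` per update step (the convention of the
framework family this architecture descends from), batch size 8. Slice
samples are shuffled across cases each epoch with the run seed. After every
epoch the model is scored on the validation cases as reassembled volumes —
hard Dice at threshold 0.5, averaged per case — and the weights of the best
epoch are checkpointed; "validation measure" is read as Dice since that is
what the learning curves track. Full-scale training is 200 epochs; the test
and acceptance configurations train 15 epochs at 64×64 with base_filters 8,
where validation Dice plateaus on phantoms.

The cohort split is stratified by fat saturation first and TKV within each
stratum: per-stratum group quotas come from largest-remainder apportionment
(test set and each fold's validation set), and within a stratum the
TKV-sorted cases are assigned by systematic striding with seeded jitter, so
every partition samples the whole severity range. A Mann–Whitney rank test
between any partition and the remainder is the balance check. Each non-test
case appears in exactly one fold's validation set; the fold's training set
is the remaining non-test cases.

## Ensemble

The three fold models each predict binary slice masks at member threshold
0.5 (not stated by the tracing protocol; 0.5 is the natural cut for a
sigmoid output). A voxel is positive iff ≥2 of 3 members vote for it —
votes on binarized outputs, not averaged probabilities. Multiplying the
fused mask by the kidney mask is available as opt-in post-processing
(`apply_kidney_mask`) and is off by default: the two-channel input already
confines predictions to the kidneys, and residual outside-kidney false
positives should remain visible to evaluation. Predictions made on the
processing matrix are mapped back to the native grid by nearest-neighbor
resampling.

## Evaluation

Overlap metrics from voxel counts: Dice 2TP/(2TP+FP+FN), Jaccard
TP/(TP+FP+FN), sensitivity TP/(TP+FN), precision TP/(TP+FP). Undefined
denominators yield NaN — never zero — and are excluded from cohort means
with a logged count (mild cases can have near-empty masks). Hausdorff is the
exact symmetric max-min Euclidean distance over all mask voxels in 3-D
voxel-index units; anisotropic spacing is deliberately ignored because the
statistic is reported in voxels. No percentile-Hausdorff variant is
provided. TCV percent difference is signed and reference-denominated,
100·(test − ref)/ref, with the manual tracing (or ground truth) as
reference. Cohort summaries are mean ± sample standard deviation (n−1).
Bland–Altman uses differences a − b with limits bias ± 1.96·sd (sample sd);
it is computed on the cystic-index fraction and rendered as percent. Linear
fits are ordinary least squares with a pointwise 95% confidence band of the
mean response. Overlay rendering colors a-only voxels violet, b-only green,
and agreement dark gray over a darkened background slice.

## Phantom generator

The generator emulates the study conditions so the pipeline can be exercised
without clinical data: two ellipsoidal kidneys with mild random axis jitter
and per-case size variation (so TKV has a real distribution); spherical
cysts (in mm, anisotropic in voxels) centered at random kidney voxels and
clipped to the kidney, guaranteeing containment; greedy placement with
radius bisection lands the achieved cystic index within ±10% relative of the
target (a couple of voxels of slack covers integer quantization on tiny
targets), or raises a feasibility error naming the constraint. Severity
targets span 0.5%–90% across a cohort; exactly round(0.7·n) of n cases are
fat-saturated, matching the reported cohort composition.

Intensities are arbitrary units whose ordering is the contract: bright cysts
(800) > parenchyma (300) > complex cysts (100), background 50 for
fat-saturated scans and 400 with extra variance otherwise. Complex (T2-dark)
cysts are kept a volume minority: a cyst is flagged dark only while the
complex share of total cyst volume stays below `complex_cyst_fraction`
(default 10%). A few bright extra-renal fluid bodies (CSF, gallbladder,
vessels — always present in real T2 scans) are rendered outside the kidneys;
they anchor the upper intensity percentiles of every scan regardless of cyst
burden, which is what makes volume-wide percentile normalization meaningful,
and they exercise the two-channel constraint since bright voxels outside the
kidney channel must not be segmented. Noise is additive Gaussian (sigma 30),
a deliberate simplification of MR (Rician) noise adequate for pipeline
testing.

A second manual reader is simulated by re-thresholding the truth mask's
signed distance transform against a smooth random field; expected Dice
against the truth decreases monotonically with the perturbation level, and
level 0 returns the truth exactly.

What passing on phantoms does **not** show: robustness to MR bias fields,
partial-volume boundaries, renal pelvis and vessel ambiguity, inter-scanner
intensity variation, or real reader behavior. The phantoms have crisp
piecewise-constant tissue classes, so phantom agreement numbers sit well
above what clinical data would yield.

## Problem sizes and numerical choices

Tests and the acceptance script run the full pipeline at a reduced scale
chosen as the smallest configuration that still exercises every component:
64×64×16 phantom grids, 64×64 processing matrix, base_filters 8, 26-case
cohorts (20 train/validation, 6 hold-out), 3 folds, 15 epochs; the
determinism check runs a complete pipeline twice at 32×32. Dice-loss
smoothing 1.0; batch-norm epsilon 1e-5, momentum 0.1; Adam beta (0.9,
0.999), epsilon 1e-7; He weight initialization. Max-pool gradient routes to
the first maximum on ties. One master seed fans out to per-stage seeds via
`numpy.random.SeedSequence`; all stage seeds are logged in run manifests.

## Known limitations

Pure-numpy training is CPU-bound and meant for the test scale; full-scale
(256×256, 200 epochs, base_filters 32) training is supported by the same
code but would be slow without an accelerator. The generator makes no
attempt at MR physics (coil profiles, Rician noise, partial volume).
Individual-cyst instance separation and counting, phenotype classification,
liver cysts and DICOM ingestion are out of scope.
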