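# Methods

## The encoding

A lesion annotated on axial slice *i* of a CT volume is represented as an
H×W×3 8-bit image whose channels are the crops of slices *i−1*, *i*, *i+1*
(red, green, blue), all taken at slice *i*'s annotation box, converted from
stored values to Hounsfield units (`HU = slope·stored + intercept`),
windowed, and resized bilinearly to a square model input. Two choices here
are deliberate and load-bearing:

- **Neighbors are cropped at the current slice's box.** If each slice were
  cropped at its own per-slice box, the lesion would be re-centered in every
  channel and the in-plane displacement between slices — the very signal a
  2.5D encoding exists to expose — would be erased. Keeping the box fixed
  preserves that displacement inside the crop.
- **Volume edges clamp.** At the first/last slice the missing neighbor is
  replaced by the boundary slice itself rather than zeros, so channel
  intensity statistics stay comparable across the dataset.

Windowing maps `[level − width/2, level + width/2]` linearly onto [0, 255]
with clamping and half-away-from-zero rounding. The default window is the
standard abdominal soft-tissue setting, level 40 HU / width 400 HU,
configurable per run. The single-slice baseline ("original" arm) replicates
the green crop across all three channels so both arms share one classifier
input shape.

## Evaluation protocol

Folds are assigned to *patients*, never to images: within each class,
patients sorted by descending image count (count ties shuffled by the seed)
are greedily placed into the currently lightest fold. Each fold then serves
once as the test set. Per-fold test confusion matrices are summed
("pooled") into one whole-dataset matrix — every image counted exactly once
— from which accuracy, precision and recall are computed with Wilson 95%
intervals; the positive class is the tubular/appendicitis-like one
throughout, and predictions threshold the positive-class score at 0.5.

AUC is computed in its Mann–Whitney form (probability that a random
positive outscores a random negative, ties at half), which equals the
trapezoidal area under the empirical ROC curve; the test suite asserts that
equality to 1e-12 against `sklearn.metrics.roc_curve` as an independent
route. Arms are compared with DeLong's test for correlated AUCs (structural
components estimator for the variances and covariance, normal reference for
the AUC difference), validated against a 200,000-replicate stratified
bootstrap of the paired AUC difference.

Minority-class balancing synthesizes augmented copies of minority training
records (cycling, fresh parameter draws) until exact parity with the
majority class. Balancing and augmentation happen **after** fold splitting,
from training-fold records only, and synthetic records are flagged and
excluded from every test set — the leakage-safe ordering.

A further consistency tool, `reconstruct_confusion_from_printed`, inverts a
published metrics row: given the two class totals and precision/recall
printed at two decimals, it enumerates every integer (TP, FP) pair
consistent with them. For all six rows of the motivating study's results
table (totals 1,959/823) the solution is unique and reproduces the printed
accuracy exactly, which both validates the rows' internal consistency and
pins down the rounding convention (half away from zero).

## Reference classifier

The classifier behind the pluggable contract is a from-scratch NumPy CNN:
three blocks of two batch-normalized 3×3 convolutions with leaky-ReLU
(slope 0.1) and a 2×2 max-pool, then global average pooling and a single
logit; binary cross-entropy under Adam. Defaults: 32×32×3 input, widths
(12, 24, 48), ≈80k parameters. Inputs are scaled to [0, 1]; ImageNet-style
per-channel normalization applies only when a pretrained backbone is
plugged in instead. Two design notes from development:

- the double conv per block gives the last stage a receptive field (~31 px)
  that spans a whole lesion triplet at 32 px input, which a single-conv
  stack does not;
- batch normalization is what makes from-scratch optimization insensitive
  to the weight-initialization seed; without it a single-logit net of this
  size intermittently sits at the trivial constant solution for tens of
  epochs.

The published transfer-learning schedule is kept as the `TrainConfig`
default (200 epochs max, batch 64, Adam at 1e-4 dropping to 1e-5 once the
epoch count exceeds 30 — "greater than 30" read strictly, so epoch 30 still
trains at the base rate — patience-10 early stopping on validation loss,
best-validation weights restored). The desk-scale experiment uses its own
schedule suited to a from-scratch batch-normalized net: 50 epochs max,
batch 64, 3e-3 dropping to 3e-4 after epoch 40, patience 12. Early stopping
fires when the minimum of the last `patience` validation losses fails to
beat the minimum of all earlier ones; histories shorter than the patience
never trigger. The validation set is a patient-grouped 20% split of the
training fold. Grad-CAM follows the standard formulation: channel weights
are the global-average-pooled gradients of the class score w.r.t. the last
conv stage's feature maps; the map is the ReLU of the weighted sum,
bilinearly upsampled and max-normalized.

## The phantom

The synthetic cohort exists to make one claim testable without clinical
data: *that the fused encoding extracts cross-slice information a
single-slice classifier provably cannot have.* Each 24×96×96 volume
(3 mm slices, 0.7 mm pixels) holds one soft-edged elliptical lesion
(+60 HU over a 30 HU background, Gaussian noise σ = 8 HU, semi-axes
4–7 px) on 5 consecutive slices, annotated per slice with a 4 px box
margin, stored as DICOM with slope 1 / intercept −1024 to exercise the
real rescale path.

The middle lesion slice is drawn from a sampler shared by both classes —
position, semi-axes and orientation have identical distributions, and the
placement margin is wide enough that no class-dependent rejection occurs —
so the Bayes-optimal single-slice accuracy on lesion-centered crops is 50%
by construction. Class identity is carried only by cross-slice placement:
the *tubular* class moves the lesion center 3 px per slice along one
consistent random direction (a tube crossing the imaging plane obliquely);
the *focal* class draws an independent direction each slice (incoherent
inflammation). In the fused image the tubular class therefore shows R and B
lesions displaced symmetrically about G along a line, while the focal class
shows them at random relative offsets. A centroid-geometry probe puts the
achievable separation at ≈0.98 AUC on interior lesion slices; the two edge
slices of each lesion run (whose missing-side neighbor contains no lesion)
are uninformative in either class, capping whole-cohort accuracy near 78%.

What the phantom does **not** emulate: anatomy, organ context, partial
volume effects, scanner noise spectra, annotation jitter, or class
imbalance (the clinical cohort has 1,959 vs 823 images; the phantom is
balanced, so the balancing path is exercised by dedicated tests instead).
Passing the phantom experiment shows the pipeline extracts cross-slice
signal under controlled conditions; it does not certify clinical
performance.

## Experiment defaults and problem sizes

The standard experiment (`FusionExperiment` defaults, also what
`scripts/acceptance.py` runs) is 100 phantom patients per class, 2-fold
patient-grouped CV, both arms, 32 px inputs, widths (12, 24, 48), and two
stochastically augmented copies of every training record (rotation ±180° —
axial in-plane orientation is arbitrary, so full-circle rotation is
label-preserving — shifts ±8%, zoom 0.9–1.1). These sizes complete in
about ten minutes on a single core while leaving the superposition arm a
comfortable margin over the single-slice arm (observed: ≈68% vs ≈47%
pooled accuracy, AUC ≈0.79 vs ≈0.48, DeLong p ≪ 0.001 at seed 1). Unit and
property tests run at much smaller scales (≤6 patients/class, 16 px, ≤3
epochs) where only contracts, not learning quality, are asserted.

## Numerical conventions and degenerate inputs

- Rounding is half away from zero wherever a float meets an integer grid
  (8-bit quantization, table reconstruction).
- Slices sort ascending by scan-axis position, falling back to instance
  number; duplicate positions, mixed series and inconsistent shapes are
  rejected.
- Boxes are 0-based, top-left origin, half-open — the ImageJ convention —
  and must lie inside the slice.
- A metric with a zero denominator is reported as undefined, never
  fabricated. A DeLong comparison with zero variance is p = 1 when the AUCs
  agree and flagged degenerate otherwise.
- All stochastic steps (phantom sampling, fold tie-breaks, shuffling,
  augmentation draws, weight init) consume explicit seeds; identical
  configurations reproduce bit-identical reports in single-threaded CPU
  runs.

## Known limitations

- The reference CNN is a deliberately small stand-in for the pretrained
  EfficientNet backbones the full-scale protocol targets; parameter counts
  and epochs-to-stop of those backbones are out of scope.
- Only rectangular single-frame-DICOM annotations are supported; no
  multi-frame DICOM, non-rectangular ROIs, or >3-slice stacks.
- Confidence intervals use Wilson's method; published tables built with a
  different CI method will match in point estimates but not bounds.
- The phantom's accuracy ceiling (edge slices, above) means phantom
  accuracies should be compared between arms, not read as absolute
  performance numbers.
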