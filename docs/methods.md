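# Methods

## Problem and model

The task is binary classification of posteroanterior chest radiographs —
cardiomegaly vs normal — under domain shift: the model is optimized on a
labeled source dataset X (size n) and must generalize to an unlabeled
target dataset Z (size m) from a different acquisition protocol, sharing
the label space.  Three training regimes are implemented.

**Source-only.** Encoder E and classifier C_S minimize the weighted
categorical cross-entropy L_C alone.  Evaluated either in-domain (T→T) or
across domains (S→T), it provides the baselines.

**DRDA (deep reconstruction domain adaptation).** A target decoder D_T
reconstructs target images from the shared encoder's features.  Per step,
C_S is updated by L_C, D_T by the reconstruction loss L_R, and E by
λ_c L_C + λ_r L_R with λ_c = λ_r = 0.5.  The encoder must therefore retain
enough target structure to reconstruct it, which counteracts the collapse
of source-fitted features on shifted inputs.

**RDRDA (regularized DRDA).** Adds a domain discriminator D trained with
binary cross-entropy L_D (source = 1, target = 0; a single 1/bs factor
normalizes the sum over both bs-sized domain halves, so an uninformed
discriminator sits at 2·ln 2).  The encoder additionally minimizes the
inverted-label adversarial loss L_adv = −(1/bs) Σ log D(E(z)), with
weights (λ_c, λ_r, λ_d) = (0.45, 0.45, 0.1).  Within a step the
discriminator is updated first, on the current encoder's features, then the
encoder/classifier/decoder group — the usual adversarial ordering.  Setting
λ_d = 0 reproduces DRDA's L_C/L_R trajectories bitwise (a tested
invariant); this works because every component draws its initialization and
dropout randomness from an independent seed-derived stream, so adding the
discriminator perturbs nothing else.

L_R is the per-sample squared L2 norm summed over all pixels and channels,
averaged over the batch.  Its magnitude therefore grows with image area,
which interacts with the fixed λ_r; a per-pixel-normalized variant is
available (`reconstruction_loss(per_pixel=True)`) but the summed form is
the default.  Class imbalance is handled by per-sample weights
w = n⁻/n for positives and n⁺/n for negatives, computed on the full source
training set, so both classes contribute the same total weight n⁺n⁻/n.

## Networks

The encoder is a convolutional backbone, a single trainable 3×3 convolution
with 1024 filters (stride 1), batch normalization, ReLU, and global average
pooling, yielding a 1024-long feature vector.  Pretrained ImageNet
backbones (ResNet152, DenseNet121/201, Xception, InceptionV3) are
recognized configuration tags whose weights are not bundled; the runnable
default is `scratch_small`, three Conv-ReLU-MaxPool blocks (8/16/32
channels) trained from scratch.  The whole desk-scale bundle stays under
2 M parameters.

The decoder maps the feature vector through a dense 8×8×128 seed and a
stack of transposed convolutions (ReLU everywhere, final layer linear).
The reference plan upsamples 8 → 17 → 35 → 37 → 74 → 149 → 299 → 299 → 299
('valid' layers follow out = (in−1)·s + k, 'same' layers out = in·s) to a
299×299×3 image.  For smaller input sides (8·2^k) a reduced plan is derived
automatically from stride-2 'same' doublings; the shape arithmetic is
validated at construction, never at first forward.  Classifier and
discriminator are Dropout → Dense(512) → ReLU → Dropout → Dense heads with
softmax-2 and sigmoid-1 outputs respectively; the dropout rate (0.5
default) is a configuration knob.

Because no deep-learning framework is part of the dependency set, the
layers live in `cxrda.nn`: a small numpy library with manual
backpropagation (strided-slice convolutions, transposed convolutions
implemented as the exact adjoint map, batch norm, pooling, dropout) and one
Adam optimizer per component so the update partition stays explicit.  Every
backward pass is tested against central finite differences, and the
transposed convolution against the adjoint identity
⟨conv(x), y⟩ = ⟨x, convᵀ(y)⟩.

## Optimization protocol

Adam with a fixed learning rate; reference settings 1e-6 for 200 epochs at
batch size 16 and 299-px inputs.  The desk profile used by tests and
examples is 1e-3, 30 epochs, batch 16 at 64-px inputs with the scratch
backbone and a 64-filter head — sized so a complete three-regime, three-seed
comparison runs in minutes on one CPU.  Cross-domain batches are balanced:
each batch holds bs labeled source and bs unlabeled target samples.  The
source set is traversed without replacement per epoch (seeded shuffle), the
final short batch filled by wrap-around so every source sample is used at
least once per epoch and both halves stay equal; the target set is cycled
from an independently shuffled list, reshuffled at each wrap.  During the
discriminator phase the encoder's batch-norm statistics are frozen so the
running averages accumulate each batch once (in the encoder phase, where
both domains pass through).  No early stopping or validation-based model
selection: final models are reported, validation splits exist for logging.

Target labels are structurally invisible to training: `fit` accepts the
target split as a bare image array.  A label-poisoning probe at the
experiment-grid level verifies that only the T→T regime reacts to target
training labels.

## Preprocessing pipeline

Grayscale (BT.709 luminance for RGB inputs) → CLAHE → 3×3 Gaussian
smoothing (σ = 0.8, reflected borders) → zoom-crop removing
floor(0.1·side) pixels per border (noisy edge content, text markers and
collimator frames fall in this band) → Otsu binarization inverted so the
dark lung fields become foreground → morphological opening with a 3×3
square element → connected components above an area floor (2% of image
area), reduced to the two largest (the two lungs) → tight bounding boxes →
their min/max union as the chest-cavity box → crop → bilinear resize and
channel triplication.  Boxes are 0-based and half-open.  Choices the
procedure description leaves open were fixed as follows: Otsu because it is
parameter-free and suits bimodal radiograph histograms; the zoom step is a
deterministic border crop (not a resampling zoom), matching its stated
purpose of discarding edge noise; opening order erosion→dilation, one
iteration; the CLAHE clip limit uses scikit-image's normalized convention
(default 0.01) with an 8×8 tile grid.  If no component passes the area
floor the pipeline falls back to the uncropped zoomed image with a logged
warning, so batch runs never abort.  The module draws no random numbers and
is bit-deterministic end to end.

## Synthetic phantoms and the standard study

Real multi-hospital radiograph collections cannot ship with a test suite,
so the generator emulates the geometry that defines the label: a bright
thorax ellipse, two dark lung ellipses, and a bright cardiac ellipse
straddling the midline whose width is exactly CTR × thoracic width.  The
label is cardiomegaly iff CTR ≥ 0.55 (the clinical labeling rule for the
small-hospital setting; 0.50 is available as the alternative convention).
Per-class CTR ranges default to U(0.38, 0.53) for normal and U(0.57, 0.78)
for cardiomegaly — realistic CTR spans that do not touch the threshold, so
labels are unambiguous under pixel quantization.  The surround is rendered
at 0.65 intensity (thorax 0.75, lungs 0.20, heart 0.95) so the lung fields
are the histogram's single dark mode, as on a windowed clinical image.
Seeded jitter (σ = 1 px) moves structure centers.  Structure masks are
returned alongside the image, giving the preprocessing tests pixel ground
truth; a row-scan measurement of heart and thorax widths on the masks
recovers CTR within quantization (±2 px of the thoracic width), and
nominal vs measured labels agree in ≥99% of specs outside that band.

Domain shift is appearance-only (geometry preserved): centered contrast
gain, intensity bias, Gaussian blur, additive Gaussian noise, and bright
border artifacts (frame plus text-like marks within the outer 8% band).
The identity shift is bit-identity.  The `strong()` preset — gain 0.6,
bias −0.15, blur σ 1.5, noise σ 0.06, border artifacts on — emulates a
different detector response: every tissue intensity moves, global contrast
compresses to 60%, texture statistics change, but heart/thorax/lung
remain distinguishable, so the target task stays solvable in principle.

The standard study mirrors the asymmetry of the motivating setting: a
"large archive" source with ~20% positives (train 16+64, test 8+32, clean
acquisition) and a "small clinic" target with ~60% positives (train 29+19
unlabeled, test exactly 20 positives + 13 negatives) under the strong
shift, rendered at 96 px and preprocessed to 64×64×3.  Replicates use
seeds 0–2.  On this study the source-only S→T baseline typically collapses
toward all-positive predictions (G-Mean near 0 with high sensitivity and
near-zero specificity) while both adaptation schemes recover large
fractions of target G-Mean; the acceptance test asserts the mean gain of
each scheme over the baseline is at least 10 percentage points across the
three seeds.  Individual replicates are noisy at this scale — a run can
collapse or saturate — which is why the criterion is on means.

What passing these tests does and does not show: the phantoms exercise the
full pipeline (imbalance, shift, preprocessing, unlabeled adaptation) with
known ground truth, but they are geometric stylizations — no ribs, no
mediastinal texture, no pathology other than heart width, and a
parameterized shift that is a stand-in for unknown inter-hospital
differences.  Absolute scores on phantoms say nothing about absolute
clinical performance; the tested claims are directional and structural.

## Numerical choices

Logs are clamped at ε = 1e-7 in all losses.  Probabilities/one-hot
conventions: (1,0) = normal, (0,1) = cardiomegaly; prediction threshold is
argmax with ties going to normal.  Metrics with zero denominators return 0
and set a degenerate flag.  AUC is the rank-based Mann–Whitney statistic
with half-credit for ties, computed from the positive-class probability.
Stratified splits use largest-remainder rounding per class with seeded
shuffles (per-split class proportions within one sample of the global).
Arrays are float32 in training, float64 in gradient tests.

## Known limitations

* Pretrained backbones are tags only; all reported behavior uses the
  scratch backbone, so conclusions about backbone choice cannot be drawn.
* The summed (un-normalized) reconstruction loss makes λ_r's effective
  strength depend on image area; at 64 px the reconstruction gradient
  dominates the encoder's update, which is tolerable under Adam's
  per-parameter scaling but contributes to replicate variance.
* Desk-scale runs (small n, 30 epochs) have high run-to-run variance;
  conclusions should be read from means over seeds, as the tests do.
* The CPU numpy implementation is intended for correctness and small
  studies, not throughput.
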