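# Methods

## The problem

Unilateral sensorineural hearing loss is accompanied by subtle structural
brain changes that are hard to see by eye but can be picked up by texture
statistics of a structural MR slice. `wedag` implements a three-class
computer-aided-diagnosis pipeline — healthy control (HC) vs. left-sided
(LHL) vs. right-sided (RHL) hearing loss — that reduces a preprocessed 2D
brain slice to a short global feature vector and classifies it with a
multiclass assembly of linear support vector machines. The package operates
on already-preprocessed slices (skull-stripped, spatially normalised,
smoothed); acquisition and preprocessing are outside its scope, as is slice
selection, which is a clinical judgement supplied by the user.

## Wavelet-entropy features

An n-level separable 2D discrete wavelet transform with the B-spline
biorthogonal `bior5.5` pair splits the image into 3n+1 subbands
(LLn, then HL/LH/HH at each level). On each subband the Shannon entropy of
the normalised coefficient-energy distribution is computed:

    p_i = c_i^2 / sum_j c_j^2,    H = - sum_i p_i log2 p_i   [bits]

giving a (3n+1)-element feature vector. H measures how evenly a subband's
energy is spread: 0 when a single coefficient carries everything, log2(M)
when all M coefficients are equally energetic. The statistic is invariant
to global intensity rescaling and to any permutation of coefficients within
a subband — it is a *global* feature carrying no location information.

Numerical conventions, fixed and documented because subband shapes and
entropies depend on them:

* boundary handling: half-sample symmetric extension (border pixel
  repeated), the common default for biorthogonal banks; one analysis stage
  maps axis length N to floor((N + L - 1)/2) with L = 12 for bior5.5;
* filter normalisation: sqrt(2) DC gain per analysis low-pass stage (a
  constant image c has LL1 = 2c);
* subband order: coarse to fine, [LLn, HLn, LHn, HHn, ..., HL1, LH1, HH1];
  labels use row-filter-first convention (HL = high-pass along rows);
* an all-zero subband has H = 0 by convention, and coefficients smaller
  than 1e-12 times the decomposition's largest coefficient are treated as
  zero first — high-pass subbands of a flat region are zero only up to
  float round-off, and entropy of round-off noise is meaningless;
* a 256-bin histogram entropy variant exists behind
  `variant="histogram"`; it is not scale-invariant and not the default.

The inverse transform is implemented only to verify the filter bank:
round-trip error is below 1e-8 on images from 16x16 to 256x256.

## Classifier

Each pairwise problem is the soft-margin linear SVM

    min 1/2 ||w||^2 + eps * sum_n xi_n
    s.t. y_n (w.x_n - b) >= 1 - xi_n,  xi_n >= 0

solved to optimality (the test suite holds the achieved objective within
1e-6 of an independently solved dual QP). The kernel is linear because the
model is stated and used in its primal linear form. The penalty default is
eps = 0.05, the protocol value; note that at very small training sizes this
penalty can make the regulariser dominate and collapse the classifier
toward a majority vote — a property of the model, visible in the tests.

Multiclass decisions use a decision DAG (DDAG) over the C(C-1)/2 pairwise
models. Classes are kept in a fixed order (HC, LHL, RHL by default,
configurable); the root node compares the first against the last class, a
non-negative score L_ij eliminates class j (sgn(0) = +1 by convention,
consistent with the binary tie-break toward the positive class), a negative
score eliminates class i, and after exactly C-1 evaluations one class
remains. On well-separated data the DDAG decision coincides with exhaustive
one-vs-one majority voting; near ambiguous regions it can depend on the
class order, which is why the order is part of the configuration and of the
serialised model.

Features are z-scored per column before training and scoring (default on,
switchable): entropies of different subbands live on different scales, and
with eps fixed at 0.05 the solution is not scale-free. The statistics are
always computed on the training samples given to `train_dag` — in
cross-validation, only on the training folds — and stored with the model.

## Evaluation protocol

`run_cv` implements runs x k-fold cross-validation (default 10 x 10): per
run, a stratified shuffled split seeded as master seed + run index; per
fold, standardise-train-predict; validation predictions pooled over all
runs into one confusion matrix (490 predictions for 49 samples). Folds are
stratified so every class appears in every training part (with 49 samples
and k = 10: nine folds of 5 and one of 4); when k exceeds the smallest
class count (e.g. leave-one-out) the split falls back to plain shuffled
k-fold, where stratification is undefined. Per-class metrics are the
one-vs-rest reductions (sensitivity, specificity, precision, accuracy);
ratios with zero denominators are reported as undefined (`None`/NaN), never
silently 0 or 100. Reported percentages are rounded to two decimals;
internal arithmetic is not.

## Synthetic phantoms

No public cohort exists for this task, so the package ships a generator of
labelled 2D phantoms emulating the *statistical* properties the pipeline
consumes: an elliptical brain (axes 0.8 x image extent) over zero
background, a smooth radial base intensity in [0, 1], two independent
band-limited Gaussian texture fields (mid band 0.05-0.10 and high band
0.12-0.22 cycles/px), pixel noise, and a final Gaussian blur.

Class effects, with defaults chosen as a strong-effect regime:

* LHL: the mid-band texture is spatially concentrated into a left
  mid-temporal Gaussian envelope (sigma 25 px at 256x256) with strength
  `effect_size` (default 0.8), and a hypointense lesion blob (sigma 12 px,
  depth `lesion_contrast` = 0.3) is subtracted there;
* RHL: the same with the high band and the mirrored right focus;
* HC: uniform texture, no lesion.

Because per-subband energy entropy is scale- and location-invariant,
mirror-image lesions with identical texture statistics are nearly
indistinguishable to the feature; the generator therefore encodes the
LHL/RHL contrast in *which frequency band* is spatially concentrated
(concentration lowers the entropy of the matching subbands). This is a
faithful reflection of what the method can and cannot see, not a
convenience: passing tests demonstrate recovery of band-specific texture
reorganisation, and say nothing about purely positional contrasts, bias
fields, Rician noise, registration error or anatomy, none of which the
phantom models.

Under these defaults the full pipeline (49 phantoms, level 3, 10 x 10-fold
CV) reaches 100% accuracy, and the null configuration (`effect_size = 0`,
`lesion_contrast = 0`) stays within the empirical permutation-null band at
roughly 35% — the three-class chance regime.

## Problem sizes and determinism

Every stochastic step is driven by an explicit integer seed: the phantom
cohort by its config seed, fold assignment by master seed + run index, and
the SVM solver is deterministic. Identical configuration therefore yields
byte-identical reports. The test suite runs its heaviest check — the full
pipeline plus a 20-permutation null band — on the default 49-image,
256x256 cohort in well under a minute per CV; smaller 64x64 cohorts are
used where only mechanics are being exercised.

## Known limitations

* Wavelet entropy discards all spatial localisation; laterality is only
  detectable through correlated spectral differences.
* The DDAG decision can depend on class order for ambiguous inputs.
* The eps = 0.05 default follows the implemented protocol; it is not tuned
  per dataset, and behaves degenerately for very small training sets (see
  above).
* Accuracies measured on phantoms characterise the pipeline's mechanics
  under the generator's assumptions; they are not estimates of clinical
  performance.
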