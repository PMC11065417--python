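# Methods

## Problem setting

A classifier trained to distinguish C classes (the motivating application is
insect-pest identification with C = 142) will, in deployment, be shown inputs
that belong to none of its classes: other organisms, vehicles, faces, blurred
frames. An *extrusive* out-of-distribution (OOD) detector wraps the trained
classifier without retraining it, assigns every input a confidence score, and
abstains below a threshold. This package implements the three standard
extrusive scores, the evaluation protocol used to compare them, and a
synthetic benchmark for studying how their performance depends on classifier
accuracy, the severity of distribution shift, and imbalance in the data used
to fit the detector.

## The three confidence scores

All scores are oriented so that higher means more in-distribution (ID).
Write f(x) for the classifier's penultimate ("pre-logit") feature vector and
l(x) for its logit vector of length C.

**Maximum softmax probability (MSP).** `max_i softmax(l(x))_i`. Bounded in
(1/C, 1]; it attains its floor exactly when all logits are equal. Computed
with max-subtraction so logits of magnitude ≫ 700 do not overflow.

**Energy (EBM).** The Helmholtz free energy of the logit vector,

    E(x) = −T · log Σ_i exp(l_i(x) / T),

with temperature T = 1 by default; the confidence is −E(x), computed via an
overflow-safe log-sum-exp. E is sandwiched between −max_i l_i − T·ln C and
−max_i l_i, and as T → 0 the confidence ranking converges to the max-logit
ranking.

**Class-conditional Mahalanobis (MAH).** Fit one Gaussian per class on
penultimate features of held-out labeled ID data ("ID2"): per-class means
μ̂_c and a single covariance Σ̂ *tied* across classes (pooled within-class
scatter divided by the total sample count, as in Gaussian discriminant
analysis). The score is the negated squared Mahalanobis distance to the
nearest class mean:

    M(x) = max_c −(f(x) − μ̂_c)ᵀ Σ̂⁻¹ (f(x) − μ̂_c) ≤ 0,

zero exactly at a class mean. A per-class-covariance variant is available
(`tied=False`); tied is the default because a single Σ̂ is what the
discriminant-analysis derivation of the score uses, and it is far better
conditioned when per-class counts are small. Before inversion the covariance
diagonal is ridged by `reg_eps`, defaulting to 1e-6 · trace(Σ̂)/d — scale
aware, and it keeps the degenerate zero-covariance case usable when set
explicitly. Every class must contribute ≥ 2 samples; singleton classes are
rejected by name rather than silently producing a zero-variance component.

MAH is the only score with fitting state. MSP and EBM are pure functions of
the logits, which is the entire mechanism behind their exact insensitivity
to the composition of the detector-fitting set (see the imbalance
experiment).

## Data protocol

Labeled ID data are split 70/15/15 into ID1 (classifier training), ID2
(detector fitting, used only by MAH) and ID3 (testing). The split is
stratified per class by default — the protocol itself does not require it,
but unstratified splitting can leave a class empty in ID2, which would make
the Gaussian fit ill-posed — with largest-remainder rounding per class
(remainder ties to the lower part index) so the partition is deterministic
and exact. When ID and OOD test sets differ in size they are equalized by
seeded subsampling of the larger set, so that accuracy numbers are
comparable across conditions.

## Evaluation conventions

ID is the positive class. A sample is predicted ID iff its score is ≥ the
threshold; ties predict ID. The ROC sweep runs over all observed score
values plus ±∞, so (0,0) and (1,1) are explicit endpoints. AUROC is the
trapezoidal area under this step curve, which equals the Mann–Whitney
statistic P(s_ID > s_OOD) + ½ P(s_ID = s_OOD); the tests verify this
identity exactly against pairwise enumeration. FPR95 is read off the sweep
without interpolation: the FPR at the largest threshold whose TPR reaches
0.95. "Best threshold" is formalized as the maximizer of Youden's
J = TPR − FPR (the informal "minimum false positive and maximum true
positive" does not define a unique optimum); ties break toward higher TPR,
then higher threshold, which in the separable case returns the lowest ID
score at (TPR, FPR) = (1, 0). Box-plot summaries use linear interpolation
between order statistics for the quartiles.

## The synthetic benchmark

The generator emulates the statistical structure the Mahalanobis score
assumes and that the other scores exploit indirectly:

* **ID features**: class means drawn i.i.d. N(0, `mean_scale`² I) in d
  dimensions (the simplest geometry satisfying the class-conditional
  Gaussian assumption; no sphere constraint), samples drawn
  N(μ_c, Σ_within). Defaults: C = 12 classes, d = 8, `mean_scale` = 3
  against unit within-class variance — class separations comparable to a
  decent penultimate layer, far smaller than the 142-class study system but
  with the same structure.
* **OOD features**: a mixture with uniformly chosen component per class,
  each component mean displaced a distance `delta` from its ID class mean
  *toward (and past) the feature-space origin*. The inward direction is
  deliberate: trained networks embed out-of-domain images at low penultimate
  activations, i.e. in the classifier's low-response region. Displacing in a
  random direction instead makes a linear logit map *more* confident on far
  OOD (softmax saturates along almost every ray), inverting the energy and
  MSP trends; the inward displacement is what makes all three scores resolve
  the near/far axis monotonically, as they do on real data. `delta = 0`
  reproduces the ID mixture exactly, giving an exact chance-level null.
  Alternative modes inflate the covariance by (1 + delta) or mix both
  mechanisms.
* **Class-size profiles**: `balanced` (equal counts, remainder to the
  lowest-indexed classes), `unbalanced-empirical` (counts proportional to
  supplied weights — the experiment drivers use a Zipf-like 1/rank tail to
  emulate a skewed corpus), and `unbalanced-uniform` (weights i.i.d.
  Uniform(0,1)). All use largest-remainder apportionment so totals are
  conserved exactly. An optional `min_count` floor (the experiments use 2)
  keeps every class fittable while leaving the imbalance severe.
* **Toy images** (optional, for exercising the image-level adapter): each ID
  class is a centered ellipse with class-determined aspect ratio and fill
  intensity plus small jitter and pixel noise; OOD images are rectangles
  with intensities from a band disjoint from every ID class. These are
  deliberately easy — a 16-unit hidden-layer network exceeds 90 % held-out
  accuracy within 20 epochs — because the adapter contract, not visual
  realism, is what they test.

What the generator does **not** emulate: real image statistics, feature
correlations induced by convolutional architectures, heavy-tailed or
multi-modal class-conditional densities, and label noise in the corpus.
Passing tests therefore certify the scoring and evaluation machinery and the
qualitative mechanisms (shift monotonicity, imbalance (in)sensitivity), not
performance numbers transferable to any particular real classifier.

## Reference classifier

A small numpy classifier — multinomial logistic regression, or one ReLU
hidden layer whose activations serve as the penultimate features — trained
with cross-entropy and a decoupled-weight-decay Adam optimizer (AdamW;
library defaults lr 1e-3, batch 256; the desk-scale experiment drivers use
lr 1e-2, batch 64, 40 epochs, sizes at which that schedule converges).
Training records one checkpoint per epoch tagged with held-out accuracy; the
accuracy-sweep experiment scores OOD detection through checkpoints from
early to late epochs, using their *measured* accuracies as the experimental
factor (accuracy need not rise monotonically with epoch, so no such
assumption is made). Training is seeded and reproducible on one platform;
bit-identical results across BLAS builds are not promised.

## Experiment drivers and problem sizes

All drivers are pure functions of their config and emit tidy tables
(experiment, factor_name, factor_value, method, metric, value, seed).
Test sets are frozen per seed before any method loop so methods and profiles
are always compared on identical samples.

* **Shift sweep**: delta grid (0, 1, 2, 4, 8), 5 seeds, ~180 test samples
  per side after equalization; records AUROC and FPR95.
* **Accuracy sweep**: checkpoints at epochs (1, 2, 4, 8, 16, 40) of the
  hidden-layer classifier, fixed delta = 3; MAH is refit per checkpoint
  because the features change with training.
* **Imbalance**: the three profiles at a shared total of 96 samples
  (min 2 per class), MAH refit per profile on fresh ID2 draws with the same
  class means; MSP/EBM scored once and their rows repeated verbatim. The
  shared test set uses 1,500 samples per side: the balanced-vs-uniform AUROC
  contrast is ≈ 0.01, so a test set small enough to add ±0.02 of sampling
  noise per seed would mask it; at 1,500 per side the paired gap is resolved
  in ~30 seeds.

## Known limitations

* The scalar `delta` is an idealized, one-dimensional stand-in for the
  qualitative spectrum of real OOD sources; there is no principled mapping
  from a real dataset to a delta value.
* A linear logit map cannot reproduce deep networks' behavior along
  arbitrary rays in feature space; conclusions about MSP/EBM at extreme
  shifts (beyond the classifier's plausible feature range) are outside the
  emulation.
* The imbalance effect on MAH is small at desk scale (≈ 0.01 AUROC); it is a
  mechanism demonstration, not an effect-size estimate.
* Checkpoint-based accuracy variation spans roughly 0.15–1.0 held-out
  accuracy on the synthetic task; it emulates an accuracy axis, not any
  particular training curriculum.
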