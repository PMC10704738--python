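# Methods

This note documents the models, the synthetic data the tests run on, the
numerical choices, and the known limitations of `rosscreen`.

## Target variable and labelling

Raw elicitor-triggered chemiluminescence is strictly positive and spans
roughly 9.5–540,000 relative units, so all modelling uses y = log₁₀(ROS)
(range ≈ 0.98–5.73). A compound is labelled a ROS modulator when y ≥ θ; the
default θ = 4.67 is inclusive (y = θ counts) and kept as configuration, not
a constant. At this threshold a typical diversity library yields ≈3.5%
positives (351 of 9,991 in the motivating screen). Compounds without a
measurement are excluded from fitting with a logged count, never imputed.

## Scaling

Descriptors are z-scored (per-column mean/stddev fit on the training
library) everywhere Euclidean distances matter — SMOTE neighbourhoods, GTM
fitting, map-space proximity — because raw descriptor magnitudes differ by
orders of magnitude and would otherwise dominate distances. Zero-variance
columns are kept with stddev replaced by 1 (they map to 0 and contribute
nothing to distances) so column indices stay aligned between training and
screening tables. Each fitted model stores its scaler and applies it
internally, so callers always pass unscaled descriptors.

## SMOTE

Implemented from first principles (Chawla-style): for each needed sample,
pick a minority point x, one of its k = 5 nearest minority neighbours z
(Euclidean in scaled space, self excluded, distance ties broken toward the
lower row index), and emit x + u·(z − x) with u ~ U(0,1). The minority is
raised exactly to the majority count; the integer part of the per-original
quota is uniform and the remainder is assigned to randomly chosen minority
points. Each synthetic row's parent, neighbour and u are recorded as
provenance, which the tests use to verify the convex-combination identity
and neighbour validity against a brute-force all-pairs scan. Because the
downstream model is a *regressor*, the target y is interpolated with the
same u as the descriptors — the only self-consistent way to give synthetic
rows a training target.

Augmentation ordering: the default pipeline oversamples **before** the
90/10 split. This is deliberate — it reproduces the published protocol —
but it leaks information: the test split then contains synthetic points
interpolated between training modulators, and precision/recall measured
there describe interpolation within known chemistry. The package therefore
also implements a stratified pre-SMOTE holdout (10% of each class removed
before augmentation, scored untouched), and the test suite asserts the
optimism gap between the two protocols rather than pretending either number
alone characterises the model.

## Feature selection

A 100-tree random-forest regressor (unlimited depth, seed 0) fit on the
un-augmented library ranks descriptors by impurity-decrease importance
(permutation importance is available behind a flag). Ranking precedes
augmentation so importances are not distorted by duplicated minority
structure. The working subset is a configured top-k (default 47); when k is
unset, the knee of the sorted-importance curve is used — the point of
maximum perpendicular distance to the chord from the first to the last
point, whose index equals the number of features preceding the knee. For
tables with fewer than k features the whole table is kept.

## ROS inference model

The neural network has three relu hidden layers (128, 64, 32) and a linear
output, trained with Adam on mean squared error for 100 epochs. Published
hyperparameter tables list "hidden layers 4" but only three sizes; this
package reads that as three hidden layers plus the output layer (four
weight layers), and a fourth hidden layer is one configuration flag away.
Details the source leaves unspecified are fixed at batch size 32, learning
rate 10⁻³, no early stopping (the epoch budget always runs to completion),
no dropout — all configurable. The baseline is a 100-tree random forest.
Both models are evaluated through the identical path: RMSE on log₁₀ ROS
plus precision/recall/F-measure after binarising predictions and targets at
θ (a regression model screens compounds by thresholding its prediction, so
classification metrics follow from the same rule). Ratios with empty
denominators are reported as flagged nulls, never as 0.

## GTM

Standard generative topographic mapping: K = 15×15 latent points on
[−1,1]², M = 5×5 Gaussian RBF centres plus a bias column, weight matrix W
mapping basis activations into data space, isotropic noise precision β.
EM runs a fixed 100 iterations (no early stopping; an optional tolerance
flag exists but is off by default) with log-sum-exp responsibilities.
Numerical choices:

- **RBF width.** The configured width 5 is ambiguous as an absolute latent-
  space σ (the basis would be near-constant over a 2-unit square). The
  interpretation is a switch: `relative` (default; σ = width × RBF-centre
  spacing = 2.5 at defaults) or `absolute` (as printed). All contract
  invariants hold under both.
- **Initialisation.** W is solved by regularised least squares so the
  initial manifold spans the first two principal components (scaled by the
  square roots of their eigenvalues); β⁻¹ starts at the larger of the third
  PCA eigenvalue and the squared half-mean nearest-neighbour distance
  between mapped prototypes. The square keeps units of variance.
- **Monotonicity.** With λ > 0 the EM objective is the penalised likelihood;
  the recorded `loglik_trace` is the data log-likelihood minus
  (λ/2)‖W‖², which EM increases monotonically (asserted to 1e-8 relative
  slack over 100 iterations in the tests). The raw data log-likelihood is
  kept alongside as `data_loglik_trace`; it can dip by ~10⁻⁴ late in a run
  as the prior trades likelihood for smaller weights.
- **Projection.** Posterior mean over the latent grid (default; a convex
  combination of grid points, hence always inside [−1,1]²); posterior mode
  by flag. The map used for selection is fit jointly on candidates plus
  reference modulators so both live in one coordinate system.

## Screening funnel

Stage 1 streams descriptor tables in 5,000-row chunks (memory bounded by
one chunk; the candidate set is chunk-size- and row-order-invariant, which
the tests check for chunk sizes 1, 7, 5,000 and N). Stage 2 partitions the
map into an 8×8 grid of 64 compartments — half-open cells, ids row-major
from the bottom-left, the +1 boundary closed, so the partition is exact.
Within each compartment containing at least one reference modulator,
candidates receive competition ranks for distance-to-nearest-reference
(ascending) and predicted log ROS (descending); the selection key is the
rank sum, ties broken by higher prediction then lexicographic id. Rank
combination is used because the two criteria have incommensurable units
(map distance vs log luminescence); a rank sum is scale-free. The
per-compartment quota (default 10) and an optional global cap are tunables,
and an exclusion id-list (e.g. chemist-flagged deleterious compounds) is
honoured at selection time.

## Synthetic data generator

The generator produces libraries with the statistical shape the pipeline
assumes, so every stage is testable without proprietary data:

- **Descriptors.** A low-rank latent-factor model induces correlated
  columns (strength 0.5 by default over 5 factors); ~30% of columns are
  converted to count-like Poisson marginals through a Gaussian copula,
  mimicking the mix of continuous physicochemical values and atom counts in
  real descriptor tables.
- **Activity.** A small set of informative descriptors (8 of 219 by
  default) drives activity through a normalised linear term plus one
  pairwise interaction and one saturating tanh term, so the relationship is
  partially nonlinear and a linear model cannot be perfect.
- **Calibration.** The noisy log-activity is mapped through a monotone
  two-piece linear function anchored so its minimum, its (1 − fraction)
  quantile, and its maximum land exactly on log₁₀ 9.5, the threshold 4.67
  and log₁₀ 540,000. The positive fraction (default 351/9,991 ≈ 3.5%) is
  exact by construction, and raw ROS respects the assay's range.
- **Noise.** Gaussian in log₁₀ units, default sd 0.35 — roughly half the
  published test RMSE of the real screen, leaving headroom for model error,
  and consistent with sub-half-decade replicate variability in
  luminescence assays.
- **Seeds.** The structure–activity relationship (which descriptors are
  informative, their coefficients, the factor loadings) is drawn from a
  `structure_seed` separate from the sampling `seed`, so libraries with
  different sampling seeds inhabit one "chemical universe"; a model trained
  on one library can meaningfully screen another, which is how the funnel's
  enrichment is measured.

What the generator does **not** emulate: real descriptor distributions
(heavy tails, hard correlations from shared substructure), activity cliffs,
assay plate effects, or chemistry. Passing tests demonstrate that the
pipeline's machinery is correct and that it recovers planted signal under
realistic shapes and noise — not that any particular accuracy will transfer
to a real compound library.

## Problem sizes in the test suite

The acceptance-level tests train at the motivating screen's scale (9,991
compounds × 219 descriptors, 351 positives) and stream a 20,000-row
screening table from the same synthetic universe; property tests use
200–10,000-point instances sized so each oracle comparison stays exact and
quick. These sizes are the package's reference experiment configuration;
the generator accepts arbitrary n.

## Known limitations

- Descriptor computation from structures is out of scope; tables of
  precomputed descriptors are the interface (an SDF pass extracts ids only).
- The in-library accuracy protocol leaks by construction (see SMOTE
  ordering above); use the holdout protocol for honest generalisation
  estimates.
- The network trains on CPU via scikit-learn's multilayer perceptron;
  exact weight trajectories are reproducible for a fixed seed and backend
  but not across BLAS implementations.
- GTM magnification factors, GTM-based regression, and mini-batch/EM
  variants are not implemented.
- Secondary-selection weights between proximity and predicted activity are
  a design choice (unweighted rank sum); there is no ground truth for the
  "right" trade-off.
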