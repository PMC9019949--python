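# Methods

## Problem

Estimation of model accuracy (EMA/QA) asks how good a single predicted
protein structure (a "decoy") is, without access to the native structure.
`diffqa` implements a single-model method whose only input is the
disagreement between two inter-residue distance maps of the same protein:

* **A** — the map predicted from sequence by an external real-valued
  distance predictor (an L×L text matrix supplied by the user), and
* **B** — the map computed from the decoy's coordinates.

**A** encodes where residues are *expected* to be relative to one another;
**B** encodes where the model *put* them. Their residual is therefore a
direct, feature-free image of model error, and a convolutional network can
regress the decoy's global quality (GDT-TS, in [0, 1]) from it.

## Feature construction

1. **Representative atom.** Distances are measured between C-beta atoms,
   falling back to C-alpha for glycine or when C-beta is absent (the
   convention of common sequence-based distance predictors). The choice is
   configurable and recorded in the feature store and checkpoints, and
   inference refuses a store/checkpoint pair that disagrees.
2. **Mutual filter.** Distances above a cutoff (default 16 Å) say little
   about the fold. Wherever *either* A[i,j] or B[i,j] exceeds the cutoff,
   *both* entries are zeroed, giving A* and B*.
3. **Difference map.** U = upper triangle (strictly above the diagonal) of
   A* − B*. The lower triangle and diagonal are exactly zero; D is
   symmetric so no information is lost, and halving the support cheapens
   training.

Residues missing from a model (chain gaps) keep their sequence position:
their rows/columns in B are set far above the cutoff so the mutual filter
removes those pairs, keeping A and B aligned at L×L. A model whose residue
numbering spans a different length than the predicted map is rejected as a
misalignment rather than guessed at. Predicted maps that are asymmetric by
more than 0.5 Å are treated as corrupt; smaller asymmetries are averaged
away as (M + Mᵀ)/2.

## Network

A four-block 2D CNN with channel attention, written directly on numpy
(im2col + GEMM convolutions with hand-derived backward passes; every layer
is gradient-checked against central finite differences in the test suite):

* Conv block: 3×3 convolution → batch normalization → leaky ReLU
  (slope 0.01). Default channel progression 1 → 16 → 32 → 64 → 256.
* Blocks 1 and 2 end with a squeeze-and-excitation (SE) block,
  reduction ratio 16: global average per channel → FC (C → C/16) → leaky
  ReLU → FC (C/16 → C) → sigmoid; the per-channel weights in [0, 1]
  re-scale the block's output. Clamping every gate to 1 reproduces the
  attention-free network exactly, which makes ablation comparisons
  well-defined.
* Global max-pooling collapses each of the 256 final channels to its
  maximum, so the parameter count and output shape are independent of L.
* Four dense blocks (widths 256 → 256 → 64 → 16 → 1), leaky ReLU except
  the final plain ReLU, so predictions are non-negative scalars. The output
  is not clamped at 1: ranking is unaffected, and the score scale is
  learned from data.

Spatial resolution is reduced by strided convolutions (default strides
1, 2, 2, 2). Since the global max-pool ultimately discards spatial layout,
the downsampling costs little accuracy while reducing the arithmetic per
forward/backward pass by roughly an order of magnitude — the design choice
that makes full training practical on a single CPU core in minutes.

Weights use kaiming (fan-in) initialization matched to the leaky-ReLU gain,
except the output layer, whose weights are damped to standard deviation
1e-3 with the bias at 0.5 (the middle of the score range). A full-scale
random projection at the output can start negative on every input, and a
terminal ReLU that is dead on the whole training set receives no gradient
and never recovers; the damped start keeps it active for any input scale
while leaving every layer trainable from the first step.

## Training

Smooth-L1 loss on the residual x = predicted − true score:
0.5 x² for |x| < 1, |x| − 0.5 otherwise; its derivative is x on (−1, 1) and
±1 outside (the closed-interval convention at |x| = 1, where both branches
agree). Since GDT-TS residuals live well inside (−1, 1) the loss is usually
quadratic; the linear tails bound the influence of outliers.

Optimization is Adam (β₁ = 0.9, β₂ = 0.999) at a constant learning rate of
5·10⁻⁵ with batch size 16. Because maps of different proteins have
different sides, batches are *length-homogeneous*: records are grouped by
L, shuffled, and chunked to ≤ 16. From every batch, 80% of members
(seeded-random, at least one; singleton batches go entirely to training)
enter the training split and the rest the validation split, so both splits
cover the full length distribution. Batch order (not membership) is
reshuffled each epoch. The epoch count is configurable (default 120 for the
estimator; the full benchmark pipeline uses 200); the state with the lowest
validation loss is kept — with a constant learning rate the validation loss
keeps improving in bursts, so late best epochs are common and the
checkpoint restore matters. All randomness flows from integer seeds through
`numpy.random.Generator`, making runs bit-reproducible.

## Evaluation suite

* **Ranking loss** per target: |best true score − true score of the decoy
  ranked first by prediction|; ties in predicted score are broken by
  lexicographically smallest model id (deterministic; community practice
  varies and no convention is canonical).
* **Per-target PCC**: Pearson correlation of (predicted, true) over a
  target's pool; undefined (and excluded from the mean, with a logged
  count) for pools smaller than 2 or constant score sequences. The report
  also carries the pooled-over-all-models PCC and the best-vs-selected
  PCC, since summary correlations are quoted in all three senses in the
  EMA literature.
* **Two-sample Kolmogorov–Smirnov test**: D = sup |F₁,ₙ − F₂,ₘ| evaluated
  exactly over the pooled sample points, with the asymptotic two-sample
  Kolmogorov p-value (scipy's `ks_2samp(method="asymp")`); applied to
  (1) all true vs all predicted scores and (2) per-target best vs selected
  true scores.
* **Skewness** of the ranking-loss distribution: the population (biased)
  estimator m₃/m₂^{3/2} with 1/n moments, no small-sample correction.

## Synthetic benchmark

Real decoy sets with predictor-derived distance maps are large downloads
and their labels need superposition software, so the package ships a
generator that emulates the statistical structure of that data at desk
scale:

* **Native chain**: self-avoiding random walk, 3.8 Å virtual bonds,
  ≥ 4 Å between non-consecutive residues. No secondary structure or
  Ramachandran realism — the network only ever sees distance residuals, so
  chain realism matters less than distance-map statistics.
* **Decoys**: native coordinates + isotropic Gaussian noise, with noise
  scales cycled through {0.25, 0.5, 1, 2, 4} Å so each 20-decoy pool spans
  near-perfect to heavily distorted models.
* **Predicted map**: the native representative-atom map plus symmetric
  Gaussian noise (default σ = 0.5 Å), clipped at zero — an imperfect
  "sequence-based" predictor.
* **Label**: a superposition-free GDT-TS surrogate — the mean over cutoffs
  {1, 2, 4, 8} Å of the fraction of residue pairs (native distance ≤ the
  working threshold) whose decoy-vs-native distance error is below the
  cutoff. A zero-noise decoy scores exactly 1; with the default noise
  ladder the pooled labels span ≈ 0.36–1.0 (σ = 4 Å distorts distance
  errors to a scale where ~45% of pairs still fall under the 8 Å cutoff,
  so labels do not reach arbitrarily low values).

Decoy PDB files carry C-alpha plus idealized pseudo-C-beta atoms (1.53 Å
along the backbone-bond bisector; glycine has none), so the featurizer's
atom convention, including the fallback, is exercised by round-trips.

Because the label is a deterministic function of the native and decoy
distance maps — exactly the information the difference map exposes — the
regression task is learnable in principle, which is what the end-to-end
learning test verifies. Passing it shows the pipeline can extract
quality signal from distance residuals under controlled noise; it does not
certify performance on real decoy sets, whose error modes (fragment
re-use, register shifts, domain re-orientation) are not emulated.

## Problem sizes and numerical choices

The default benchmark used by the learning test and the acceptance script
is 30 targets, lengths uniform in [30, 60], 20 decoys per target (600
models, ~480 train / ~120 validation), trained 200 epochs — about five minutes
on one CPU core. Tests use float64 for gradient checks (finite-difference
agreement ~1e-7) and float32 for training. Degenerate inputs are defined
behaviour: empty record lists error, empty validation sets warn and skip
validation bookkeeping, constant samples make PCC/skewness undefined
markers rather than numbers. Argmax ties in the global max-pool resolve to
the first flattened index; predicted-score ties resolve to the smallest
model id.

## Known limitations

* No mmCIF input; PDB coordinate records only (first model, first chain,
  highest-occupancy altLoc).
* The quality surrogate is rank-faithful to, but not identical with,
  superposition-based GDT-TS.
* Short-range |i−j| pairs are not masked from the difference map; whether
  masking helps is untested here.
* The network reports a non-negative score that can exceed 1; a
  report-time clamp is deliberately not applied.
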