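# Methods

## Model

The package implements a reentrant multi-map architecture for post-labeled
unsupervised classification. Its components and the assumptions behind them:

**Kohonen maps (one per modality).** A rectangular lattice of neurons, each
holding a prototype in data space. Training is online competitive learning:
the sample's best-matching unit (BMU, L2 argmin over prototypes; ties go to
the lowest row-major index) and its lattice neighbours move toward the
sample by `eps(t) * exp(-d_lattice² / 2σ(t)²)` of their gap. Both the
learning rate and the neighbourhood width decay geometrically,
`x(t) = x_i (x_f/x_i)^(t/t_f)`, with `t` counting individual sample
presentations (a single global clock; `t_f = epochs × n_samples`). Since
`0 ≤ eps·h ≤ 1`, every update is a contraction toward the sample — this is
asserted as a property test. Prototypes are initialized uniformly at random
inside the per-feature data range, and training order is a fresh per-epoch
shuffle from a seeded generator, so runs are bit-reproducible.

**Map activation.** A trained map responds to `v` with
`a_n = exp(-‖v − w_n‖ / α)` — the *unsquared* Euclidean norm in the
exponent, which is the form this family of models states; a `squared`
switch on `ActivationParams` provides the common Gaussian-kernel variant
for experimentation. The scalar map activation `a^s` is the maximum
(attained at the BMU).

**Hebbian lateral matrices.** One dense nonnegative matrix per unordered map
pair (the reverse direction is the transpose — the update rule is symmetric
in the two maps). After the maps are frozen, each index-aligned training
sample strengthens the single entry linking the two maps' BMUs by
`μ·a_x·a_y`. Weights only grow; no cap, decay or normalization is applied.
Because each sample touches one entry per pair, the matrices stay sparse
(5–7 % nonzero at the desk scale used here).

**Neuron labeling.** Each neuron gets a class-probability vector from a
small annotated subset: `p(j,s,i)` is the fraction of neuron `(j,s)`'s
summed labeling activation contributed by class-`i` samples. The labeling
activation is additive,
`A_s^j = c1_j a_s^j + Σ_{l≠j} c2_{l,j} · a^l · W[bmu_l, s]`, with named
coefficient presets *unimodal* (all c2 = 0; the default), *divergence*
(all c1 = 0) and *mixed*. Assigned class = argmax (ties to the lowest class
id). Afferent activations are strictly positive, so under unimodal labeling
the probability vectors always normalize; a degenerate all-zero activation
sum (possible under divergence labeling with untrained laterals) falls back
to a uniform vector.

**Fused inference.** At test time aggregation is multiplicative:
`A_s^j = a_s^j × Π_{l≠j} a^l · W[bmu_l, s]`, and the prediction is the
assigned class of the globally most active neuron over all maps (ties to
the lowest (map, neuron) pair). The additive/multiplicative asymmetry
between labeling and inference is intentional in the model family and is
implemented as stated. `a^l · W[bmu_l, s]` is interpreted as the *scalar*
BMU activation of the source map times the single weight from that BMU to
neuron `s`; the alternative reading (full activation-vector dot product
with the weight column) is not the default because the Hebbian rule only
ever trains BMU-pair entries. If pruning (or untrained laterals) drives
*every* fused activation to zero, prediction falls back to the afferent
activations alone, which are strictly positive.

**Pruning.** `prune_weakest(laterals, keep_fraction)` ranks the nonzero
entries of each matrix by weight and keeps the top
`ceil(keep_fraction · nnz)`, where `nnz` is the nonzero count of the
*trained* matrix. That reference count is recorded on first pruning, so
pruning repeatedly at the same fraction is idempotent and the kept-rate
axis of a pruning sweep always refers to the trained matrix. Ties at the
cut keep the lower flat index (deterministic).

## Tunable parameters

| parameter | default | units / meaning |
|---|---|---|
| `eps_i, eps_f` | 0.5, 0.01 | learning rate per presentation |
| `sigma_i, sigma_f` | max(width,height)/2, 0.5 | neighbourhood width, lattice units |
| `epochs` | 5 | passes over the training set (`t_f = epochs·n`) |
| `alpha` | `"auto"` in the estimator; `m` (input dim) in the low-level API | activation sharpness divisor, data units |
| `mu` | 1.0 | Hebbian learning rate (pure scale; does not affect rankings or argmaxes) |
| `c1, c2` | unimodal preset | labeling coefficients in [0,1] |
| `keep_fraction` | 1.0 | kept share of trained nonzero lateral weights |

`alpha="auto"` calibrates each map's α to its mean quantization error (mean
sample-to-BMU distance) on the training data, so a typical in-cluster sample
activates its BMU at about 1/e while distant prototypes fall off steeply.
This keeps activations discriminative regardless of dimension or feature
scaling; a fixed α equal to the input dimension (the dimension-invariant
convention of the low-level API) makes all activations cluster near 1 on
unit-scaled data, which leaves argmaxes intact but weakens labeling
contrast. Calibrating to the quantization error was the single most
effective activation choice in our sweeps.

## The synthetic benchmark

`GeneratorSpec`/`generate` build k index-aligned modalities of isotropic
Gaussian class clusters with engineered complementary confusions: within
each modality, the classes of a configured "confusion pair" share a region
(centers `delta_near` apart) while all other class centers are mutually
`delta_far` apart (placed on orthogonal axes scaled to that distance, then
randomly rotated; features min-max scaled to [0,1]). Defaults: 2 modalities
of dimension 16, 10 classes, modality 0 confuses {4,9}, modality 1 confuses
{1,7}, `delta_near=0.12`, `delta_far=1.0`, `cluster_spread=0.075`, splits
2000 / 200 / 500 (train / label / test) with near-balanced classes.

The geometry is calibrated so the confused centers sit ≈1.6 cluster
standard deviations apart: deep enough that the nearest-true-center oracle
errs on roughly a fifth of the pair's samples (per-modality accuracy
≈0.93–0.95), shallow enough that prototypes in the overlap region retain a
class lean the labeling stage can exploit. Pushing the overlap deeper makes
each map's overlap neurons class-agnostic; fused inference then routes
about half of the confused samples to the weak map (the two maps' top fused
candidates at the joint BMU pair have *identical* value by the symmetry of
the Hebbian rule), and the fused accuracy collapses toward the unimodal
one. Moving it shallower removes the headroom fusion could recover. Higher
modality dimensions (32–64) were rejected: distance concentration flattens
the activations and weakens fusion.

What the generator deliberately does not emulate: raw-pixel/MFCC manifold
structure, unequal modality dimensionalities and qualities, label noise,
class imbalance, and the much larger sample-to-connection ratio of real
MNIST-scale runs. Passing tests on this benchmark demonstrate the
mechanics — complementary-confusion repair, sparsity, determinism — not
full-scale accuracy figures.

## Desk-scale behaviour of fusion and pruning

At the benchmark's scale, ten-replicate medians are typically: best
unimodal ≈ 0.94, fused ≈ 0.96–0.99, fused after keeping 10 % of nonzero
laterals ≈ 0.93–0.96. Two quantitative caveats follow from the scale, not
from the method:

- The fused-over-unimodal margin is limited by the single confused pair
  (at most one tenth of the test set) plus per-neuron labeling noise; the
  median margin fluctuates between about +1.5 and +5 points across seed
  batches, always positive.
- A 100×100 lateral matrix trained by 2000 Hebbian events holds ~500–650
  nonzero entries; keeping 10 % leaves ~0.6 connections per neuron row, so
  14–18 % of test samples lose every lateral path and fall back to
  afferent-only prediction. Aggressive pruning therefore costs 2–4 points
  here, whereas at full scale (≈20k nonzero entries, ~8 kept per row) the
  same kept-rate is reported to sit on an accuracy plateau. The ordering
  `acc(keep 0.01) ≤ acc(keep 0.1) ≤ acc(1.0)` and the bit-exactness of
  `keep_fraction=1.0` hold at any scale and are tested.

## Numerical choices

- All BMU searches and activation evaluations use the same distance
  expression in per-sample and batched code paths, so batch results are
  bit-identical to scalar loops (asserted in tests) and tie-breaks never
  diverge between paths.
- BMU ties → lowest flat index; label argmax ties → lowest class id; fused
  winner ties → lowest (map, neuron) pair. All deterministic.
- Seeds: the estimator derives per-map initialization and shuffling streams
  from one `SeedSequence`, so a single integer reproduces a fit bit-exactly;
  the replicate study derives data seeds as `seed + 9973·r (mod 2³¹−1)`.
- `eps_i = eps_f = 0` is accepted as a degenerate frozen-map schedule
  (useful in tests); `sigma` must stay positive.
- Model containers are `.npz` archives with a JSON metadata block and a
  format version; loading rejects version mismatches and truncated files,
  and round-trips are bit-exact.

## Known limitations

- Online/simultaneous SOM + Hebbian learning is out of scope: laterals are
  trained only after the maps are frozen.
- No weight normalization or decay on the lateral matrices; very long
  Hebbian training grows weights without bound (harmless for argmax-based
  inference, but magnitudes are not comparable across differently sized
  training sets).
- The multiplicative fusion assumes all modalities are present at test
  time; missing-modality inference is not implemented.
- The CLI realizes the multi-stage pipeline sequentially in one process;
  per-map computations share no state, preserving the conceptual
  parallelism, but no distributed execution is provided.
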