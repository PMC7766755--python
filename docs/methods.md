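# Methods

## The measurement

`causalplane` quantifies the causal structure of a dense feedforward layer
L1 → L2 (weight matrix `W`, elementwise activation, no biases by default) by
intervening on it rather than by observing it on data.  The inputs are forced
to a maximum-entropy state — i.i.d. uniform over each input node's activation
range — and the information transmitted to the outputs is measured:

* **Effective information**: `EI = I(L1; L2) | do(L1 = Hmax)`, the mutual
  information between the joint input state and the joint output state under
  the uniform intervention.  EI is data-independent: it reflects what the
  layer's mechanism *would do* under any input, not what it does on a
  particular data set.
* **Sensitivity**: `sum over edges (i,j) of I(t_i; t_j) | do(i = Hmax)`, where
  target j is driven through the single edge alone (`activation(w_ij * t_i)`,
  all other incoming edges removed).  It measures transmission with
  interaction effects absent.
* **Degeneracy**: `sensitivity − EI`, computed algebraically — the
  information lost because overlapping fan-ins make upstream perturbation
  sources ambiguous from downstream observations.
* **EI_parts**: `sum over (i,j) of I(t_i; t_j) | do(L1 = Hmax)` — pairwise
  MIs under the *joint* intervention.
* **phi (feedforward integrated information)**: `EI − EI_parts`, the
  irreducible joint contribution of the layer's edges.  It is not bounded
  below by zero; negative values indicate mostly noisy joint effects.

The *causal plane* plots degeneracy (x) against sensitivity (y).  Since
`EI = sensitivity − degeneracy`, motion along the 45° line (the EI
*nullcline*) leaves EI unchanged; layers are tracked as points moving in this
plane across training checkpoints.

## Estimation

Activations are discretized into `n_bins` uniform-width bins over fixed
per-node ranges; bins are half-open except the closed top bin, and
out-of-range values are clipped into the boundary bins.  Ranges follow the
upstream-activation convention: (0, 1) for sigmoid, (−1, 1) for tanh, and
[0, 1] for relu (truncating relu's unbounded codomain; at weight 1 a relu
edge then exactly fills the binning range, which is what makes its
characteristic peak sit at 1).  Data-input nodes, which have no upstream
activation, use [0, 1].

MI is the plug-in (maximum-likelihood histogram) estimate in bits.  No bias
correction (Miller–Madow or otherwise) is applied; instead every estimate
carries a *convergence trace* — values at doubling sample counts — and a
flag comparing the last two doublings against a tolerance.  The plug-in
estimate is biased upward when the occupied joint state space is comparable
to the sample count; for a deterministic layer the input-entropy terms cancel
(`EI` reduces to the plug-in entropy of the binned output), so the bias grows
with output width and bin count.  This matters for the wide training-time
measurements (below) and is why the default trajectory budget should be read
comparatively, not absolutely.

Joint states are counted in a sparse hash map keyed by bin-index tuples
(dense `bincount` arrays when the full space is ≤ 2^22 cells), so memory is
proportional to observed states, never to `n_bins ** n_nodes`.  Sampling
streams in batches; the EI/EI_parts pair is computed from one shared joint
injection (common random numbers, reducing the variance of `phi`), while
sensitivity uses independent per-source-node sub-streams spawned from the
same master seed.

Numerical conventions: estimates are clamped at 0 from below; a constant
marginal short-circuits MI to exactly 0; edges with exactly zero weight are
skipped in the sensitivity and EI_parts sums (their contribution is exactly
zero); degeneracy and phi are reported unclamped, so small negative values
reflect Monte-Carlo noise honestly.

A deterministic midpoint-quadrature oracle (`quadrature_ei`) computes the
same binned MI by exhaustive integration for 1- and 2-input layers (default
1e5 cells per input dimension for one input, 2048 per dimension for two) and
is used throughout the tests as an independent cross-check of the sampler.

## Characteristic single-edge curves

`ei_curve_single_edge` scans EI of an isolated edge over a weight grid,
sharing one input draw across grid points so the curve is smooth and its
argmax sits at the exact plug-in optimum for the chosen bin count.  For relu
the peak is exactly at weight 1 for every bin count.  For sigmoid and tanh
the exact plug-in argmax *oscillates with the bin count* (e.g. ≈ 3.10 and
≈ 1.55 at 16 bins) around the continuum optimum of the output's differential
entropy (≈ 2.85 and ≈ 1.42, obtained as the bin count grows): the uniform
input pushed through a monotone nonlinearity produces bin-boundary
commensurability effects that a finite histogram cannot avoid.  The often
quoted closed-form peak locations e and coth(1) are continuum idealizations;
the binned estimator implemented here does not reproduce them exactly at any
fixed bin count, and the corresponding checks in the test suite document
this divergence rather than hide it.

## Synthetic tasks

Both bundled generators emit class-balanced feature tables scaled to the
unit cube (matching the intervention convention for data-input nodes), with
one-hot targets.

* `iris_like` (4 features → 3 classes, 120 train / 30 test): three Gaussian
  blobs (σ = 0.08) separated by *direction* rather than offset, because
  bias-free networks can only carve zero-threshold hyperplanes; classes 1
  and 2 overlap slightly.  Calibrated so a logistic regression reaches
  ≥ 0.90 test accuracy (the real flower data sits near 0.97).
* `mnist_like` (25 features → 5 classes, 500 train / 250 test): every class
  is a two-mode Gaussian mixture (σ = 0.12).  Classes 0–1 get an *antipodal*
  second mode (`1 − c`), which no linear functional can separate from the
  rest; classes 2–4 get an independent second mode.  This reproduces the
  degenerate many-modes-to-few-classes character of downsampled digit
  classification: linear accuracy ≈ 0.75 while a small nonlinear network
  reaches ≈ 0.95.

What the generators do *not* emulate: correlated pixel structure, manifold
curvature, heavy class imbalance, label noise.  Passing the trajectory tests
therefore shows that the *measurement suite* resolves the
separable-vs-degenerate contrast, not that it reproduces numbers obtained on
the real data sets.

## Training protocol

Vanilla gradient descent on squared error with one-hot targets, learning
rate 0.01, uniform fan-in initialization `U(±1/√fanin)`, no biases; batch
size 10 for 4000 epochs (iris-like) and 50 for 500 epochs (mnist-like).  The
gradient uses the squared error *summed* over the batch and output
dimensions (the classic backprop objective); reported loss values are
per-sample per-output means for readability.  Under mean-reduced gradients
the stated learning rate is too small for these bias-free sigmoid networks
to fit within the stated epoch budgets at all, so the sum convention is the
one consistent with the protocol actually converging.

Measurement checkpoints default to a geometric schedule (12 points, denser
early, always including step 0 and the final step) because causal-structure
movement concentrates in the steep-loss phase.  The per-checkpoint
measurement budget defaults to 1e5 samples with 16 bins — a deliberate
desk-scale choice; estimates carry convergence flags, and wide first layers
(25 inputs) are visibly biased upward at this budget, uniformly across the
conditions being compared.

## Redundancy experiment

`redundancy_experiment` retrains the mnist-like network in three variants —
base (two hidden layers), one hidden layer removed, and redundant hidden
layers added — and compares per-layer causal-plane path lengths and mean
nullcline distances at matched final accuracy.  Bias-free sigmoid stacks
deeper than four layers do not optimize under plain gradient descent (the
forward map contracts to a constant and gradients vanish), so the default
adds **one** redundant layer and gives every variant a uniform 3000-epoch
budget, under which all three variants reach comparable test accuracy.  The
added layer's shorter path and smaller nullcline distance are assessed as
means over layers and over ≥ 3 seeds; the comparison is qualitative, not a
reproduction of any printed figure.

## Known limitations

* Plug-in MI bias at trajectory budgets (see above); absolute EI values at
  1e5 samples for 25-input layers should not be compared against converged
  (≥ 1e7 sample) values.
* The sigmoid/tanh single-edge peak locations are bin-count dependent
  (commensurability oscillation); only the relu peak is bin-invariant.
* The quadrature oracle covers at most two input nodes; wider layers are
  cross-checked only through invariants (bounds, permutation symmetry,
  exact zero cases).
* Continuous (binless) MI estimators, partition-search integrated
  information, and convolutional/recurrent layers are out of scope.
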