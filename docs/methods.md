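# Methods

This note documents the models implemented in `koniolearn`, the design
choices that were genuinely open, the numerical conventions, and what the
shipped tests do and do not demonstrate.

## Neuron model

A neuron is a rate-coding unit: its output `O ∈ [0, 1]` is a firing
probability, not a membrane potential or spike train.  The activation is
a shifted sigmoid

    O = σ(k (net + 0.5 − 2 s)),      σ(z) = 1 / (1 + e^−z),

with `net` the weighted input sum, `s ∈ [0, 1]` the shift and `k > 0` the
slope (compression) factor.  The induced firing threshold — the net input
at which `O = 1/2` — is `T = 2 s − 0.5 ∈ [−0.5, 1.5]`.  The default
`k = 500` makes the unit effectively binary away from threshold, which is
why winner readout compares excitations `net − T` rather than outputs:
at `k = 500` two outputs can differ only in the 16th decimal while their
excitations differ by 0.06.

σ is evaluated with a sign branch so that `e^z` is only computed for
`z ≤ 0`; arguments up to `|z| = 10⁴` are exact and overflow-free.

**Intrinsic plasticity.**  After producing `O`, the shift moves by

    s ← (ν O + s) / (1 + ν),        ν ≥ 0,

a convex combination of shift and output, so `s` can never leave
`[0, 1]`.  With constant `O` the shift converges geometrically,
`|s_t − O| = |s₀ − O| (1+ν)^−t`, which the tests verify to 1e−12.  The
endpoints `s ∈ {0, 1}` are admitted as closure points of the open range;
any output in `(0, 1)` immediately restores strict interiority.  Output
is always computed with the pre-update shift; shifting is a consequence
of the activity just produced.

## Presynaptic rule

Synaptic efficacies live in `[0, 1]` and update as `Δw = η I (O − w)`.
Algebraically `w' = w(1 − ηI) + ηI·O` is a convex combination, so the
unit interval is invariant (tested exhaustively on a 0.05 grid of all
four arguments).  On a stationary stream the expected update vanishes
exactly at `w* = E[IO]/E[I]`, the conditional probability of postsynaptic
firing given presynaptic firing; simulation at `n = 10⁵`, `η = 0.02`
recovers random conditionals within ±0.03 (±0.02 for the anchored
0.8/0.6 stream).  The step size `η·I·|O − w|` shrinks as `w` approaches
`O`: adapted synapses change less, which is the rule's intrinsic
metaplasticity.

## Metaplastic learning rate (AMP)

The rate model scales a base rate inversely with estimated pattern
probability:

    η_eff(x) = clip(η₀ · p̄ / (ε + p̂(x)),  η₀ c_min,  η₀ c_max).

`p̂` is an exact histogram for discrete patterns and a product-Gaussian
kernel density (Silverman bandwidth, via `scipy.stats.gaussian_kde`) for
continuous ones; `p̄` is the mean estimated probability over the training
patterns, so uniform data yields `η_eff ≈ η₀`.  Defaults: `ε = 10⁻³`,
clip `(0.1, 10)`.  The rate is evaluated once per pattern presentation —
the mechanism is defined at pattern level, not per weight.  With
`c_min = c_max = 1` the clip pins `η_eff = η₀` exactly, and AMP gradient
descent is bit-identical to plain gradient descent; the demonstration MLP
(logistic activations, mean-square error) exists for exactly this
equivalence test, a finite-difference gradient check, and a skewed-task
comparison in which the rare class trains to lower error under AMP.

## Competitive layer and settling

`net_j = Σ_i w_ji x_i + a_j O_j(t−1) − g Σ_{m≠j} O_m(t−1)`: feedforward
drive plus an autapse (recurrent self-excitation, weight `a_j ∈ [0,1]`,
learned) minus fixed-gain lateral inhibition from all other neurons
(`g`, default 1, never learned — inhibitory synapses are
non-modifiable).  Updates are synchronous: all step-`t` nets use
step-`t−1` outputs, making the dynamics independent of neuron order and
exactly reproducible.

A settle run starts from silence (`O = 0` for all neurons) and stops when

1. exactly one output is ≥ `θ_fire` and all others ≤ `1 − θ_fire`
   (default `θ_fire = 0.9`; with `k = 500` the outputs are near-binary so
   the value is insensitive), or
2. the state stagnates: no output changes by more than 1e−9 — and, when
   shift adaptation is active, no shift is still moving by more than that
   either.  The shift clause matters: during the silent phase the outputs
   are constant at ≈0 while homeostasis is still dragging thresholds
   down toward firing, and that phase must not be mistaken for
   convergence; or
3. a step budget runs out (non-convergence is reported in the trace, not
   raised).

The winner is `argmax_j (net_j − T_j)` over the final step, ties to the
lowest index.  The inner loop is numba-compiled; a pure-Python step
function with identical arithmetic exists alongside it and a test pins
their agreement at 1e−15.

## Competitive Perceptron

**Input coding.**  Raw patterns in `[0,1]^d` are complement-coded
(`x ↦ (x, 1−x)`) and divisively normalized to total activity `scale`
(default 1).  Complement coding makes the all-zero pattern representable
and the normalization denominator constant; divisive normalization is the
single-layer analogue of the KLN's shunting basket neuron.  The `scale`
set point fixes the drive of a tuned neuron relative to the homeostatic
floor of an idle one.

**Supervised training** is winner-only competitive learning.  Each
presentation settles with adaptation on; then only the winning neuron
updates, with the postsynaptic term clamped to the winner's one-hot
target entry: reinforcement toward 1 if the winner is the labelled class,
depression toward 0 otherwise (autapses update the same way with the
neuron's own settled output as the presynaptic term).  The alternative —
clamping every neuron to the one-hot target each presentation — has a
degenerate fixed point on complement-coded XOR: every encoded component
is active with identical magnitude in exactly one pattern of each class,
so all weights converge to 0.5 and the feedforward drive carries no
pattern information; training then provably plateaus at 3/4.  Winner-only
updates break that symmetry because error events touch different encoded
components for different patterns, and any configuration that classifies
all patterns correctly is absorbing.

**Unsupervised training** applies the presynaptic rule to every neuron
with the WTA-resolved outputs (winner 1, others 0) as the postsynaptic
terms.  The resolved outputs, not the raw final-step sigmoids, are the
right learning signal here: the synchronous near-binary dynamics can
oscillate between all-fire and all-off phases, and the raw final step
would then reinforce every neuron toward 1.  Resolution reflects what the
competition computes — the winner fires, lateral inhibition silences the
rest.  Class labels, when available, are attached afterwards by majority
vote over winners.

**Prediction** freezes the shifts (`ν = 0`) and settles from silence;
repeated calls are identical, and identical seeds give byte-identical
models and traces (model JSON is written with `repr`-exact floats and
sorted keys).

### XOR demonstration

`evaluate_xor` trains a 2-neuron supervised CP on the four XOR patterns
(neuron 0 ↔ {(0,0), (1,1)}).  The shipped configuration —
`η = 0.025`, `ν = 0.08`, `k = 500`, `g = 1`, weights and autapses
initialized U(0, 0.1), initial shift 0.5, settle budgets 25 (training) /
50 (evaluation), epoch cap 16 000 with early stop at 4/4 frozen
accuracy, and re-initialization from the same seeded stream after 2 500
epochs without improvement — was selected by a small grid search over
`η`, `ν` and the budgets, then validated on 160 held-out seeds (all
reached 4/4; median solve time is a few hundred epochs, and a 50-seed
run takes ≈15 s on one CPU).  Training is a stochastic search: the
homeostatic churn explores configurations, error-driven updates bias the
walk, perfect configurations absorb it, and the patient restart frees
the ~3 % of seeds that fall into a non-solving attractor.

The ablation control — complement coding off, autapses off, a single
settle step, frozen shifts — reduces prediction to
`argmax_j (w_j·x − T_j)`, a linear readout of the normalized input, and
XOR's classes are not linearly separable in that space (their class
means coincide), so the control fails for every seed.  Together the two
halves show it is the recurrent settling with complement coding and
homeostatic thresholds, not some accident of parameterization, that
yields the nonlinear capability.

## Koniocortex-like network

The simplified assembly chains per-channel TC neurons (shifted sigmoids
with their own slope `k_TC = 5` and velocity `ν_TC = 0.05`, whose shifts
track each channel's long-run mean output), a shunting stage that divides
the S-layer drive by summed TC activity (`ε = 10⁻⁶` guards zero), and a
competitive S layer with autapses trained exactly as the CP.  Basket-cell
inhibition is folded into the layer's fixed gain rather than simulated as
separate units — explicit inhibitory units with non-modifiable weight 1
would add no observable behavior at this level of description.  With TC
and shunting configured to identity the assembly reduces bitwise to a CP
without input coding, which is tested.  The default preset uses 15 input
channels and 10 S neurons; all sizes are configurable.

## Synthetic data

All inputs are generated in-package, deterministically per seed: the XOR
truth table; paired Bernoulli firing streams with prescribed
`P(I)`, `P(O|I=1)`, `P(O|I=0)`; isotropic Gaussian clusters with
deterministic means on `{0.2, 0.8}`-corners of the unit box (spread 0.05
unless stated, clipped to `[0,1]`); and frequency-skewed draws from a
prototype set.  Datasets round-trip through the package CSV dialect
bit-exactly (`repr` floats).  The generators emulate stationary,
low-dimensional, well-separated structure; they do not emulate label
noise, covariate drift, correlated features or high dimensionality, so
passing tests bound behavior only under those benign conditions.

## Cluster experiments and problem sizes

The cluster study uses 3 clusters × 50 points in 2-D at spread 0.05.
Classification consistency is measured with supervised training
(`η = 0.025`, `ν = 0.08`, 200-epoch cap with early stop and a 50-epoch
restart patience): 20/20 seeds reach perfect consistency.  Quantization
error is the mean Euclidean distance from each raw pattern to the
prototype decoded from its winner's weight row,
`x̂_i = w_i / (w_i + w̄_i)` with `w̄` the complement-component weight —
a decoding that recovers the cluster mean exactly at the presynaptic
fixed point.  Mean QE falls from ≈0.15 with 3 neurons to ≈0.11 with 6:
adding neurons does not degrade, and here improves, the code.
Unsupervised specialization is demonstrated at 2 clusters / 2 neurons
(≈100 % of seeds with `η = 0.02`, `ν = 0.01`, 40 epochs).

These sizes — 10⁵-step streams, 50-seed XOR batteries, 20-seed cluster
batteries — keep any single check in the seconds-to-a-minute range on a
single CPU while leaving the statistical margins wide.

## Known limitations

* **Unsupervised k-way partitioning for k ≥ 3 is unreliable.**  With
  3 clusters and 3 neurons, unsupervised training settles at ≈0.65
  consistency (two specialists; the third neuron stays flat) across wide
  grids of `η`, `ν`, gain, slope, normalization set point and learning-
  signal variants.  The mechanism is instructive: intrinsic plasticity
  pins each neuron's threshold near its own mean drive, so competition
  runs on *contrast*; the loser-decay that creates contrast also
  flattens idle neurons, and an entrenched winner keeps a protective
  excitation margin sustained by the inhibition-driven oscillation of
  the reset-to-silence dynamics.  Escaping this would need an ingredient
  beyond the implemented mechanisms (e.g. a conscience bias or
  per-neuron learning-rate annealing), which we deliberately do not add.
* Spike timing, refractory periods and membrane dynamics are out of
  scope; the model is rate-coding throughout.
* The printed single-run trained thresholds of the original XOR network
  (`T₀ = 0.15`, `T₁ = 0.05`) are not reproduction targets: they come
  from an unspecified protocol, and many parameter sets solve the task.
  The package reproduces the *capability* and the worked winner
  comparison (excitations 0.13 vs 0.07 → neuron 0), not those point
  values.
* Supervised training's stochastic-search character means wall-clock
  time per seed is heavy-tailed; the epoch caps bound it.
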