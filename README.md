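# koniolearn

Competitive rate-coding neural networks with biologically inspired
plasticity: homeostatic **intrinsic plasticity**, the probabilistic
**presynaptic learning rule**, frequency-dependent **metaplasticity**, and
**lateral-inhibition winner-take-all** dynamics — assembled into a
*Competitive Perceptron* (a single-layer network that, unlike a classical
perceptron, can learn XOR) and a simplified *koniocortex-like network*.

## Who this is for

Computational-neuroscience and bio-inspired-ML practitioners who want a
small, deterministic, fully tested reference implementation of these
mechanisms — each usable on its own (a neuron model, a learning rule, a
rate modulator, a competitive layer) or as the assembled networks.

## The model

Each neuron `j` is a rate-coding unit with a shifted steep sigmoid
activation

    O_j = 1 / (1 + exp(-k (net_j + 0.5 - 2 s_j))),      net_j = Σ_i w_ij x_i,

whose firing threshold is `T_j = 2 s_j - 0.5`.  Three plasticity
mechanisms act on it:

* **Intrinsic plasticity** — the shift follows recent activity,
  `s(t) = (ν O + s(t-1)) / (1 + ν)`: active neurons raise their threshold,
  silent neurons lower it, which stabilizes the layer and equalizes win
  rates.
* **Presynaptic rule** — `Δw = η I (O - w)` with `I`, `O` the pre- and
  postsynaptic firing probabilities.  Its fixed point is
  `w* = E[IO]/E[I] = P(O fires | I fired)`: each weight is a conditional
  probability estimate, and updates shrink as the weight adapts
  (a metaplasticity property).
* **Artificial metaplasticity (AMP)** — a variable learning rate
  `η_eff = clip(η₀ p̄ / (ε + p̂(x)), η₀ c_min, η₀ c_max)` that makes the
  network learn more from infrequent patterns; with uniform data it
  reduces exactly to the base rate.

A **competitive layer** wires such neurons with fixed-gain lateral
inhibition (inhibitory synapses are non-modifiable) and optional autapses
(recurrent self-excitation).  An input is classified by *settling*: the
layer starts from silence and iterates synchronously until one neuron
fires and the rest are suppressed; the winner is the neuron with the
largest excitation `net_j - T_j`.  The **Competitive Perceptron** adds a
complement-coding + divisive-normalization front end; the **KLN** instead
feeds inputs through adaptive thalamocortical (TC) relay neurons and a
shunting (divisive) basket stage.

Because settling is recurrent and the steep sigmoid makes each step a
near-binary decision, the frozen network computes more than a linear
threshold: a trained 2-neuron CP classifies all four XOR patterns, which
is impossible for any single-step linear WTA readout (the package tests
both halves of that claim).

## Worked example

```sh
python examples/xor_demo.py
```

```
training stopped at epoch 6184
thresholds T = [0.444 0.422]

x1 x2 | class  winner  excitations (net - T)
0  0  |   0      0     [-0.551 -0.562]  ok
0  1  |   1      1     [-0.624 -0.386]  ok
1  0  |   1      1     [-0.518 -0.513]  ok
1  1  |   0      0     [-0.555 -0.556]  ok

accuracy: 4/4
```

The trained 2-neuron network settles on each XOR pattern and the more
excited neuron's class is read out: neuron 0 encodes {(0,0), (1,1)},
neuron 1 encodes {(0,1), (1,0)} — a nonlinearly separable partition
learned by a single layer.  The other scripts in `examples/` each
demonstrate one mechanism: `presynaptic_fixed_point.py` (a weight
converging to P(O|I) = 0.6), `intrinsic_plasticity_demo.py` (geometric
shift convergence), `metaplasticity_demo.py` (rare-pattern learning-rate
boost), `cluster_classification.py` (competitive classification and
quantization-error scalability) and `kln_demo.py` (the TC → shunting →
competition assembly).

There is also a thin CLI:

```sh
konio train --data xor.csv --mode supervised --neurons 2 --seed 7 --out run1/
konio predict --model run1/model.json --data xor.csv --out preds.csv
konio demo xor --seeds 10
```

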