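"""Homeostatic shift adaptation of a single neuron.

With constant output drive the activation-function shift converges
geometrically to the output level, with ratio 1/(1 + nu) per step.
"""

from koniolearn import NeuronState, threshold_of, update_shift

state = NeuronState(s=0.9, nu=0.5)
TARGET = 0.2  # constant low activity: the sigmoid should shift leftward

print("step   shift s    threshold T   |s - O| / prediction")
s0 = state.s
for t in range(1, 11):
    state = update_shift(state, TARGET)
    predicted = abs(s0 - TARGET) * (1 + state.nu) ** (-t)
    print(f"{t:4d}   {state.s:.5f}    {threshold_of(state):+.5f}      "
          f"{abs(state.s - TARGET):.6f} / {predicted:.6f}")

print("\nLow activity drags the shift (and hence the firing threshold) "
      "down until the neuron's activity matches its drive — the "
      "homeostatic mechanism that keeps silent neurons competitive.")
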