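"""The presynaptic rule estimates a conditional firing probability.

Drive a single synapse with a stationary stream of paired pre/post
activity and watch the weight converge to P(post fires | pre fired).
"""

from koniolearn import bernoulli_pair_stream, presynaptic_update

P_I, P_O_GIVEN_I = 0.8, 0.6
I, O = bernoulli_pair_stream(P_I, P_O_GIVEN_I, 0.1, 100_000, seed=1)

w, tail, count = 0.5, 0.0, 0
for t in range(I.size):
    w = presynaptic_update(w, I[t], O[t], eta=0.02)
    if t >= 80_000:
        tail += w
        count += 1

print(f"stream: P(I=1) = {P_I}, P(O=1 | I=1) = {P_O_GIVEN_I}")
print(f"long-run mean weight over the last 20k steps: {tail / count:.4f}")
print(f"analytic fixed point E[IO]/E[I] = {P_O_GIVEN_I:.4f}")
print("The weight fluctuates around the conditional probability: the "
      "synapse has learned how predictive its input is of the output.")
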