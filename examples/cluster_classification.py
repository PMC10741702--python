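"""Competitive classification of Gaussian clusters, and scalability.

Trains 3- and 6-neuron Competitive Perceptrons on three tight clusters
and compares accuracy and quantization error (distance from each pattern
to the prototype decoded from its winner's weight row).
"""

import numpy as np

from koniolearn import TrainConfig, gaussian_clusters, predict, train


def run(neurons, seed=0):
    ds = gaussian_clusters(3, 50, dim=2, spread=0.05, seed=seed)
    cfg = TrainConfig(neurons=neurons, seed=seed, mode="supervised",
                      epochs=200, early_stop=True, restart_stall=50)
    model, _ = train(ds, cfg)
    acc = np.mean([predict(model, x)[0] == y
                   for x, y in zip(ds.patterns, ds.labels)])
    W = model.layer.weights
    d = ds.patterns.shape[1]
    proto = W[:, :d] / (W[:, :d] + W[:, d:] + 1e-12)
    wins = np.array([predict(model, x)[1] for x in ds.patterns])
    qe = np.mean(np.linalg.norm(ds.patterns - proto[wins], axis=1))
    return acc, qe, proto


acc3, qe3, proto3 = run(3)
acc6, qe6, _ = run(6)
print(f"3 neurons: accuracy {acc3:.2f}, quantization error {qe3:.3f}")
print(f"6 neurons: accuracy {acc6:.2f}, quantization error {qe6:.3f}")
print(f"decoded 3-neuron prototypes:\n{np.round(proto3, 2)}")
print("Prototypes are decoded from complement-coded weight rows as "
      "w/(w + w_complement); extra neurons refine the code rather than "
      "degrade it.")
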