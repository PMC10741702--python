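"""Simplified koniocortex-like network on cluster data.

TC neurons adapt to per-channel mean activity, the shunting basket stage
divisively normalizes total drive, and the spiny-stellate layer competes
through lateral inhibition with autapses.
"""

import numpy as np

from koniolearn import (TrainConfig, gaussian_clusters, kln_predict,
                        kln_train)

ds = gaussian_clusters(3, 40, dim=3, spread=0.05, seed=0)
cfg = TrainConfig(neurons=3, seed=0, mode="supervised", epochs=500,
                  eta=0.1, nu=0.05, early_stop=True, restart_stall=100)
model, trace = kln_train(ds, cfg)

acc = np.mean([kln_predict(model, x)[0] == y
               for x, y in zip(ds.patterns, ds.labels)])
print(f"classification accuracy over {len(ds)} patterns: {acc:.2f}")
print(f"adapted TC shifts: {np.round(model.tc_shifts, 3)}")
print(f"S-layer thresholds: {np.round(model.layer.thresholds, 3)}")
print("TC shifts settle near each channel's mean drive; the S layer's "
      "winner-take-all competition assigns each cluster to one neuron.")
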