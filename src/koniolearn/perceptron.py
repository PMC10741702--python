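"""The Competitive Perceptron (CP).

A single-layer network of steep shifted-sigmoid neurons with normalized
inputs, lateral inhibition, autapses and intrinsic plasticity, trained by
the presynaptic rule.  Classification is winner-take-all: an input is
encoded, the layer settles from silence, and the neuron with the largest
final excitation ``net - T`` wins.

Input coding
------------
Raw patterns in ``[0, 1]^d`` are complement-coded (appending ``1 - x``) and
divisively normalized so every encoded pattern has unit total activity.
Complement coding keeps the all-zero pattern representable; divisive
normalization mirrors the shunting basket neuron of the koniocortex-like
network.

Training
--------
*Supervised* mode is winner-only competitive learning: after settling (with
intrinsic plasticity active), only the winning neuron updates, with the
postsynaptic term clamped to that neuron's one-hot target entry — weights
are reinforced toward 1 when the winner is the pattern's labelled class and
depressed toward 0 otherwise.  Errors on different patterns touch different
encoded components, which breaks the symmetry between neurons and lets the
recurrent settle dynamics carve the non-convex decision regions needed for
problems like XOR that no single-step linear readout can solve.

*Unsupervised* mode applies the presynaptic rule with the WTA-resolved
outputs (the winner's output is one, the inhibited rest are zero), so each
weight estimates the conditional probability of that neuron winning given
each input component — winners specialize, and the homeostatic shifts keep
losers competitive.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .datasets import Dataset, xor_dataset
from .errors import DimensionError, DomainError
from .layer import CompetitiveLayerState, settle
from .plasticity import AmpRateModel

__all__ = [
    "InputCoding",
    "TrainConfig",
    "CpModel",
    "TrainTrace",
    "encode",
    "train",
    "predict",
    "evaluate_xor",
    "xor_demo_config",
    "xor_ablation_config",
]


@dataclass(frozen=True)
class InputCoding:
    """Front-end normalization applied to every raw pattern.

    ``scale`` is the activity set point of the divisive normalization:
    encoded patterns sum to ``scale`` (a shunting normalization with a
    configurable gain).  The set point fixes how strongly a tuned neuron
    can be driven relative to the homeostatic floor of a silent one, so
    it trades winner stability against how easily an idle neuron can
    barge back into the competition.
    """

    complement: bool = True
    divisive: bool = True
    eps: float = 1e-6
    scale: float = 1.0

    def encoded_dim(self, raw_dim: int) -> int:
        return 2 * raw_dim if self.complement else raw_dim


def encode(coding: InputCoding, x) -> np.ndarray:
    """Complement-code and divisively normalize one raw pattern."""
    x = np.asarray(x, dtype=float).ravel()
    if np.any((x < 0) | (x > 1)) or not np.all(np.isfinite(x)):
        raise DomainError("raw input components must lie in [0, 1]")
    v = np.concatenate([x, 1.0 - x]) if coding.complement else x.copy()
    if coding.divisive:
        v = coding.scale * v / (v.sum() + coding.eps)
    return v


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one CP training run.

    The defaults are the configuration shipped for the XOR demonstration,
    found by a small grid search over ``eta``, ``nu`` and the epoch cap.
    ``seed`` is mandatory: every random draw in training flows from it.
    """

    neurons: int
    seed: int
    mode: str = "supervised"          # "supervised" | "unsupervised"
    eta: float = 0.025                # presynaptic learning rate
    nu: float = 0.08                  # intrinsic-plasticity velocity
    k: float = 500.0                  # sigmoid slope
    gain: float = 1.0                 # fixed lateral-inhibition gain
    theta_fire: float = 0.9
    epochs: int = 16000
    settle_max_steps: int = 25        # training settles (adapt on)
    eval_max_steps: int = 50          # frozen evaluation settles
    init_weight_low: float = 0.0
    init_weight_high: float = 0.1
    init_shift: float = 0.5
    autapses: bool = True
    complement: bool = True
    divisive: bool = True
    eps: float = 1e-6
    scale: float = 1.0
    amp: bool = False                 # frequency-modulated learning rate
    amp_floor: float = 1e-3
    amp_clip: tuple = (0.1, 10.0)
    amp_discrete: bool = True
    early_stop: bool = True           # stop when training accuracy hits 1
    adapt_in_training: bool = True    # intrinsic plasticity during settles
    restart_stall: int = 2500         # supervised: reinit after this many
                                      # epochs without accuracy improvement
                                      # (0 disables)

    def __post_init__(self):
        if self.neurons < 1:
            raise DomainError("neurons must be >= 1")
        if self.mode not in ("supervised", "unsupervised"):
            raise DomainError(f"unknown mode {self.mode!r}")
        if not (0.0 <= self.eta <= 1.0):
            raise DomainError("eta must lie in [0, 1]")
        if self.nu < 0:
            raise DomainError("nu must be >= 0")
        if self.epochs < 1:
            raise DomainError("epochs must be >= 1")
        if self.seed is None:
            raise DomainError("seed is mandatory")

    @property
    def coding(self) -> InputCoding:
        return InputCoding(self.complement, self.divisive, self.eps,
                           self.scale)

    def to_json(self) -> dict:
        obj = dataclasses.asdict(self)
        obj["amp_clip"] = list(self.amp_clip)
        return obj


@dataclass
class CpModel:
    """A trained Competitive Perceptron."""

    coding: InputCoding
    layer: CompetitiveLayerState
    class_map: dict
    mode: str
    raw_dim: int
    eval_max_steps: int = 50

    def copy(self) -> "CpModel":
        return CpModel(self.coding, self.layer.copy(), dict(self.class_map),
                       self.mode, self.raw_dim, self.eval_max_steps)


@dataclass
class TrainTrace:
    """Per-presentation winners plus per-epoch training accuracy."""

    winners: np.ndarray          # (presentations,) winner index
    pattern_index: np.ndarray    # (presentations,) which pattern was shown
    epoch: np.ndarray            # (presentations,)
    accuracy: list = field(default_factory=list)   # per checked epoch
    stopped_epoch: int = -1

    def to_csv(self) -> str:
        lines = ["presentation,epoch,pattern,winner"]
        for i in range(self.winners.size):
            lines.append(f"{i},{self.epoch[i]},{self.pattern_index[i]},"
                         f"{self.winners[i]}")
        return "\n".join(lines) + "\n"


def _init_layer(cfg: TrainConfig, enc_dim: int,
                rng: np.random.Generator) -> CompetitiveLayerState:
    W = rng.uniform(cfg.init_weight_low, cfg.init_weight_high,
                    (cfg.neurons, enc_dim))
    if cfg.autapses:
        a = rng.uniform(cfg.init_weight_low, cfg.init_weight_high,
                        cfg.neurons)
    else:
        a = np.zeros(cfg.neurons)
    return CompetitiveLayerState(
        weights=W, autapses=a, shifts=np.full(cfg.neurons, cfg.init_shift),
        gain=cfg.gain, k=cfg.k, nu=cfg.nu, theta_fire=cfg.theta_fire)


def _as_arrays(data):
    if isinstance(data, Dataset):
        return data.patterns, data.labels
    return np.atleast_2d(np.asarray(data, dtype=float)), None


def _frozen_winners(layer, encoded, max_steps):
    frozen = layer.copy()
    frozen.nu = 0.0
    return np.array([settle(frozen, e, max_steps=max_steps, adapt=False,
                            record=False).winner for e in encoded])


def train(data, cfg: TrainConfig, labels=None, warm_start: CpModel = None):
    """Train a CP on patterns (rows); returns ``(CpModel, TrainTrace)``.

    ``data`` may be a :class:`~koniolearn.datasets.Dataset` (labels taken
    from it) or a plain array with ``labels`` passed separately.  In
    supervised mode the label set must fit the neuron count (neuron ``j``
    is the prototype of class ``j``).  Passing ``warm_start`` continues
    from an existing model's layer instead of a fresh random one —
    continual learning on new data.
    """
    patterns, ds_labels = _as_arrays(data)
    if labels is None:
        labels = ds_labels
    n_pat = patterns.shape[0]
    if n_pat < 1:
        raise DomainError("training needs at least one pattern")
    supervised = cfg.mode == "supervised"
    if supervised:
        if labels is None:
            raise DomainError("supervised mode requires labels")
        labels = np.asarray(labels, dtype=int).ravel()
        if labels.min() < 0 or labels.max() >= cfg.neurons:
            raise DimensionError(
                f"labels span {labels.min()}..{labels.max()} but the layer "
                f"has {cfg.neurons} neurons")
    coding = cfg.coding
    encoded = np.array([encode(coding, x) for x in patterns])
    rng = np.random.default_rng(cfg.seed)
    if warm_start is not None:
        layer = warm_start.layer.copy()
        if layer.n_inputs != encoded.shape[1]:
            raise DimensionError("warm-start model input size mismatch")
    else:
        layer = _init_layer(cfg, encoded.shape[1], rng)

    rates = None
    if cfg.amp:
        rates = AmpRateModel(base_rate=cfg.eta, floor=cfg.amp_floor,
                             clip=cfg.amp_clip,
                             discrete=cfg.amp_discrete).fit(patterns)

    winners, pat_idx, epoch_idx, accs = [], [], [], []
    stopped = cfg.epochs - 1
    best_acc, last_improve = -1.0, 0
    W, a = layer.weights, layer.autapses
    for ep in range(cfg.epochs):
        for idx in rng.permutation(n_pat):
            e = encoded[idx]
            trace = settle(layer, e, max_steps=cfg.settle_max_steps,
                           adapt=cfg.adapt_in_training, record=False)
            out = trace.outputs[-1]
            win = trace.winner
            eta = rates.rate(patterns[idx]) if rates is not None else cfg.eta
            eta = min(eta, 1.0)
            if supervised:
                tgt = 1.0 if win == labels[idx] else 0.0
                W[win] += eta * e * (tgt - W[win])
                if cfg.autapses:
                    a[win] += eta * out[win] * (tgt - a[win])
            else:
                # WTA resolution: the winner's output is one, the others
                # are silenced by lateral inhibition, and those resolved
                # outputs are what the presynaptic rule sees
                resolved = np.zeros(cfg.neurons)
                resolved[win] = 1.0
                W += eta * e[None, :] * (resolved[:, None] - W)
                if cfg.autapses:
                    a += eta * resolved * (resolved - a)
            winners.append(win)
            pat_idx.append(idx)
            epoch_idx.append(ep)
        if supervised and cfg.early_stop:
            pred = _frozen_winners(layer, encoded, cfg.eval_max_steps)
            acc = float(np.mean(pred == labels))
            accs.append(acc)
            if acc == 1.0:
                stopped = ep
                break
            if acc > best_acc:
                best_acc, last_improve = acc, ep
            elif cfg.restart_stall and ep - last_improve >= cfg.restart_stall:
                # trapped in a non-solving attractor: reinitialize from the
                # same seeded stream and keep searching
                layer = _init_layer(cfg, encoded.shape[1], rng)
                W, a = layer.weights, layer.autapses
                best_acc, last_improve = -1.0, ep
    else:
        stopped = cfg.epochs - 1

    if supervised:
        class_map = {j: j for j in range(cfg.neurons)}
    else:
        pred = _frozen_winners(layer, encoded, cfg.eval_max_steps)
        class_map = {}
        for j in range(cfg.neurons):
            mask = pred == j
            if labels is not None and mask.any():
                vals, counts = np.unique(np.asarray(labels)[mask],
                                         return_counts=True)
                class_map[j] = int(vals[np.argmax(counts)])
            else:
                class_map[j] = j

    model = CpModel(coding=coding, layer=layer, class_map=class_map,
                    mode=cfg.mode, raw_dim=patterns.shape[1],
                    eval_max_steps=cfg.eval_max_steps)
    trace = TrainTrace(winners=np.array(winners, dtype=int),
                       pattern_index=np.array(pat_idx, dtype=int),
                       epoch=np.array(epoch_idx, dtype=int),
                       accuracy=accs, stopped_epoch=stopped)
    return model, trace


def predict(model: CpModel, x, record: bool = False):
    """Classify one raw pattern with frozen dynamics.

    Returns ``(class_label, winner_index, SettleTrace)``.  Shifts do not
    adapt during evaluation, so repeated calls are identical.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.shape != (model.raw_dim,):
        raise DimensionError(
            f"input length {x.size} != model raw dim {model.raw_dim}")
    e = encode(model.coding, x)
    frozen = model.layer.copy()
    frozen.nu = 0.0
    trace = settle(frozen, e, max_steps=model.eval_max_steps, adapt=False,
                   record=record)
    label = model.class_map.get(trace.winner, trace.winner)
    return label, trace.winner, trace


def xor_demo_config(seed: int, **overrides) -> TrainConfig:
    """The shipped 2-neuron XOR training configuration."""
    kwargs = dict(neurons=2, seed=seed, mode="supervised")
    kwargs.update(overrides)
    return TrainConfig(**kwargs)


def xor_ablation_config(seed: int) -> TrainConfig:
    """Linear control: no complement coding, no autapses, one settle step,
    frozen shifts.  A CP so ablated is a single-step linear WTA readout
    and provably cannot represent XOR."""
    return TrainConfig(neurons=2, seed=seed, mode="supervised", nu=0.0,
                       autapses=False, complement=False,
                       settle_max_steps=1, eval_max_steps=1,
                       adapt_in_training=False, epochs=200)


def evaluate_xor(cfg: TrainConfig = None, seed: int = 0) -> float:
    """Train a 2-neuron supervised CP on the XOR truth table.

    Returns the fraction of the four patterns classified correctly by the
    trained, frozen model (neuron 0 <-> class 0 = {(0,0), (1,1)}).
    """
    if cfg is None:
        cfg = xor_demo_config(seed)
    if cfg.neurons != 2 or cfg.mode != "supervised":
        raise DomainError("evaluate_xor expects a 2-neuron supervised config")
    ds = xor_dataset()
    model, _ = train(ds, cfg)
    hits = sum(predict(model, x)[0] == y
               for x, y in zip(ds.patterns, ds.labels))
    return hits / len(ds)
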