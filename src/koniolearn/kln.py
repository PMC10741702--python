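"""Simplified Koniocortex-Like Network (KLN).

A three-stage assembly inspired by the granular sensory cortex:

* **TC** thalamocortical relay neurons — one shifted-sigmoid neuron per
  input component.  Through intrinsic plasticity each TC shift tracks the
  long-run mean of its own output, so the TC stage adapts to (and thereby
  extracts) the mean component of the input stream.
* **SB** shunting basket neuron — sums all TC outputs and divides the
  drive of every downstream neuron by that total (divisive
  normalization), bounding responses and making them invariant to overall
  input intensity.
* **S** spiny stellate neurons — a competitive layer with autapses,
  lateral inhibition (the basket-cell inhibition is folded into the
  layer's fixed gain) and presynaptic-rule learning.

With the TC stage frozen to the identity and the shunting division
disabled, the assembly reduces exactly to a Competitive Perceptron
without input coding.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .datasets import Dataset
from .errors import DimensionError, DomainError
from .layer import CompetitiveLayerState, settle
from .neuron import _activate_arr, _shift_arr
from .perceptron import TrainConfig, TrainTrace, _init_layer, _as_arrays

__all__ = [
    "KlnModel",
    "tc_forward",
    "shunting_normalize",
    "kln_train",
    "kln_predict",
    "fig_preset",
]


@dataclass
class KlnModel:
    """TC preprocessing states plus the competitive S layer."""

    tc_shifts: np.ndarray
    layer: CompetitiveLayerState
    tc_k: float = 5.0
    tc_nu: float = 0.05
    sb_eps: float = 1e-6
    tc_identity: bool = False
    sb_identity: bool = False
    class_map: dict = None
    eval_max_steps: int = 50

    def __post_init__(self):
        self.tc_shifts = np.asarray(self.tc_shifts, dtype=float).ravel()
        if self.tc_shifts.size != self.layer.n_inputs:
            raise DimensionError("TC count must equal S-layer input count")
        if self.class_map is None:
            self.class_map = {j: j for j in range(self.layer.n_neurons)}

    @property
    def n_inputs(self) -> int:
        return self.tc_shifts.size

    def copy(self) -> "KlnModel":
        return replace(self, tc_shifts=self.tc_shifts.copy(),
                       layer=self.layer.copy(),
                       class_map=dict(self.class_map))


def tc_forward(model: KlnModel, x, adapt: bool = False) -> np.ndarray:
    """TC stage: per-component shifted sigmoid, optionally adapting.

    With ``tc_identity`` the stage passes the raw components through
    unchanged (used for the reduction to a plain competitive perceptron).
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.shape != (model.n_inputs,):
        raise DimensionError(
            f"input length {x.size} != TC count {model.n_inputs}")
    if model.tc_identity:
        return x.copy()
    out = _activate_arr(x, model.tc_shifts, model.tc_k)
    if adapt:
        model.tc_shifts = _shift_arr(model.tc_shifts, out, model.tc_nu)
    return out


def shunting_normalize(tc_out, weights_row, eps: float) -> float:
    """Divisively normalized net input for one S neuron.

    ``(sum_i w_i tc_i) / (sum_i tc_i + eps)`` — invariant under positive
    rescaling of TC activity (up to ``eps``) and bounded by ``max(w)``.
    """
    tc_out = np.asarray(tc_out, dtype=float).ravel()
    w = np.asarray(weights_row, dtype=float).ravel()
    if tc_out.shape != w.shape:
        raise DimensionError("tc_out and weights row must have equal length")
    if np.any(tc_out < 0):
        raise DomainError("TC outputs must be non-negative")
    return float((w @ tc_out) / (tc_out.sum() + eps))


def _sb_input(model: KlnModel, tc_out: np.ndarray) -> np.ndarray:
    """Shunting-normalized input vector fed to the S layer."""
    if model.sb_identity:
        return tc_out
    return tc_out / (tc_out.sum() + model.sb_eps)


def kln_train(data, cfg: TrainConfig, labels=None,
              tc_k: float = 5.0, tc_nu: float = 0.05,
              tc_identity: bool = False, sb_identity: bool = False):
    """Train a KLN; mirrors competitive-perceptron training.

    The TC stage adapts during training (unless ``tc_identity``); the
    presynaptic rule updates S excitatory and autapse weights only — the
    basket inhibition is a fixed, non-modifiable gain.
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
            raise DimensionError("labels do not fit the neuron count")

    rng = np.random.default_rng(cfg.seed)
    layer = _init_layer(cfg, patterns.shape[1], rng)
    model = KlnModel(
        tc_shifts=np.full(patterns.shape[1], cfg.init_shift), layer=layer,
        tc_k=tc_k, tc_nu=0.0 if tc_identity else tc_nu, sb_eps=cfg.eps,
        tc_identity=tc_identity, sb_identity=sb_identity,
        eval_max_steps=cfg.eval_max_steps)

    winners, pat_idx, epoch_idx = [], [], []
    W, a = layer.weights, layer.autapses
    best_acc, last_improve = -1.0, 0
    for ep in range(cfg.epochs):
        for idx in rng.permutation(n_pat):
            tc = tc_forward(model, patterns[idx],
                            adapt=cfg.adapt_in_training)
            e = _sb_input(model, tc)
            trace = settle(layer, e, max_steps=cfg.settle_max_steps,
                           adapt=cfg.adapt_in_training, record=False)
            out = trace.outputs[-1]
            win = trace.winner
            if supervised:
                tgt = 1.0 if win == labels[idx] else 0.0
                W[win] += cfg.eta * e * (tgt - W[win])
                if cfg.autapses:
                    a[win] += cfg.eta * out[win] * (tgt - a[win])
            else:
                # WTA-resolved outputs: winner 1, inhibited rest 0
                resolved = np.zeros(cfg.neurons)
                resolved[win] = 1.0
                W += cfg.eta * e[None, :] * (resolved[:, None] - W)
                if cfg.autapses:
                    a += cfg.eta * resolved * (resolved - a)
            winners.append(win)
            pat_idx.append(idx)
            epoch_idx.append(ep)
        if supervised and cfg.early_stop:
            pred = np.array([kln_predict(model, x)[1] for x in patterns])
            acc = float(np.mean(pred == labels))
            if acc == 1.0:
                break
            if acc > best_acc:
                best_acc, last_improve = acc, ep
            elif cfg.restart_stall and ep - last_improve >= cfg.restart_stall:
                layer = _init_layer(cfg, patterns.shape[1], rng)
                model.layer = layer
                W, a = layer.weights, layer.autapses
                best_acc, last_improve = -1.0, ep

    if supervised:
        model.class_map = {j: j for j in range(cfg.neurons)}
    else:
        pred = np.array([kln_predict(model, x)[1] for x in patterns])
        class_map = {}
        for j in range(cfg.neurons):
            mask = pred == j
            if labels is not None and mask.any():
                vals, counts = np.unique(np.asarray(labels)[mask],
                                         return_counts=True)
                class_map[j] = int(vals[np.argmax(counts)])
            else:
                class_map[j] = j
        model.class_map = class_map

    trace = TrainTrace(winners=np.array(winners, dtype=int),
                       pattern_index=np.array(pat_idx, dtype=int),
                       epoch=np.array(epoch_idx, dtype=int),
                       stopped_epoch=cfg.epochs - 1)
    return model, trace


def kln_predict(model: KlnModel, x):
    """Frozen evaluation; returns ``(class_label, winner, SettleTrace)``."""
    frozen = model.copy()
    tc = tc_forward(frozen, x, adapt=False)
    e = _sb_input(frozen, tc)
    frozen.layer.nu = 0.0
    trace = settle(frozen.layer, e, max_steps=model.eval_max_steps,
                   adapt=False, record=False)
    label = model.class_map.get(trace.winner, trace.winner)
    return label, trace.winner, trace


def fig_preset(seed: int, **overrides) -> TrainConfig:
    """Default-size preset: 15 input components, 10 S neurons."""
    kwargs = dict(neurons=10, seed=seed, mode="unsupervised", epochs=20,
                  early_stop=False)
    kwargs.update(overrides)
    return TrainConfig(**kwargs)
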