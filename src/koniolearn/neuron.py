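"""Shifted-sigmoid rate-coding neuron.

A neuron is described by the shift ``s`` of its activation function, a slope
factor ``k`` and a shift velocity ``nu``.  Its output is a firing
probability

.. math::

    O = \\frac{1}{1 + e^{-k\\,(\\mathrm{net} + 0.5 - 2s)}}

so the activation crosses one half exactly at the threshold
``T = 2 s - 0.5``.  Intrinsic plasticity moves the shift toward recent
activity,

.. math::

    s(t) = \\frac{\\nu\\, O + s(t-1)}{1 + \\nu},

a convex combination of the previous shift and the output: highly active
neurons shift rightward (raising their threshold), silent neurons shift
leftward.  This homeostasis is what lets a competitive layer self-organize
without any neuron saturating permanently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import DimensionError, DomainError

__all__ = [
    "NeuronState",
    "net_input",
    "activate",
    "threshold_of",
    "update_shift",
    "stable_sigmoid",
]


def stable_sigmoid(z):
    """Numerically stable logistic function, valid for huge ``|z|``.

    Branches on the argument sign so ``exp`` is only ever evaluated on
    non-positive values; with slope factors of several hundred the naive
    form overflows.
    """
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class NeuronState:
    """State of one rate-coding neuron.

    Parameters
    ----------
    s : float
        Activation-function shift, in ``[0, 1]``.  The derived firing
        threshold is ``T = 2 s - 0.5`` in ``[-0.5, 1.5]``.
    k : float
        Positive sigmoid slope (compression) factor.  Steep values
        (``k = 500``) make the output effectively binary.
    nu : float
        Non-negative shift velocity; ``nu = 0`` freezes intrinsic
        plasticity.
    last_output : float
        Most recent firing probability, in ``[0, 1]``.
    """

    s: float = 0.5
    k: float = 500.0
    nu: float = 0.0
    last_output: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.s <= 1.0):
            raise DomainError(f"shift s={self.s!r} outside [0, 1]")
        if not self.k > 0.0:
            raise DomainError(f"slope k={self.k!r} must be positive")
        if not self.nu >= 0.0:
            raise DomainError(f"velocity nu={self.nu!r} must be >= 0")
        if not (0.0 <= self.last_output <= 1.0):
            raise DomainError(
                f"last_output={self.last_output!r} outside [0, 1]")

    def to_json(self) -> dict:
        return {"s": self.s, "k": self.k, "nu": self.nu}

    @classmethod
    def from_json(cls, obj: dict) -> "NeuronState":
        return cls(s=obj["s"], k=obj["k"], nu=obj["nu"])


def net_input(weights, inputs) -> float:
    """Weighted sum of inputs, ``net = sum_i w_i x_i``.

    Both vectors must hold values in ``[0, 1]`` (efficacies and firing
    probabilities) and have the same length.
    """
    w = np.asarray(weights, dtype=float)
    x = np.asarray(inputs, dtype=float)
    if w.shape != x.shape or w.ndim != 1 or w.size < 1:
        raise DimensionError(
            f"weights {w.shape} and inputs {x.shape} must be equal-length "
            "1-d vectors")
    for name, v in (("weights", w), ("inputs", x)):
        if np.any((v < 0.0) | (v > 1.0)) or not np.all(np.isfinite(v)):
            raise DomainError(f"{name} components must lie in [0, 1]")
    return float(w @ x)


def activate(net: float, state: NeuronState) -> float:
    """Firing probability of a neuron for a given net input.

    Equals 0.5 exactly at ``net = T = 2 s - 0.5`` and is strictly
    increasing in ``net``.
    """
    if not math.isfinite(net):
        raise DomainError(f"net input {net!r} is not finite")
    return stable_sigmoid(state.k * (net + 0.5 - 2.0 * state.s))


def threshold_of(state: NeuronState) -> float:
    """Activation threshold ``T = 2 s - 0.5`` of a neuron."""
    return 2.0 * state.s - 0.5


def update_shift(state: NeuronState, output: float) -> NeuronState:
    """One intrinsic-plasticity step; returns the updated state.

    The new shift ``(nu * O + s) / (1 + nu)`` is a convex combination of
    the current shift and the output, so it can never leave ``[0, 1]``;
    with constant output the shift converges geometrically to it with
    ratio ``1 / (1 + nu)``.
    """
    if not (0.0 <= output <= 1.0):
        raise DomainError(f"output {output!r} outside [0, 1]")
    new_s = (state.nu * output + state.s) / (1.0 + state.nu)
    return replace(state, s=new_s, last_output=output)


# --- array kernels used by the layer dynamics -------------------------------
# These operate on plain float arrays (one entry per neuron) and skip
# per-call validation; the layer owns the invariants.

def _activate_arr(nets: np.ndarray, s: np.ndarray, k: float) -> np.ndarray:
    z = k * (nets + 0.5 - 2.0 * s)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _shift_arr(s: np.ndarray, out: np.ndarray, nu: float) -> np.ndarray:
    return (nu * out + s) / (1.0 + nu)
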