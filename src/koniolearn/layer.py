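"""Competitive layer: lateral inhibition, autapses, settling dynamics.

Each neuron receives the weighted input plus a recurrent excitatory autapse
from itself, minus a fixed-gain inhibition from every other neuron:

    net_j = sum_i w_ji x_i + a_j O_j(t-1) - g * sum_{m != j} O_m(t-1)

Updates are synchronous: all nets at step ``t`` use the outputs of step
``t - 1``, which makes the dynamics independent of neuron ordering.  A
settle run starts from silence (all previous outputs zero) and iterates
until a single neuron fires (output above ``theta_fire`` while all others
are below ``1 - theta_fire``), the outputs stagnate, or a step budget runs
out.  The winner is read from the final step as the neuron with the
largest excitation ``net_j - T_j``; with steep sigmoids the outputs
themselves are numerically saturated, so comparing excitations is the
meaningful readout.

The inhibition gain is fixed (inhibitory synapses are non-modifiable);
only excitatory and autapse weights learn.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .errors import DimensionError, DomainError
from .neuron import NeuronState, _activate_arr, _shift_arr

__all__ = [
    "CompetitiveLayerState",
    "SettleTrace",
    "layer_step",
    "settle",
    "wta_winner",
]

_STAGNATION_TOL = 1e-9


@dataclass
class CompetitiveLayerState:
    """Weights and neuron states of one competitive layer.

    ``weights`` is (neurons x inputs) with entries in [0, 1];
    ``autapses`` one non-negative self-excitation weight per neuron;
    ``gain`` the fixed lateral-inhibition strength; ``shifts`` the
    per-neuron activation-function shifts.  ``k`` and ``nu`` are shared
    by all neurons of the layer, matching a homogeneous population.
    """

    weights: np.ndarray
    autapses: np.ndarray
    shifts: np.ndarray
    gain: float = 1.0
    k: float = 500.0
    nu: float = 0.0
    theta_fire: float = 0.9
    last_outputs: np.ndarray = None

    def __post_init__(self):
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=float))
        self.autapses = np.asarray(self.autapses, dtype=float).ravel()
        self.shifts = np.asarray(self.shifts, dtype=float).ravel()
        n = self.weights.shape[0]
        if self.autapses.shape != (n,) or self.shifts.shape != (n,):
            raise DimensionError(
                "weights, autapses and shifts disagree on neuron count")
        if np.any((self.weights < 0) | (self.weights > 1)):
            raise DomainError("excitatory weights must lie in [0, 1]")
        if np.any((self.autapses < 0) | (self.autapses > 1)):
            raise DomainError("autapse weights must lie in [0, 1]")
        if np.any((self.shifts < 0) | (self.shifts > 1)):
            raise DomainError("shifts must lie in [0, 1]")
        if not (self.gain >= 0 and self.k > 0 and self.nu >= 0):
            raise DomainError("gain >= 0, k > 0 and nu >= 0 required")
        if not (0.5 < self.theta_fire < 1.0):
            raise DomainError("theta_fire must lie in (0.5, 1)")
        if self.last_outputs is None:
            self.last_outputs = np.zeros(n)
        else:
            self.last_outputs = np.asarray(self.last_outputs,
                                           dtype=float).ravel()

    @property
    def n_neurons(self) -> int:
        return self.weights.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.weights.shape[1]

    @property
    def thresholds(self) -> np.ndarray:
        """Per-neuron activation thresholds ``T = 2 s - 0.5``."""
        return 2.0 * self.shifts - 0.5

    @property
    def neurons(self) -> list:
        """Per-neuron states as :class:`~koniolearn.neuron.NeuronState`."""
        return [NeuronState(s=float(s), k=self.k, nu=self.nu,
                            last_output=float(o))
                for s, o in zip(self.shifts, self.last_outputs)]

    def copy(self) -> "CompetitiveLayerState":
        return replace(self, weights=self.weights.copy(),
                       autapses=self.autapses.copy(),
                       shifts=self.shifts.copy(),
                       last_outputs=self.last_outputs.copy())


@dataclass
class SettleTrace:
    """Step-by-step record of one settle run."""

    nets: np.ndarray       # (steps, neurons)
    outputs: np.ndarray    # (steps, neurons)
    shifts: np.ndarray     # (steps, neurons)
    winner: int
    steps: int             # recorded rows; == total_steps when recording
    converged: str         # "fired" | "stagnated" | "max_steps"
    total_steps: int = 0

    def to_csv(self) -> str:
        """Long-format CSV: one row per (step, neuron)."""
        buf = io.StringIO()
        buf.write("step,neuron,net,output,shift\n")
        for t in range(self.steps):
            for j in range(self.nets.shape[1]):
                buf.write(f"{t},{j},{self.nets[t, j]!r},"
                          f"{self.outputs[t, j]!r},{self.shifts[t, j]!r}\n")
        return buf.getvalue()


def wta_winner(nets, thresholds) -> int:
    """Index of the most excited neuron, by ``net_j - T_j``.

    Ties break to the lowest index (argmax convention), which keeps the
    readout deterministic.
    """
    nets = np.asarray(nets, dtype=float).ravel()
    thr = np.asarray(thresholds, dtype=float).ravel()
    if nets.size == 0:
        raise DomainError("wta_winner needs at least one neuron")
    if nets.shape != thr.shape:
        raise DimensionError("nets and thresholds must have equal length")
    return int(np.argmax(nets - thr))


def _net(layer: CompetitiveLayerState, x: np.ndarray,
         prev_out: np.ndarray) -> np.ndarray:
    ff = layer.weights @ x
    inhibition = layer.gain * (prev_out.sum() - prev_out)
    return ff + layer.autapses * prev_out - inhibition


def layer_step(layer: CompetitiveLayerState, x, prev_out, adapt: bool):
    """One synchronous update; returns ``(outputs, new_layer)``.

    The input ``x`` and ``prev_out`` must match the layer dimensions.  If
    ``adapt`` is set, every shift takes one intrinsic-plasticity step
    toward the output just produced.
    """
    x = np.asarray(x, dtype=float).ravel()
    prev_out = np.asarray(prev_out, dtype=float).ravel()
    if x.shape != (layer.n_inputs,):
        raise DimensionError(
            f"input length {x.size} != layer inputs {layer.n_inputs}")
    if prev_out.shape != (layer.n_neurons,):
        raise DimensionError(
            f"prev_out length {prev_out.size} != neurons {layer.n_neurons}")
    new = layer.copy()
    nets = _net(new, x, prev_out)
    out = _activate_arr(nets, new.shifts, new.k)
    if adapt:
        new.shifts = _shift_arr(new.shifts, out, new.nu)
    new.last_outputs = out
    return out, new


@njit(cache=True)
def _settle_kernel(ff, autapses, gain, shifts, k, nu, theta, adapt,
                   max_steps, record):
    """Hot inner loop of :func:`settle`; see there for semantics."""
    n = ff.shape[0]
    rows = max_steps if record else 1
    hist_net = np.zeros((rows, n))
    hist_out = np.zeros((rows, n))
    hist_s = np.zeros((rows, n))
    prev = np.zeros(n)
    nets = np.zeros(n)
    out = np.zeros(n)
    s = shifts.copy()
    code = 2  # max_steps
    steps = 0
    for t in range(max_steps):
        total = 0.0
        for j in range(n):
            total += prev[j]
        for j in range(n):
            nets[j] = ff[j] + autapses[j] * prev[j] - gain * (total - prev[j])
            z = k * (nets[j] + 0.5 - 2.0 * s[j])
            if z >= 0.0:
                out[j] = 1.0 / (1.0 + np.exp(-z))
            else:
                ez = np.exp(z)
                out[j] = ez / (1.0 + ez)
        if adapt:
            for j in range(n):
                s[j] = (nu * out[j] + s[j]) / (1.0 + nu)
        if record:
            for j in range(n):
                hist_net[t, j] = nets[j]
                hist_out[t, j] = out[j]
                hist_s[t, j] = s[j]
        steps = t + 1
        n_fire = 0
        quiet = True
        for j in range(n):
            if out[j] >= theta:
                n_fire += 1
            elif out[j] > 1.0 - theta:
                quiet = False
        delta = 0.0
        for j in range(n):
            d = abs(out[j] - prev[j])
            if d > delta:
                delta = d
            prev[j] = out[j]
        if adapt:
            # shifts still moving counts as state change: the silent
            # phase before homeostasis brings a neuron to threshold must
            # not be mistaken for convergence
            for j in range(n):
                d = abs(nu * (out[j] - s[j]) / (1.0 + nu))
                if d > delta:
                    delta = d
        if n_fire == 1 and quiet:
            code = 0  # fired
            break
        if delta < _STAGNATION_TOL:
            code = 1  # stagnated
            break
    if not record:
        for j in range(n):
            hist_net[0, j] = nets[j]
            hist_out[0, j] = out[j]
            hist_s[0, j] = s[j]
    return hist_net, hist_out, hist_s, nets, out, s, steps, code


_CONVERGED = ("fired", "stagnated", "max_steps")


def settle(layer: CompetitiveLayerState, x, max_steps: int = 50,
           adapt: bool = False, record: bool = True) -> SettleTrace:
    """Iterate the layer from silence until a winner emerges.

    Mutates ``layer`` shifts in place when ``adapt`` is True (training);
    with ``adapt`` False the layer is left untouched and the run is a pure
    frozen evaluation.  Set ``record=False`` to skip per-step history in
    hot loops (the trace then holds only the final step).
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.shape != (layer.n_inputs,):
        raise DimensionError(
            f"input length {x.size} != layer inputs {layer.n_inputs}")
    if max_steps < 1:
        raise DomainError("max_steps must be >= 1")
    ff = layer.weights @ x
    hist_net, hist_out, hist_s, nets, out, shifts, steps, code = (
        _settle_kernel(ff, layer.autapses, layer.gain, layer.shifts,
                       layer.k, layer.nu, layer.theta_fire, adapt,
                       max_steps, record))
    thresholds = 2.0 * shifts - 0.5
    winner = wta_winner(nets, thresholds)
    if adapt:
        layer.shifts = shifts
        layer.last_outputs = out.copy()
    steps_rec = steps if record else 1
    return SettleTrace(
        nets=hist_net[:steps_rec], outputs=hist_out[:steps_rec],
        shifts=hist_s[:steps_rec], winner=winner, steps=steps_rec,
        converged=_CONVERGED[code], total_steps=steps)
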