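"""Synaptic learning rules.

Two mechanisms live here.

*Presynaptic rule.*  The incremental, probabilistic form of Grossberg's
presynaptic learning rule,

.. math::

    \\Delta w = \\eta\\, I\\, (O - w),

where ``I`` and ``O`` are pre- and postsynaptic firing probabilities.  The
expected update vanishes exactly when ``w = E[I O] / E[I]``, so a weight
trained on a stationary stream of activity converges to the conditional
probability that the postsynaptic neuron fires given that the presynaptic
neuron fired.  The update magnitude shrinks as ``w`` approaches ``O`` —
already-adapted synapses change less, a metaplasticity property.

*Artificial metaplasticity (AMP).*  A variable learning rate that makes the
network learn more from infrequent patterns.  :class:`AmpRateModel`
estimates the probability of each training pattern (an exact histogram for
discrete data, a product-Gaussian kernel density for continuous data) and
emits

.. math::

    \\eta_{\\mathrm{eff}} = \\mathrm{clip}\\!\\left(
        \\eta_0 \\, \\frac{\\bar p}{\\varepsilon + \\hat p(x)},\\;
        \\eta_0 c_{\\min},\\; \\eta_0 c_{\\max}\\right),

non-increasing in the estimated pattern probability and equal to the base
rate when all patterns are equally likely.  :class:`AmpMlp` is a minimal
logistic multilayer perceptron used to demonstrate AMP-modulated gradient
descent on the mean square error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde

from .errors import DimensionError, DomainError, NotFittedError

__all__ = [
    "presynaptic_update",
    "AmpRateModel",
    "amp_rate",
    "AmpMlp",
    "amp_backprop_step",
    "backprop_step",
]


def presynaptic_update(w, I, O, eta):
    """Apply ``w' = w + eta * I * (O - w)`` elementwise.

    All four arguments must lie in ``[0, 1]`` (scalars or broadcastable
    arrays); the result then provably stays in ``[0, 1]`` since
    ``w' = w (1 - eta I) + eta I O`` is a convex combination.
    """
    w = np.asarray(w, dtype=float)
    I = np.asarray(I, dtype=float)
    O = np.asarray(O, dtype=float)
    eta = np.asarray(eta, dtype=float)
    for name, v in (("w", w), ("I", I), ("O", O), ("eta", eta)):
        if np.any((v < 0.0) | (v > 1.0)) or not np.all(np.isfinite(v)):
            raise DomainError(f"{name} must lie in [0, 1]")
    out = w + eta * I * (O - w)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class AmpRateModel:
    """Pattern-frequency-modulated learning rate.

    Parameters
    ----------
    base_rate : float
        The unmodulated rate ``eta_0`` in ``(0, 1]``.
    floor : float
        Small positive ``epsilon`` guarding the division.
    clip : tuple of float
        ``(c_min, c_max)`` multipliers bounding the emitted rate to
        ``[eta_0 * c_min, eta_0 * c_max]``.
    discrete : bool
        Exact histogram over patterns when True, product-Gaussian kernel
        density (Silverman bandwidth) when False.
    """

    base_rate: float = 0.1
    floor: float = 1e-3
    clip: tuple = (0.1, 10.0)
    discrete: bool = True
    _hist: dict = field(default=None, repr=False)
    _kde: object = field(default=None, repr=False)
    _mean_p: float = field(default=None, repr=False)

    def __post_init__(self):
        if not (0.0 < self.base_rate <= 1.0):
            raise DomainError("base_rate must be in (0, 1]")
        if not self.floor > 0.0:
            raise DomainError("floor must be positive")
        c_min, c_max = self.clip
        if not (0.0 <= c_min <= c_max):
            raise DomainError("clip bounds must satisfy 0 <= c_min <= c_max")

    @property
    def fitted(self) -> bool:
        return self._mean_p is not None

    def fit(self, patterns) -> "AmpRateModel":
        """Estimate pattern probabilities from training patterns (rows)."""
        X = np.atleast_2d(np.asarray(patterns, dtype=float))
        if X.shape[0] < 1:
            raise DomainError("need at least one pattern to fit")
        if self.discrete:
            keys = [tuple(row) for row in X]
            counts = {}
            for key in keys:
                counts[key] = counts.get(key, 0) + 1
            n = len(keys)
            self._hist = {key: c / n for key, c in counts.items()}
            probs = np.array([self._hist[key] for key in keys])
        else:
            # scipy's gaussian_kde needs variability in every dimension;
            # degenerate (constant) columns are dropped from the estimate.
            live = X.std(axis=0) > 0
            if not live.any():
                self._kde = None
                probs = np.ones(X.shape[0])
            else:
                self._kde = (live, gaussian_kde(X[:, live].T,
                                                bw_method="silverman"))
                probs = self._kde[1](X[:, live].T)
        self._mean_p = float(np.mean(probs))
        return self

    def _p_hat(self, pattern) -> float:
        x = np.asarray(pattern, dtype=float).ravel()
        if self.discrete:
            return float(self._hist.get(tuple(x), 0.0))
        if self._kde is None:
            return 1.0
        live, kde = self._kde
        return float(kde(x[live][:, None])[0])

    def rate(self, pattern) -> float:
        """Effective learning rate for one pattern; see module docstring."""
        if not self.fitted:
            raise NotFittedError("AmpRateModel.rate called before fit")
        raw = self.base_rate * self._mean_p / (self.floor + self._p_hat(pattern))
        c_min, c_max = self.clip
        return float(np.clip(raw, self.base_rate * c_min,
                             self.base_rate * c_max))

    def to_json(self) -> dict:
        obj = {
            "base_rate": self.base_rate,
            "floor": self.floor,
            "clip": list(self.clip),
            "discrete": self.discrete,
            "mean_p": self._mean_p,
        }
        if self.discrete and self._hist is not None:
            obj["histogram"] = [[list(k), v] for k, v in
                                sorted(self._hist.items())]
        return obj


def amp_rate(model: AmpRateModel, pattern) -> float:
    """Functional alias for :meth:`AmpRateModel.rate`."""
    return model.rate(pattern)


class AmpMlp:
    """Minimal logistic MLP trained by (AMP-modulated) gradient descent.

    Weights are conventional unbounded reals; every layer applies a
    logistic activation so outputs live in ``[0, 1]``.  The loss is the
    mean square error over the output units.
    """

    def __init__(self, layer_sizes, seed: int, scale: float = 0.5):
        if len(layer_sizes) < 2:
            raise DimensionError("need at least input and output layers")
        rng = np.random.default_rng(seed)
        self.layer_sizes = list(layer_sizes)
        self.weights = [rng.uniform(-scale, scale, (n_out, n_in))
                        for n_in, n_out in zip(layer_sizes, layer_sizes[1:])]
        self.biases = [rng.uniform(-scale, scale, n_out)
                       for n_out in layer_sizes[1:]]

    def forward(self, x):
        a = np.asarray(x, dtype=float)
        if a.shape != (self.layer_sizes[0],):
            raise DimensionError(
                f"input shape {a.shape} != ({self.layer_sizes[0]},)")
        for W, b in zip(self.weights, self.biases):
            z = W @ a + b
            a = 1.0 / (1.0 + np.exp(-z))
        return a

    def gradients(self, x, target):
        """Backpropagated MSE gradients, ``E = mean((y - t)^2)``."""
        t = np.asarray(target, dtype=float)
        if t.shape != (self.layer_sizes[-1],):
            raise DimensionError(
                f"target shape {t.shape} != ({self.layer_sizes[-1]},)")
        activations = [np.asarray(x, dtype=float)]
        for W, b in zip(self.weights, self.biases):
            z = W @ activations[-1] + b
            activations.append(1.0 / (1.0 + np.exp(-z)))
        y = activations[-1]
        delta = (2.0 / y.size) * (y - t) * y * (1.0 - y)
        gW, gb = [], []
        for layer in range(len(self.weights) - 1, -1, -1):
            gW.append(np.outer(delta, activations[layer]))
            gb.append(delta.copy())
            if layer > 0:
                a = activations[layer]
                delta = (self.weights[layer].T @ delta) * a * (1.0 - a)
        gW.reverse()
        gb.reverse()
        return gW, gb

    def copy(self) -> "AmpMlp":
        dup = AmpMlp.__new__(AmpMlp)
        dup.layer_sizes = list(self.layer_sizes)
        dup.weights = [W.copy() for W in self.weights]
        dup.biases = [b.copy() for b in self.biases]
        return dup


def backprop_step(model: AmpMlp, pattern, target, eta: float) -> AmpMlp:
    """Plain gradient-descent step at constant rate ``eta``."""
    gW, gb = model.gradients(pattern, target)
    out = model.copy()
    for W, b, dW, db in zip(out.weights, out.biases, gW, gb):
        W -= eta * dW
        b -= eta * db
    return out


def amp_backprop_step(model: AmpMlp, pattern, target,
                      rates: AmpRateModel) -> AmpMlp:
    """Gradient step with the rate modulated once per pattern presentation.

    With a degenerate rate model (``c_min = c_max = 1``) the step is
    bit-identical to :func:`backprop_step` at the base rate.
    """
    return backprop_step(model, pattern, target, rates.rate(pattern))
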