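"""Seeded synthetic data generators.

Everything the test suite and the examples consume is generated here:
the XOR truth table, correlated Bernoulli firing streams, Gaussian cluster
sets and frequency-skewed pattern draws.  All generators are deterministic
given their seed, and every :class:`Dataset` round-trips through the
package CSV dialect bit-exactly (floats written with ``repr``).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .errors import DimensionError, DomainError

__all__ = [
    "Dataset",
    "xor_dataset",
    "bernoulli_pair_stream",
    "gaussian_clusters",
    "skewed_frequency_dataset",
]


@dataclass
class Dataset:
    """Patterns in ``[0, 1]`` with optional integer labels and metadata."""

    patterns: np.ndarray
    labels: np.ndarray = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.patterns = np.atleast_2d(np.asarray(self.patterns, dtype=float))
        if np.any((self.patterns < 0) | (self.patterns > 1)):
            raise DomainError("patterns must lie in [0, 1]")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int).ravel()
            if self.labels.size != self.patterns.shape[0]:
                raise DimensionError("labels length must match pattern count")

    def __len__(self) -> int:
        return self.patterns.shape[0]

    def to_csv(self) -> str:
        dim = self.patterns.shape[1]
        cols = [f"x{i}" for i in range(dim)]
        if self.labels is not None:
            cols.append("label")
        buf = io.StringIO()
        buf.write(",".join(cols) + "\n")
        for i in range(len(self)):
            row = [repr(float(v)) for v in self.patterns[i]]
            if self.labels is not None:
                row.append(str(int(self.labels[i])))
            buf.write(",".join(row) + "\n")
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str) -> "Dataset":
        lines = [ln for ln in text.strip().splitlines() if ln]
        header = lines[0].split(",")
        has_label = header[-1] == "label"
        n_feat = len(header) - (1 if has_label else 0)
        patterns, labels = [], []
        for ln in lines[1:]:
            parts = ln.split(",")
            if len(parts) != len(header):
                raise DomainError(f"malformed CSV row: {ln!r}")
            patterns.append([float(v) for v in parts[:n_feat]])
            if has_label:
                labels.append(int(parts[-1]))
        return cls(patterns=np.array(patterns, dtype=float),
                   labels=np.array(labels, dtype=int) if has_label else None)


def xor_dataset() -> Dataset:
    """The four XOR patterns with labels ``x1 XOR x2``."""
    patterns = np.array([[0., 0.], [0., 1.], [1., 0.], [1., 1.]])
    labels = np.array([0, 1, 1, 0])
    return Dataset(patterns, labels, meta={"generator": "xor"})


def bernoulli_pair_stream(p_i: float, p_o_given_i1: float,
                          p_o_given_i0: float, n: int, seed: int):
    """Paired binary streams ``(I, O)`` with a prescribed joint law.

    Draws ``I ~ Bernoulli(p_i)`` and ``O | I`` with the stated
    conditionals; returns two length-``n`` 0/1 float arrays.  This is the
    stationary firing stream on which the presynaptic rule's weight
    converges to ``P(O = 1 | I = 1)``.
    """
    for name, p in (("p_i", p_i), ("p_o_given_i1", p_o_given_i1),
                    ("p_o_given_i0", p_o_given_i0)):
        if not (0.0 <= p <= 1.0):
            raise DomainError(f"{name}={p!r} outside [0, 1]")
    if n < 1:
        raise DomainError("n must be >= 1")
    rng = np.random.default_rng(seed)
    I = (rng.random(n) < p_i).astype(float)
    u = rng.random(n)
    O = np.where(I == 1.0, u < p_o_given_i1, u < p_o_given_i0).astype(float)
    return I, O


def _cluster_means(k: int, dim: int) -> np.ndarray:
    """Deterministic, well-spread cluster centers inside [0.2, 0.8]^dim.

    The first ``2^dim`` centers are hypercube corners of {0.2, 0.8}^dim in
    binary-counting order; further centers fall back to an evenly spaced
    diagonal grid.  Deterministic in (k, dim) so tests are stable.
    """
    means = []
    for i in range(min(k, 2 ** dim)):
        bits = [(i >> b) & 1 for b in range(dim)]
        means.append([0.2 + 0.6 * bit for bit in bits])
    extra = k - len(means)
    for i in range(extra):
        t = (i + 1) / (extra + 1)
        means.append([0.2 + 0.6 * t] * dim)
    return np.array(means, dtype=float)


def gaussian_clusters(k: int, n_per: int, dim: int = 2, spread: float = 0.05,
                      seed: int = 0) -> Dataset:
    """``k`` isotropic Gaussian clusters clipped to the unit box."""
    if k < 1 or n_per < 1 or dim < 1:
        raise DomainError("k, n_per and dim must be >= 1")
    if spread < 0:
        raise DomainError("spread must be >= 0")
    rng = np.random.default_rng(seed)
    means = _cluster_means(k, dim)
    patterns = np.empty((k * n_per, dim))
    labels = np.empty(k * n_per, dtype=int)
    for c in range(k):
        block = slice(c * n_per, (c + 1) * n_per)
        patterns[block] = means[c] + spread * rng.standard_normal((n_per, dim))
        labels[block] = c
    np.clip(patterns, 0.0, 1.0, out=patterns)
    return Dataset(patterns, labels,
                   meta={"generator": "gaussian_clusters", "k": k,
                         "n_per": n_per, "dim": dim, "spread": spread,
                         "seed": seed})


def skewed_frequency_dataset(patterns, freqs, n: int, seed: int) -> Dataset:
    """``n`` draws of the given prototype patterns with given frequencies."""
    patterns = np.atleast_2d(np.asarray(patterns, dtype=float))
    freqs = np.asarray(freqs, dtype=float).ravel()
    if freqs.size != patterns.shape[0]:
        raise DimensionError("freqs length must match pattern count")
    if abs(freqs.sum() - 1.0) > 1e-12 or np.any(freqs < 0):
        raise DomainError("freqs must be non-negative and sum to 1")
    if n < 1:
        raise DomainError("n must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.choice(patterns.shape[0], size=n, p=freqs)
    return Dataset(patterns[idx], idx.astype(int),
                   meta={"generator": "skewed_frequency", "seed": seed})
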