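"""Kohonen self-organizing map: lattice, annealing schedule, training, activation.

A SOM is a rectangular 2D grid of neurons, each carrying a prototype weight
vector in data space. Training is competitive: for each presented sample the
closest prototype (the best-matching unit, BMU) and its lattice neighbours are
pulled toward the sample, with a learning rate ``eps(t)`` and a Gaussian
neighbourhood width ``sigma(t)`` that both decay geometrically over the run.

After training, a map responds to an input ``v`` with per-neuron activations

    a_n = exp(-||v - w_n|| / alpha)

whose maximum (attained at the BMU) is the scalar map activation used by the
Hebbian cross-modal machinery in :mod:`resom.hebbian`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AnnealSchedule",
    "ActivationParams",
    "SomGrid",
    "epsilon_at",
    "sigma_at",
    "find_bmu",
    "neighborhood",
    "som_step",
    "train_som",
    "activations",
    "quantization_error",
]


@dataclass(frozen=True)
class AnnealSchedule:
    """Geometric decay schedule for learning rate and neighbourhood width.

    Parameters
    ----------
    eps_i, eps_f : float
        Initial and final learning rates (per presentation, dimensionless).
        ``eps_i = eps_f = 0`` is allowed and freezes the map.
    sigma_i, sigma_f : float
        Initial and final neighbourhood widths, in lattice-distance units.
    t_f : int
        Total number of sample presentations (epochs x samples).
    """

    eps_i: float
    eps_f: float
    sigma_i: float
    sigma_f: float
    t_f: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.eps_f <= self.eps_i <= 1.0):
            raise ValueError(
                f"need 0 <= eps_f <= eps_i <= 1, got eps_i={self.eps_i}, eps_f={self.eps_f}"
            )
        if not (0.0 < self.sigma_f <= self.sigma_i):
            raise ValueError(
                f"need 0 < sigma_f <= sigma_i, got sigma_i={self.sigma_i}, sigma_f={self.sigma_f}"
            )
        if self.t_f < 1:
            raise ValueError(f"t_f must be >= 1, got {self.t_f}")

    @classmethod
    def default_for(cls, width: int, height: int, t_f: int) -> "AnnealSchedule":
        """Config defaults: sigma_i = max(width, height)/2, sigma_f = 0.5,
        eps_i = 0.5, eps_f = 0.01."""
        return cls(eps_i=0.5, eps_f=0.01, sigma_i=max(width, height) / 2.0,
                   sigma_f=0.5, t_f=t_f)


@dataclass(frozen=True)
class ActivationParams:
    """Sharpness of the exponential map activation.

    ``alpha`` divides the (by default unsquared) Euclidean distance in the
    exponent; ``squared=True`` switches to the common Gaussian-kernel variant
    exp(-||.||^2 / alpha).
    """

    alpha: float
    squared: bool = False

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")


def _geometric(t: float, t_f: int, v_i: float, v_f: float) -> float:
    if not (0 <= t <= t_f):
        raise ValueError(f"iteration t={t} outside [0, {t_f}]")
    if v_i == 0.0:
        return 0.0
    return v_i * (v_f / v_i) ** (t / t_f)


def epsilon_at(t: float, sched: AnnealSchedule) -> float:
    """Learning rate eps(t) = eps_i * (eps_f/eps_i)^(t/t_f)."""
    return _geometric(t, sched.t_f, sched.eps_i, sched.eps_f)


def sigma_at(t: float, sched: AnnealSchedule) -> float:
    """Neighbourhood width sigma(t) = sigma_i * (sigma_f/sigma_i)^(t/t_f)."""
    return _geometric(t, sched.t_f, sched.sigma_i, sched.sigma_f)


@dataclass
class SomGrid:
    """A 2D neuron lattice with prototype weight vectors.

    Neurons are enumerated row-major: flat index ``k`` sits at lattice
    coordinate ``(k // width, k % width)``. ``weights`` has one row per
    neuron, in data units.
    """

    width: int
    height: int
    weights: np.ndarray
    positions: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("grid dimensions must be positive")
        self.weights = np.ascontiguousarray(self.weights, dtype=np.float64)
        n = self.width * self.height
        if self.weights.ndim != 2 or self.weights.shape[0] != n:
            raise ValueError(
                f"weights must be ({n}, m), got {self.weights.shape}"
            )
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        rows, cols = np.divmod(np.arange(n), self.width)
        self.positions = np.column_stack([rows, cols]).astype(np.int64)

    @property
    def n_neurons(self) -> int:
        return self.width * self.height

    @property
    def input_dim(self) -> int:
        return self.weights.shape[1]

    @classmethod
    def random_init(cls, width: int, height: int, data: np.ndarray,
                    rng: np.random.Generator) -> "SomGrid":
        """Uniform random prototypes within the per-feature data range."""
        data = np.asarray(data, dtype=np.float64)
        lo, hi = data.min(axis=0), data.max(axis=0)
        w = rng.uniform(lo, hi, size=(width * height, data.shape[1]))
        return cls(width=width, height=height, weights=w)

    def copy(self) -> "SomGrid":
        return SomGrid(self.width, self.height, self.weights.copy())


def _check_vector(grid: SomGrid, v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64)
    if v.shape != (grid.input_dim,):
        raise ValueError(
            f"input vector has shape {v.shape}, expected ({grid.input_dim},)"
        )
    if not np.all(np.isfinite(v)):
        raise ValueError("input vector must be finite")
    return v


def find_bmu(grid: SomGrid, v: np.ndarray) -> int:
    """Index of the best-matching unit: argmin_n ||v - w_n||.

    Ties are broken toward the lowest flat (row-major) index.
    """
    v = _check_vector(grid, v)
    d2 = ((grid.weights - v) ** 2).sum(axis=1)
    return int(np.argmin(d2))


def neighborhood(t: float, n: int, s: int, sched: AnnealSchedule,
                 grid: SomGrid) -> float:
    """Gaussian lattice-neighbourhood factor h(t, n, s) in (0, 1].

    ``exp(-||p_n - p_s||^2 / (2 sigma(t)^2))`` with Euclidean distance on the
    integer lattice coordinates.
    """
    nn = grid.n_neurons
    if not (0 <= n < nn and 0 <= s < nn):
        raise IndexError(f"neuron indices ({n}, {s}) out of range [0, {nn})")
    d2 = float(np.sum((grid.positions[n] - grid.positions[s]) ** 2))
    sig = sigma_at(t, sched)
    return float(np.exp(-d2 / (2.0 * sig * sig)))


def _neighborhood_all(t: float, s: int, sched: AnnealSchedule,
                      grid: SomGrid) -> np.ndarray:
    d2 = np.sum((grid.positions - grid.positions[s]) ** 2, axis=1)
    sig = sigma_at(t, sched)
    return np.exp(-d2 / (2.0 * sig * sig))


def som_step(grid: SomGrid, v: np.ndarray, t: int,
             sched: AnnealSchedule) -> SomGrid:
    """One competitive-learning update; mutates and returns ``grid``.

    All neurons move toward ``v`` by ``eps(t) * h(t, n, s)`` of their gap,
    with ``s`` the BMU. Since 0 <= eps*h <= 1 no neuron can overshoot, so the
    update is a contraction toward the sample.
    """
    v = _check_vector(grid, v)
    s = find_bmu(grid, v)
    eps = epsilon_at(t, sched)
    if eps > 0.0:
        h = _neighborhood_all(t, s, sched, grid)
        grid.weights += (eps * h)[:, None] * (v - grid.weights)
    return grid


def train_som(grid: SomGrid, dataset: np.ndarray, sched: AnnealSchedule,
              seed: int) -> SomGrid:
    """Train in place over ``t = 0 .. t_f - 1`` presentations.

    Samples are presented in per-epoch shuffled order drawn from
    ``np.random.default_rng(seed)``; ``t_f`` larger than the dataset starts a
    fresh shuffled pass whenever the previous one is exhausted, so the run is
    bit-reproducible for a fixed seed.
    """
    data = np.asarray(dataset, dtype=np.float64)
    if data.ndim != 2 or data.shape[0] == 0:
        raise ValueError("dataset must be a non-empty (n, m) array")
    rng = np.random.default_rng(seed)
    n = data.shape[0]
    order = np.empty(0, dtype=np.intp)
    pos = 0
    for t in range(sched.t_f):
        if pos >= order.size:
            order = rng.permutation(n)
            pos = 0
        som_step(grid, data[order[pos]], t, sched)
        pos += 1
    return grid


def activations(grid: SomGrid, v: np.ndarray,
                params: ActivationParams) -> tuple[np.ndarray, float]:
    """Per-neuron activations a_n = exp(-||v - w_n|| / alpha) and their max.

    All values lie in (0, 1]; the max is attained at the BMU (up to ties).
    Returns ``(a, a_bmu)``.
    """
    v = _check_vector(grid, v)
    d = ((grid.weights - v) ** 2).sum(axis=1)
    if not params.squared:
        d = np.sqrt(d)
    a = np.exp(-d / params.alpha)
    return a, float(a.max())


def batch_responses(
    grid: SomGrid, data: np.ndarray, params: ActivationParams,
    chunk: int = 512,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized :func:`activations` + :func:`find_bmu` over sample rows.

    Returns ``(A, bmus, a_bmu)`` with ``A`` of shape (n_samples, n_neurons).
    Distances are computed with the same expression as the per-sample path,
    so BMU tie-breaks and activation values agree bit-for-bit with it.
    """
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 2 or data.shape[1] != grid.input_dim:
        raise ValueError(
            f"data must be (n, {grid.input_dim}), got {data.shape}"
        )
    if not np.all(np.isfinite(data)):
        raise ValueError("data must be finite")
    n = data.shape[0]
    A = np.empty((n, grid.n_neurons))
    bmus = np.empty(n, dtype=np.intp)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        d = ((data[lo:hi, None, :] - grid.weights[None, :, :]) ** 2).sum(axis=2)
        bmus[lo:hi] = d.argmin(axis=1)
        if not params.squared:
            d = np.sqrt(d)
        A[lo:hi] = np.exp(-d / params.alpha)
    return A, bmus, A[np.arange(n), bmus]


def quantization_error(grid: SomGrid, data: np.ndarray) -> float:
    """Mean Euclidean distance from each sample to its BMU prototype."""
    data = np.asarray(data, dtype=np.float64)
    d2 = (
        np.einsum("ij,ij->i", data, data)[:, None]
        - 2.0 * data @ grid.weights.T
        + np.einsum("ij,ij->i", grid.weights, grid.weights)[None, :]
    )
    return float(np.mean(np.sqrt(np.maximum(d2.min(axis=1), 0.0))))
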