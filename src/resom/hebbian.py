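"""Hebbian lateral connections between modality maps.

Every neuron of one map is connected to every neuron of another map through a
nonnegative lateral weight. After the individual maps are trained and frozen,
the lateral weights are learned from co-activation: for each index-aligned
multimodal sample, the connection between the two maps' BMUs is strengthened
by ``mu * a_x * a_y`` where ``a_x, a_y`` are the scalar BMU activations.
Weights only ever grow, which makes the resulting matrices sparse in practice
and motivates the pruning analysis (:func:`prune_weakest`).

One matrix is stored per *unordered* map pair (canonical order x < y); the
reverse direction is the transposed view, since the update rule is symmetric
in the two maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .som import ActivationParams, SomGrid, batch_responses

__all__ = [
    "LateralMatrix",
    "hebbian_step",
    "train_associations",
    "pair_count",
    "nonzero_fraction",
    "prune_weakest",
]


@dataclass
class LateralMatrix:
    """Dense nonnegative lateral weights between two maps.

    ``W[i, j]`` links neuron ``i`` of map ``map_x`` to neuron ``j`` of map
    ``map_y``, with ``map_x < map_y`` canonically.
    """

    map_x: int
    map_y: int
    W: np.ndarray
    mu: float = 1.0
    #: nonzero count of the trained, unpruned matrix; set by the first call
    #: to :func:`prune_weakest` so that repeated pruning at the same kept
    #: fraction is a no-op (the fraction always refers to the trained matrix)
    pruned_from: int | None = None

    def __post_init__(self) -> None:
        if self.map_x >= self.map_y:
            raise ValueError(
                f"pair must be canonically ordered, got ({self.map_x}, {self.map_y})"
            )
        if self.mu < 0:
            raise ValueError(f"mu must be nonnegative, got {self.mu}")
        self.W = np.ascontiguousarray(self.W, dtype=np.float64)
        if self.W.ndim != 2:
            raise ValueError("W must be 2-dimensional")
        if np.any(self.W < 0):
            raise ValueError("lateral weights must be nonnegative")

    @classmethod
    def zeros(cls, map_x: int, map_y: int, n_x: int, n_y: int,
              mu: float = 1.0) -> "LateralMatrix":
        return cls(map_x, map_y, np.zeros((n_x, n_y)), mu=mu)

    def copy(self) -> "LateralMatrix":
        return LateralMatrix(self.map_x, self.map_y, self.W.copy(),
                             mu=self.mu, pruned_from=self.pruned_from)


def hebbian_step(lat: LateralMatrix, bmu_x: int, bmu_y: int,
                 a_x: float, a_y: float, mu: float | None = None) -> LateralMatrix:
    """Strengthen the single BMU-pair weight by ``mu * a_x * a_y`` (in place)."""
    mu = lat.mu if mu is None else mu
    if mu < 0:
        raise ValueError(f"mu must be nonnegative, got {mu}")
    n_x, n_y = lat.W.shape
    if not (0 <= bmu_x < n_x and 0 <= bmu_y < n_y):
        raise IndexError(f"BMU indices ({bmu_x}, {bmu_y}) out of range for {lat.W.shape}")
    lat.W[bmu_x, bmu_y] += mu * a_x * a_y
    return lat


def pair_count(k: int) -> int:
    """Number of unordered map pairs, k(k-1)/2 — grows quadratically in k."""
    if k < 1:
        raise ValueError(f"need at least one modality, got k={k}")
    return k * (k - 1) // 2


def train_associations(
    maps: Sequence[SomGrid],
    modalities: Sequence[np.ndarray],
    act_params: Sequence[ActivationParams],
    mu: float = 1.0,
) -> dict[tuple[int, int], LateralMatrix]:
    """Learn all k(k-1)/2 lateral matrices from index-aligned modality data.

    The maps are frozen; for each sample every map's BMU and scalar BMU
    activation is computed, and each unordered pair's matrix gets one Hebbian
    increment at its BMU-pair entry. Matrices start from zero.
    """
    k = len(maps)
    if len(modalities) != k or len(act_params) != k:
        raise ValueError("maps, modalities and act_params must have equal length")
    if mu < 0:
        raise ValueError(f"mu must be nonnegative, got {mu}")
    lengths = {np.asarray(x).shape[0] for x in modalities}
    if len(lengths) > 1:
        raise ValueError(f"modalities are misaligned: lengths {sorted(lengths)}")

    bmus, acts = [], []
    for grid, data, p in zip(maps, modalities, act_params):
        _, b, a = batch_responses(grid, data, p)
        bmus.append(b)
        acts.append(a)

    laterals: dict[tuple[int, int], LateralMatrix] = {}
    for x, y in combinations(range(k), 2):
        lat = LateralMatrix.zeros(x, y, maps[x].n_neurons, maps[y].n_neurons, mu=mu)
        np.add.at(lat.W, (bmus[x], bmus[y]), mu * acts[x] * acts[y])
        laterals[(x, y)] = lat
    return laterals


def nonzero_fraction(lat: LateralMatrix | np.ndarray) -> float:
    """Fraction of strictly positive entries."""
    W = lat.W if isinstance(lat, LateralMatrix) else np.asarray(lat)
    return float(np.count_nonzero(W > 0) / W.size)


def prune_weakest(
    laterals: dict[tuple[int, int], LateralMatrix],
    keep_fraction: float,
) -> dict[tuple[int, int], LateralMatrix]:
    """Zero all but the strongest ``keep_fraction`` of *nonzero* entries.

    Within each matrix the nonzero entries are ranked by weight and the top
    ``ceil(keep_fraction * nnz)`` survive, where ``nnz`` is the nonzero count
    of the *trained* matrix (recorded on first pruning, so pruning again at
    the same fraction changes nothing); ties at the cut keep the lower flat
    index. ``keep_fraction=1.0`` returns exact copies. Returns new matrices;
    the inputs are untouched.
    """
    if not (0.0 < keep_fraction <= 1.0):
        raise ValueError(f"keep_fraction must be in (0, 1], got {keep_fraction}")
    pruned: dict[tuple[int, int], LateralMatrix] = {}
    for key, lat in laterals.items():
        out = lat.copy()
        nnz_now = int(np.count_nonzero(out.W > 0))
        base = nnz_now if out.pruned_from is None else out.pruned_from
        out.pruned_from = base
        if keep_fraction < 1.0 and nnz_now:
            n_keep = min(int(np.ceil(keep_fraction * base)), nnz_now)
            flat = out.W.ravel()
            nz = np.flatnonzero(flat > 0)
            # stable sort on descending weight: ties keep lower flat index
            order = nz[np.argsort(-flat[nz], kind="stable")]
            flat[order[n_keep:]] = 0.0
        pruned[key] = out
    return pruned
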