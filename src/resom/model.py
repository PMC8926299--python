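"""Reentrant SOM: k modality maps coupled by Hebbian lateral matrices.

The assembled network supports the full post-labeled unsupervised workflow:

1. each map is trained on its own modality without labels;
2. lateral matrices are trained from BMU co-activation (:mod:`resom.hebbian`);
3. a small annotated subset assigns a class-probability vector to every
   neuron — each neuron's labeling activation is its afferent activation
   plus coefficient-weighted lateral contributions, and the probability of
   class ``i`` is the share of that neuron's activation mass contributed by
   class-``i`` samples;
4. at test time each neuron's fused activation is the *product* of its
   afferent activation with the lateral activity arriving from every other
   map's BMU, and the prediction is the label of the globally most active
   neuron across all maps.

``ReSOM`` / ``ReSOMResults`` wrap this pipeline in an estimator interface:
construct the estimator from a training dataset, ``fit()`` to obtain a
results object carrying the fitted network, then evaluate, prune or persist.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .hebbian import LateralMatrix, pair_count, prune_weakest, train_associations
from .som import (
    ActivationParams,
    AnnealSchedule,
    SomGrid,
    activations,
    batch_responses,
    find_bmu,
    quantization_error,
    train_som,
)
from .synthetic import MultimodalDataset

__all__ = [
    "LabelingCoefficients",
    "LabelTable",
    "MapSpec",
    "ResomModel",
    "build_resom",
    "EvaluationReport",
    "ReSOM",
    "ReSOMResults",
]


@dataclass(frozen=True)
class LabelingCoefficients:
    """Mixing coefficients of the neuron-labeling activation.

    ``c1[j]`` scales map ``j``'s afferent activation; ``c2[l, j]`` scales the
    lateral activity arriving from map ``l`` at map ``j``. All values lie in
    [0, 1]. The three named modes: *unimodal* (all c2 = 0, label each map
    from its own activations only — the default), *divergence* (all c1 = 0,
    label purely from the other modalities), *mixed* (anything else).
    """

    c1: np.ndarray
    c2: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "c1", np.asarray(self.c1, dtype=np.float64))
        object.__setattr__(self, "c2", np.asarray(self.c2, dtype=np.float64))
        k = self.c1.shape[0]
        if self.c2.shape != (k, k):
            raise ValueError(f"c2 must be ({k}, {k}), got {self.c2.shape}")
        for arr in (self.c1, self.c2):
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError("labeling coefficients must lie in [0, 1]")

    @classmethod
    def unimodal(cls, k: int) -> "LabelingCoefficients":
        return cls(np.ones(k), np.zeros((k, k)))

    @classmethod
    def divergence(cls, k: int) -> "LabelingCoefficients":
        c2 = np.ones((k, k)) - np.eye(k)
        return cls(np.zeros(k), c2)

    @classmethod
    def mixed(cls, c1: Sequence[float], c2: np.ndarray) -> "LabelingCoefficients":
        return cls(np.asarray(c1, dtype=float), np.asarray(c2, dtype=float))

    @property
    def mode(self) -> str:
        off_diag = self.c2[~np.eye(self.c2.shape[0], dtype=bool)]
        if not np.any(off_diag > 0):
            return "unimodal"
        if not np.any(self.c1 > 0):
            return "divergence"
        return "mixed"


@dataclass
class LabelTable:
    """Per-map, per-neuron class-probability vectors and assigned classes."""

    probs: list[np.ndarray]      # per map: (n_neurons, n_classes), rows sum to 1
    assigned: list[np.ndarray]   # per map: (n_neurons,) int argmax class
    n_classes: int

    def subset(self, which: Sequence[int]) -> "LabelTable":
        return LabelTable([self.probs[j] for j in which],
                          [self.assigned[j] for j in which], self.n_classes)


@dataclass(frozen=True)
class MapSpec:
    """Size and activation sharpness of one modality map."""

    width: int
    height: int
    input_dim: int
    alpha: float | None = None   # None -> input_dim, the dimension-invariant default
    squared: bool = False

    def activation_params(self) -> ActivationParams:
        alpha = self.input_dim if self.alpha is None else self.alpha
        return ActivationParams(alpha=alpha, squared=self.squared)


def build_resom(map_specs: Sequence[MapSpec], mu: float = 1.0) -> "ResomModel":
    """Allocate an untrained network: k maps + k(k-1)/2 zero lateral matrices."""
    maps = [
        SomGrid(ms.width, ms.height, np.zeros((ms.width * ms.height, ms.input_dim)))
        for ms in map_specs
    ]
    laterals = {
        (x, y): LateralMatrix.zeros(x, y, maps[x].n_neurons, maps[y].n_neurons, mu=mu)
        for x in range(len(maps)) for y in range(x + 1, len(maps))
    }
    return ResomModel(maps=maps,
                      act_params=[ms.activation_params() for ms in map_specs],
                      laterals=laterals)


@dataclass
class EvaluationReport:
    """Classification accuracy plus a true-by-predicted confusion matrix."""

    accuracy: float
    confusion: np.ndarray   # rows: true class, columns: predicted
    n_samples: int


@dataclass
class ResomModel:
    """The assembled network: maps, lateral matrices, optional label table."""

    maps: list[SomGrid]
    act_params: list[ActivationParams]
    laterals: dict[tuple[int, int], LateralMatrix]
    label_table: LabelTable | None = None

    def __post_init__(self) -> None:
        k = self.k
        expected = {(x, y) for x in range(k) for y in range(x + 1, k)}
        if set(self.laterals) != expected:
            raise ValueError(
                f"need exactly the {pair_count(k) if k else 0} canonical map pairs, "
                f"got {sorted(self.laterals)}"
            )
        for (x, y), lat in self.laterals.items():
            want = (self.maps[x].n_neurons, self.maps[y].n_neurons)
            if lat.W.shape != want:
                raise ValueError(
                    f"lateral ({x},{y}) has shape {lat.W.shape}, expected {want}"
                )

    @property
    def k(self) -> int:
        return len(self.maps)

    # -- lateral plumbing ---------------------------------------------------

    def lateral_block(self, l: int, j: int) -> np.ndarray:
        """Lateral weights oriented source map ``l`` -> target map ``j``."""
        if l == j:
            raise ValueError("no lateral matrix from a map to itself")
        return self.laterals[(l, j)].W if l < j else self.laterals[(j, l)].W.T

    def lateral_activity(self, a_l: float, l: int, j: int, bmu_l: int, s: int) -> float:
        """Scalar lateral input at neuron ``s`` of map ``j``: a^l * W[bmu_l, s]."""
        W = self.lateral_block(l, j)
        n_l, n_j = W.shape
        if not (0 <= bmu_l < n_l and 0 <= s < n_j):
            raise IndexError(f"indices ({bmu_l}, {s}) out of range for {W.shape}")
        return float(a_l * W[bmu_l, s])

    def _afferent(self, sample: Sequence[np.ndarray]):
        """Per map: (activation vector, bmu, scalar BMU activation)."""
        if len(sample) != self.k:
            raise ValueError(f"sample must provide {self.k} modality vectors")
        out = []
        for grid, p, v in zip(self.maps, self.act_params, sample):
            a = activations(grid, v, p)
            out.append((a[0], find_bmu(grid, v), a[1]))
        return out

    # -- labeling (additive aggregation) ------------------------------------

    def labeling_activation(self, sample: Sequence[np.ndarray], j: int, s: int,
                            coeffs: LabelingCoefficients) -> float:
        """Additive labeling activation of neuron ``s`` on map ``j``:
        c1[j] * a_s^j + sum_{l != j} c2[l, j] * a^l * W[bmu_l, s]."""
        aff = self._afferent(sample)
        total = coeffs.c1[j] * aff[j][0][s]
        for l in range(self.k):
            if l != j and coeffs.c2[l, j] > 0:
                total += coeffs.c2[l, j] * self.lateral_activity(
                    aff[l][2], l, j, aff[l][1], s)
        return float(total)

    def _labeling_matrix(self, data: MultimodalDataset, j: int,
                         coeffs: LabelingCoefficients,
                         responses) -> np.ndarray:
        """(n_samples, n_j) labeling activations for map j."""
        A_aff, _, _ = responses[j]
        total = coeffs.c1[j] * A_aff
        for l in range(self.k):
            if l != j and coeffs.c2[l, j] > 0:
                _, bmus_l, a_l = responses[l]
                total = total + coeffs.c2[l, j] * a_l[:, None] * self.lateral_block(l, j)[bmus_l, :]
        return total

    def label_neurons(self, labeled: MultimodalDataset,
                      coeffs: LabelingCoefficients | None = None,
                      n_classes: int | None = None) -> LabelTable:
        """Assign class probabilities to every neuron from an annotated subset.

        For each neuron, p(class=i) is the fraction of its summed labeling
        activation contributed by class-i samples; the assigned class is the
        argmax (ties toward the lowest class id). Stores and returns the table.
        """
        if labeled.n_samples == 0:
            raise ValueError("labeled subset must be non-empty")
        coeffs = LabelingCoefficients.unimodal(self.k) if coeffs is None else coeffs
        if coeffs.mode != "unimodal" and not self.laterals and self.k > 1:
            raise RuntimeError("lateral matrices required for non-unimodal labeling")
        n_classes = int(labeled.labels.max()) + 1 if n_classes is None else n_classes
        present = np.unique(labeled.labels)
        if present.size < n_classes:
            warnings.warn(
                f"labeled subset covers {present.size}/{n_classes} classes",
                stacklevel=2,
            )
        onehot = np.zeros((labeled.n_samples, n_classes))
        onehot[np.arange(labeled.n_samples), labeled.labels] = 1.0

        responses = [
            batch_responses(grid, X, p)
            for grid, X, p in zip(self.maps, labeled.modalities, self.act_params)
        ]
        probs, assigned = [], []
        for j in range(self.k):
            A = self._labeling_matrix(labeled, j, coeffs, responses)
            sums = onehot.T @ A                      # (n_classes, n_j)
            totals = sums.sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                p = np.where(totals > 0, sums / totals, 1.0 / n_classes)
            probs.append(p.T)
            assigned.append(p.argmax(axis=0).astype(np.int64))
        self.label_table = LabelTable(probs, assigned, n_classes)
        return self.label_table

    # -- inference (multiplicative aggregation) ------------------------------

    def resom_activation(self, sample: Sequence[np.ndarray]) -> list[np.ndarray]:
        """Fused activation of every neuron: afferent times the product of the
        lateral activities arriving from every other map's BMU.

        With a single map the product is empty and this reduces to the plain
        afferent activation vector.
        """
        aff = self._afferent(sample)
        fused = []
        for j in range(self.k):
            A = aff[j][0].copy()
            for l in range(self.k):
                if l != j:
                    _, bmu_l, a_l = aff[l]
                    A *= a_l * self.lateral_block(l, j)[bmu_l, :]
            fused.append(A)
        return fused

    def predict(self, sample: Sequence[np.ndarray]) -> tuple[int, int, int]:
        """Predict one sample: ``(class, winning map, winning neuron)``.

        The winner is the globally most active neuron across all maps under
        the fused activation; ties resolve to the lowest (map, neuron) pair.
        If pruning (or untrained laterals) drove *every* fused activation to
        zero, the winner falls back to the most active neuron under the
        afferent activations alone, which are strictly positive.
        """
        if self.label_table is None:
            raise RuntimeError("model has no label table; call label_neurons first")
        fused = self.resom_activation(sample)
        flat = np.concatenate(fused)
        if not np.any(flat > 0):
            flat = np.concatenate([a for a, _, _ in self._afferent(sample)])
        win = int(flat.argmax())
        j_max, s_max = self._unflatten(win)
        return int(self.label_table.assigned[j_max][s_max]), j_max, s_max

    def _unflatten(self, win: int) -> tuple[int, int]:
        for j, grid in enumerate(self.maps):
            if win < grid.n_neurons:
                return j, win
            win -= grid.n_neurons
        raise IndexError("winner index out of range")

    def predict_batch(self, data: MultimodalDataset) -> np.ndarray:
        """Vectorized :meth:`predict` over a dataset; returns predicted classes."""
        if self.label_table is None:
            raise RuntimeError("model has no label table; call label_neurons first")
        responses = [
            batch_responses(grid, X, p)
            for grid, X, p in zip(self.maps, data.modalities, self.act_params)
        ]
        fused_blocks, aff_blocks = [], []
        for j in range(self.k):
            A = responses[j][0].copy()
            for l in range(self.k):
                if l != j:
                    _, bmus_l, a_l = responses[l]
                    A *= a_l[:, None] * self.lateral_block(l, j)[bmus_l, :]
            fused_blocks.append(A)
            aff_blocks.append(responses[j][0])
        fused = np.concatenate(fused_blocks, axis=1)
        afferent = np.concatenate(aff_blocks, axis=1)
        dead = ~np.any(fused > 0, axis=1)
        if np.any(dead):
            fused[dead] = afferent[dead]
        winners = fused.argmax(axis=1)
        flat_labels = np.concatenate([
            self.label_table.assigned[j] for j in range(self.k)
        ])
        return flat_labels[winners]

    def evaluate(self, test: MultimodalDataset) -> EvaluationReport:
        """Accuracy and confusion matrix (rows true, columns predicted)."""
        if test.n_samples == 0:
            raise ValueError("test set must be non-empty")
        pred = self.predict_batch(test)
        n_classes = self.label_table.n_classes
        conf = _sk_confusion(test.labels, pred, labels=np.arange(n_classes))
        return EvaluationReport(
            accuracy=float(np.mean(pred == test.labels)),
            confusion=conf,
            n_samples=test.n_samples,
        )

    # -- structure ops -------------------------------------------------------

    def prune(self, keep_fraction: float) -> "ResomModel":
        """New model with each lateral matrix pruned to its strongest
        ``keep_fraction`` of nonzero weights; the label table is shared."""
        return ResomModel(
            maps=[g.copy() for g in self.maps],
            act_params=list(self.act_params),
            laterals=prune_weakest(self.laterals, keep_fraction),
            label_table=self.label_table,
        )

    def submodel(self, which: Sequence[int]) -> "ResomModel":
        """Sub-network on a subset of maps (laterals between kept maps only)."""
        which = list(which)
        remap = {old: new for new, old in enumerate(which)}
        laterals = {}
        for (x, y), lat in self.laterals.items():
            if x in remap and y in remap:
                nx, ny = sorted((remap[x], remap[y]))
                W = lat.W if remap[x] < remap[y] else lat.W.T
                laterals[(nx, ny)] = LateralMatrix(nx, ny, W.copy(), mu=lat.mu)
        return ResomModel(
            maps=[self.maps[j].copy() for j in which],
            act_params=[self.act_params[j] for j in which],
            laterals=laterals,
            label_table=None if self.label_table is None
            else self.label_table.subset(which),
        )


# ---------------------------------------------------------------------------
# estimator-style wrapper


class ReSOM:
    """Reentrant-SOM estimator over an index-aligned multimodal dataset.

    Parameters
    ----------
    train : MultimodalDataset
        Unlabeled training data (its labels, if any, are ignored by ``fit``).
    grid_shapes : sequence of (width, height)
        One lattice size per modality.
    schedules : sequence of AnnealSchedule, optional
        Per-map annealing; defaults to ``AnnealSchedule.default_for`` with
        ``t_f = epochs * n_train``.
    alphas : "auto" | sequence of float | None
        Activation sharpness per map. ``"auto"`` (default) calibrates each
        map's alpha to its mean quantization error on the training data after
        SOM training, so that a typical in-cluster sample activates its BMU
        at about ``1/e``; ``None`` uses the per-map input dimension.
    mu : float
        Hebbian learning rate of the lateral matrices.
    epochs : int
        Full passes over the training data per map.
    """

    def __init__(self, train: MultimodalDataset,
                 grid_shapes: Sequence[tuple[int, int]], *,
                 schedules: Sequence[AnnealSchedule] | None = None,
                 alphas="auto", mu: float = 1.0, epochs: int = 5,
                 squared_norm: bool = False):
        if len(grid_shapes) != train.k:
            raise ValueError("need one grid shape per modality")
        self.train_data = train
        self.grid_shapes = [tuple(g) for g in grid_shapes]
        t_f = epochs * train.n_samples
        if schedules is None:
            schedules = [AnnealSchedule.default_for(w, h, t_f)
                         for w, h in self.grid_shapes]
        self.schedules = list(schedules)
        self.alphas = alphas
        self.mu = mu
        self.epochs = epochs
        self.squared_norm = squared_norm

    def _alpha_for(self, j: int, input_dim: int, qe: float) -> float:
        spec = self.alphas
        if not isinstance(spec, str) and spec is not None:
            spec = spec[j]
        if spec == "auto":
            return max(qe, 1e-12)
        if spec is None:
            return float(input_dim)
        return float(spec)

    def fit(self, label_data: MultimodalDataset | None = None,
            coeffs: LabelingCoefficients | None = None,
            n_classes: int | None = None, seed: int = 0,
            train_laterals: bool = True) -> "ReSOMResults":
        """Train maps, then laterals, then (optionally) the label table.

        ``train_laterals=False`` stops after the individual maps, leaving the
        lateral matrices zero-initialized (for staged pipelines that run the
        Hebbian pass separately).
        """
        k = self.train_data.k
        children = np.random.SeedSequence(seed).spawn(2 * k)
        maps, alphas_used, qerrs = [], [], []
        for j in range(k):
            X = self.train_data.modalities[j]
            grid = SomGrid.random_init(*self.grid_shapes[j], data=X,
                                       rng=np.random.default_rng(children[2 * j]))
            train_som(grid, X, self.schedules[j], seed=children[2 * j + 1])
            qe = quantization_error(grid, X)
            qerrs.append(qe)
            alphas_used.append(self._alpha_for(j, X.shape[1], qe))
            maps.append(grid)
        act_params = [ActivationParams(a, squared=self.squared_norm)
                      for a in alphas_used]
        if train_laterals:
            laterals = train_associations(maps, self.train_data.modalities,
                                          act_params, mu=self.mu)
        else:
            laterals = {
                (x, y): LateralMatrix.zeros(x, y, maps[x].n_neurons,
                                            maps[y].n_neurons, mu=self.mu)
                for x in range(k) for y in range(x + 1, k)
            }
        model = ResomModel(maps=maps, act_params=act_params, laterals=laterals)
        if label_data is not None:
            model.label_neurons(label_data, coeffs=coeffs, n_classes=n_classes)
        return ReSOMResults(model=model, estimator=self, seed=seed,
                            alphas=alphas_used, quantization_errors=qerrs)


@dataclass
class ReSOMResults:
    """Fitted ReSOM network plus fit metadata and convenience methods."""

    model: ResomModel
    estimator: ReSOM | None
    seed: int
    alphas: list[float]
    quantization_errors: list[float]

    def label(self, labeled: MultimodalDataset,
              coeffs: LabelingCoefficients | None = None,
              n_classes: int | None = None) -> "ReSOMResults":
        self.model.label_neurons(labeled, coeffs=coeffs, n_classes=n_classes)
        return self

    def predict(self, sample) -> tuple[int, int, int]:
        return self.model.predict(sample)

    def evaluate(self, test: MultimodalDataset) -> EvaluationReport:
        return self.model.evaluate(test)

    def prune(self, keep_fraction: float) -> "ReSOMResults":
        return ReSOMResults(model=self.model.prune(keep_fraction),
                            estimator=self.estimator, seed=self.seed,
                            alphas=list(self.alphas),
                            quantization_errors=list(self.quantization_errors))

    def unimodal(self, j: int) -> "ReSOMResults":
        """Single-modality sub-network (plain post-labeled SOM for map j)."""
        return ReSOMResults(model=self.model.submodel([j]),
                            estimator=None, seed=self.seed,
                            alphas=[self.alphas[j]],
                            quantization_errors=[self.quantization_errors[j]])

    def summary(self) -> str:
        """Plain-text summary of the fitted network."""
        from .hebbian import nonzero_fraction

        m = self.model
        lines = [
            "Reentrant SOM results",
            "=" * 21,
            f"modalities:        {m.k}",
            f"lateral matrices:  {len(m.laterals)}",
        ]
        for j, (grid, a, qe) in enumerate(
                zip(m.maps, self.alphas, self.quantization_errors)):
            lines.append(
                f"map {j}: {grid.width}x{grid.height} "
                f"(dim {grid.input_dim}), alpha={a:.4g}, quant. error={qe:.4g}"
            )
        for (x, y), lat in sorted(m.laterals.items()):
            lines.append(
                f"lateral ({x},{y}): shape {lat.W.shape}, "
                f"nonzero fraction {nonzero_fraction(lat):.3f}"
            )
        if m.label_table is None:
            lines.append("label table:       not fitted")
        else:
            lines.append(f"label table:       {m.label_table.n_classes} classes")
        return "\n".join(lines)
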