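"""Synthetic index-aligned multimodal datasets with engineered class confusions.

The generator emulates the situation that makes multimodal fusion worthwhile:
each modality views the same objects, is reliable on most classes, but
confuses a *different* small set of class pairs. Per modality, each class is
an isotropic Gaussian cluster; classes belonging to a configured confusion
pair share a region (their centers sit ``delta_near`` apart) while all other
class centers are mutually ``delta_far`` apart. Because the confusion pairs
differ across modalities, the modalities carry complementary information and
a fusion method can repair each map's weaknesses.

Geometry: confusion pairs share a "group" center; group centers are placed on
mutually orthogonal axes scaled so that any two groups are exactly
``delta_far`` apart, the two classes of a pair are offset ``±delta_near/2``
along a random direction, and the whole construction is passed through a
random rotation so no feature axis is special. Features are then min-max
normalized to [0, 1] per modality using the pooled splits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import ortho_group

__all__ = [
    "GeneratorSpec",
    "MultimodalDataset",
    "generate",
    "oracle_accuracy",
    "split",
]


@dataclass
class MultimodalDataset:
    """k index-aligned modality arrays sharing one integer label vector."""

    modalities: list[np.ndarray]
    labels: np.ndarray
    split: str = ""
    #: true class centers per modality in normalized feature space, when the
    #: dataset came from :func:`generate` (used by :func:`oracle_accuracy`)
    centers: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.modalities = [np.asarray(m, dtype=np.float64) for m in self.modalities]
        self.labels = np.asarray(self.labels, dtype=np.int64)
        n = {m.shape[0] for m in self.modalities}
        if len(n) != 1 or n.pop() != self.labels.shape[0]:
            raise ValueError("modalities and labels must be index-aligned")

    @property
    def n_samples(self) -> int:
        return self.labels.shape[0]

    @property
    def k(self) -> int:
        return len(self.modalities)

    def subset(self, idx: np.ndarray, split: str | None = None) -> "MultimodalDataset":
        return MultimodalDataset(
            [m[idx] for m in self.modalities], self.labels[idx],
            split=self.split if split is None else split, centers=self.centers,
        )

    def select_modalities(self, which: Sequence[int]) -> "MultimodalDataset":
        return MultimodalDataset(
            [self.modalities[j] for j in which], self.labels, split=self.split,
            centers=None if self.centers is None else [self.centers[j] for j in which],
        )


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for the synthetic multimodal problem.

    Defaults describe the desk-scale two-modality benchmark: 10 classes,
    16-dimensional modalities, modality 0 confusing classes {4, 9} and
    modality 1 confusing {1, 7}. The confused centers sit ``delta_near``
    apart — about 1.6 cluster standard deviations, deep enough that the
    nearest-center oracle errs on roughly a fifth of the pair's samples but
    shallow enough that the overlap region still carries a class lean the
    labeling stage can pick up — while all other class centers are mutually
    ``delta_far`` apart (clean separation).
    """

    k: int = 2
    n_classes: int = 10
    dims: tuple[int, ...] = (16, 16)
    n_train: int = 2000
    n_label: int = 200
    n_test: int = 500
    cluster_spread: tuple[float, ...] = (0.075, 0.075)
    confusion_pairs: tuple[tuple[tuple[int, int], ...], ...] = (
        ((4, 9),),
        ((1, 7),),
    )
    delta_near: float = 0.12
    delta_far: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1 or self.n_classes < 2:
            raise ValueError("need k >= 1 modalities and >= 2 classes")
        if min(self.n_train, self.n_label, self.n_test) < 1:
            raise ValueError("all split sizes must be >= 1")
        if not self.delta_near > 0:
            raise ValueError(f"delta_near must be positive, got {self.delta_near}")
        if not self.delta_near < self.delta_far:
            raise ValueError("delta_near must be smaller than delta_far")
        for name in ("dims", "cluster_spread", "confusion_pairs"):
            if len(getattr(self, name)) != self.k:
                raise ValueError(f"{name} must have one entry per modality")
        for pairs in self.confusion_pairs:
            flat = [c for p in pairs for c in p]
            if len(set(flat)) != len(flat):
                raise ValueError("confusion pairs within a modality must be disjoint")
            if any(not (0 <= c < self.n_classes) for c in flat):
                raise ValueError("confusion pair class out of range")


def _class_centers(spec: GeneratorSpec, j: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Raw (unnormalized) class centers for modality j."""
    m = spec.dims[j]
    pairs = spec.confusion_pairs[j]
    paired = {c for p in pairs for c in p}
    groups: list[tuple[int, ...]] = list(pairs) + [
        (c,) for c in range(spec.n_classes) if c not in paired
    ]
    if len(groups) > m:
        raise ValueError(
            f"modality {j}: need dim >= {len(groups)} for {len(groups)} cluster groups"
        )
    centers = np.zeros((spec.n_classes, m))
    scale = spec.delta_far / np.sqrt(2.0)
    for g, classes in enumerate(groups):
        base = np.zeros(m)
        base[g] = scale
        if len(classes) == 1:
            centers[classes[0]] = base
        else:
            u = rng.standard_normal(m)
            u /= np.linalg.norm(u)
            centers[classes[0]] = base + 0.5 * spec.delta_near * u
            centers[classes[1]] = base - 0.5 * spec.delta_near * u
    # random rotation: distances preserved, no feature axis privileged
    rot = ortho_group.rvs(m, random_state=rng)
    return centers @ rot.T


def _balanced_labels(n: int, n_classes: int, rng: np.random.Generator) -> np.ndarray:
    base = np.repeat(np.arange(n_classes), n // n_classes)
    extra = rng.choice(n_classes, size=n - base.size, replace=False) \
        if n - base.size > 0 else np.empty(0, dtype=np.int64)
    return rng.permutation(np.concatenate([base, extra.astype(np.int64)]))


def generate(spec: GeneratorSpec) -> tuple[MultimodalDataset, MultimodalDataset, MultimodalDataset]:
    """Draw the (train, label, test) datasets of the configured study.

    Each split gets its own near-balanced label sequence, shared across
    modalities; every modality's samples are drawn from that modality's class
    Gaussians at the shared labels, then min-max scaled to [0, 1]. Fully
    deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    centers = [_class_centers(spec, j, rng) for j in range(spec.k)]

    sizes = {"train": spec.n_train, "label": spec.n_label, "test": spec.n_test}
    labels = {name: _balanced_labels(n, spec.n_classes, rng) for name, n in sizes.items()}
    raw = {
        name: [
            centers[j][lab] + spec.cluster_spread[j] * rng.standard_normal((lab.size, spec.dims[j]))
            for j in range(spec.k)
        ]
        for name, lab in labels.items()
    }

    # per-modality min-max over the pooled splits, applied to data and centers
    norm_centers: list[np.ndarray] = []
    for j in range(spec.k):
        pooled = np.vstack([raw[name][j] for name in sizes])
        lo, hi = pooled.min(axis=0), pooled.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        for name in sizes:
            raw[name][j] = (raw[name][j] - lo) / span
        norm_centers.append((centers[j] - lo) / span)

    return tuple(
        MultimodalDataset(raw[name], labels[name], split=name, centers=norm_centers)
        for name in sizes
    )


def oracle_accuracy(dataset: MultimodalDataset,
                    centers: Sequence[np.ndarray] | None = None) -> np.ndarray:
    """Per-modality accuracy of the true-center nearest-centroid classifier.

    An upper reference for what a single modality's map can achieve: it uses
    the generator's own class centers, so it is only limited by the cluster
    overlap engineered into the spec.
    """
    centers = dataset.centers if centers is None else centers
    if centers is None:
        raise ValueError("dataset carries no true centers; pass them explicitly")
    accs = []
    for X, C in zip(dataset.modalities, centers):
        d2 = ((X[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
        accs.append(float(np.mean(d2.argmin(axis=1) == dataset.labels)))
    return np.array(accs)


def split(dataset: MultimodalDataset, fractions: Sequence[float],
          seed: int = 0) -> list[MultimodalDataset]:
    """Disjoint stratified partition of a dataset by fractions.

    Index assignment is stratified by class so each part's class mix matches
    the whole; deterministic under ``seed``. Fractions must sum to <= 1;
    leftover samples (if the sum is < 1) are dropped.
    """
    fractions = list(fractions)
    if any(f < 0 for f in fractions) or sum(fractions) > 1.0 + 1e-12:
        raise ValueError("fractions must be nonnegative and sum to <= 1")
    rng = np.random.default_rng(seed)
    parts: list[list[np.ndarray]] = [[] for _ in fractions]
    for c in np.unique(dataset.labels):
        idx = rng.permutation(np.flatnonzero(dataset.labels == c))
        bounds = np.floor(np.cumsum(fractions) * idx.size + 1e-9).astype(int)
        start = 0
        for p, stop in enumerate(bounds):
            parts[p].append(idx[start:stop])
            start = stop
    names = ("train", "label", "test")
    return [
        dataset.subset(np.sort(np.concatenate(chunks)) if chunks else np.empty(0, int),
                       split=names[p] if p < 3 else f"part{p}")
        for p, chunks in enumerate(parts)
    ]
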