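"""File formats and persistence: IDX arrays, delimited matrices, model
containers, and run configuration.

IDX is the MNIST-family interchange format: a big-endian header of
``0x00 0x00 <dtype code> <ndim>`` followed by one uint32 per dimension and
the raw big-endian payload. Arbitrary numeric modalities travel as plain
delimited text. A fitted network round-trips bit-exactly through a versioned
``.npz`` container.
"""

from __future__ import annotations

import json
import struct
import warnings
import zipfile
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .hebbian import LateralMatrix
from .model import (
    LabelTable,
    LabelingCoefficients,
    ReSOMResults,
    ResomModel,
)
from .som import ActivationParams, AnnealSchedule, SomGrid
from .synthetic import GeneratorSpec

__all__ = [
    "FormatError",
    "read_idx",
    "write_idx",
    "read_matrix",
    "write_matrix",
    "save_model",
    "load_model",
    "RunConfig",
]

CONTAINER_VERSION = 1


class FormatError(ValueError):
    """Raised for malformed IDX files or model containers."""


# ---------------------------------------------------------------------------
# IDX

_IDX_DTYPES = {
    0x08: np.dtype(">u1"),
    0x09: np.dtype(">i1"),
    0x0B: np.dtype(">i2"),
    0x0C: np.dtype(">i4"),
    0x0D: np.dtype(">f4"),
    0x0E: np.dtype(">f8"),
}
_IDX_CODES = {v.newbyteorder("="): k for k, v in _IDX_DTYPES.items()}


def read_idx(path: str | Path, normalize: bool = False) -> np.ndarray:
    """Read an IDX file into an array with the declared shape.

    ``normalize=True`` maps integer payloads onto [0, 1] by dividing by the
    dtype's maximum (255 for the usual uint8 pixels).
    """
    raw = Path(path).read_bytes()
    if len(raw) < 4:
        raise FormatError(f"{path}: truncated IDX header")
    zero1, zero2, code, ndim = struct.unpack(">BBBB", raw[:4])
    if zero1 != 0 or zero2 != 0 or code not in _IDX_DTYPES:
        raise FormatError(f"{path}: bad IDX magic {raw[:4]!r}")
    header_end = 4 + 4 * ndim
    if len(raw) < header_end:
        raise FormatError(f"{path}: truncated IDX dimension header")
    dims = struct.unpack(f">{ndim}I", raw[4:header_end])
    dtype = _IDX_DTYPES[code]
    expected = int(np.prod(dims, dtype=np.int64)) * dtype.itemsize
    if len(raw) - header_end != expected:
        raise FormatError(
            f"{path}: payload has {len(raw) - header_end} bytes, expected {expected}"
        )
    arr = np.frombuffer(raw, dtype=dtype, offset=header_end).reshape(dims)
    arr = arr.astype(dtype.newbyteorder("="))
    if normalize and np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    return arr


def write_idx(path: str | Path, arr: np.ndarray) -> None:
    """Write an array as IDX (big-endian payload, uint32 dimensions)."""
    arr = np.asarray(arr)
    native = arr.dtype.newbyteorder("=")
    if native not in _IDX_CODES:
        raise FormatError(f"dtype {arr.dtype} not representable in IDX")
    code = _IDX_CODES[native]
    with open(path, "wb") as fh:
        fh.write(struct.pack(">BBBB", 0, 0, code, arr.ndim))
        fh.write(struct.pack(f">{arr.ndim}I", *arr.shape))
        fh.write(np.ascontiguousarray(arr, dtype=_IDX_DTYPES[code]).tobytes())


# ---------------------------------------------------------------------------
# delimited matrices


def read_matrix(path: str | Path, delimiter: str = ",") -> np.ndarray:
    """Read a delimited numeric text matrix, one sample per row."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # empty input warns before we raise
            arr = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    except ValueError as err:
        raise ValueError(f"{path}: could not parse numeric matrix: {err}") from err
    if arr.size == 0:
        raise ValueError(f"{path}: empty matrix file")
    return arr


def write_matrix(path: str | Path, arr: np.ndarray, delimiter: str = ",") -> None:
    np.savetxt(path, np.atleast_2d(np.asarray(arr)), delimiter=delimiter, fmt="%.17g")


# ---------------------------------------------------------------------------
# model container


def save_model(obj: ResomModel | ReSOMResults, path: str | Path) -> None:
    """Persist a network (or fitted results) as a versioned ``.npz`` container."""
    results = obj if isinstance(obj, ReSOMResults) else None
    model = obj.model if results is not None else obj
    payload: dict[str, np.ndarray] = {}
    meta: dict[str, Any] = {
        "version": CONTAINER_VERSION,
        "k": model.k,
        "mu": [model.laterals[p].mu for p in sorted(model.laterals)],
        "pruned_from": [model.laterals[p].pruned_from
                        for p in sorted(model.laterals)],
        "widths": [g.width for g in model.maps],
        "heights": [g.height for g in model.maps],
        "alphas": [p.alpha for p in model.act_params],
        "squared": [p.squared for p in model.act_params],
        "has_labels": model.label_table is not None,
        "is_results": results is not None,
    }
    if results is not None:
        meta["seed"] = results.seed
        meta["fit_alphas"] = results.alphas
        meta["quantization_errors"] = results.quantization_errors
    for j, grid in enumerate(model.maps):
        payload[f"map{j}_weights"] = grid.weights
    for (x, y), lat in model.laterals.items():
        payload[f"lateral_{x}_{y}"] = lat.W
    if model.label_table is not None:
        meta["n_classes"] = model.label_table.n_classes
        for j in range(model.k):
            payload[f"label_probs_{j}"] = model.label_table.probs[j]
            payload[f"label_assigned_{j}"] = model.label_table.assigned[j]
    payload["meta_json"] = np.frombuffer(
        json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8
    )
    np.savez(path, **payload)


def load_model(path: str | Path) -> ResomModel | ReSOMResults:
    """Load a container written by :func:`save_model` (bit-exact round-trip)."""
    try:
        with np.load(path) as data:
            arrays = {k: data[k] for k in data.files}
    except (OSError, ValueError, KeyError, EOFError, zipfile.BadZipFile) as err:
        raise FormatError(f"{path}: corrupt model container: {err}") from err
    if "meta_json" not in arrays:
        raise FormatError(f"{path}: missing container metadata")
    meta = json.loads(bytes(arrays["meta_json"].tobytes()).decode())
    if meta.get("version") != CONTAINER_VERSION:
        raise FormatError(
            f"{path}: container version {meta.get('version')} "
            f"!= supported {CONTAINER_VERSION}"
        )
    k = meta["k"]
    maps = [
        SomGrid(meta["widths"][j], meta["heights"][j], arrays[f"map{j}_weights"])
        for j in range(k)
    ]
    act_params = [
        ActivationParams(alpha=meta["alphas"][j], squared=meta["squared"][j])
        for j in range(k)
    ]
    mus = meta["mu"]
    pruned_from = meta.get("pruned_from", [None] * len(mus))
    laterals = {}
    for i, (x, y) in enumerate(
            (x, y) for x in range(k) for y in range(x + 1, k)):
        laterals[(x, y)] = LateralMatrix(x, y, arrays[f"lateral_{x}_{y}"],
                                         mu=mus[i], pruned_from=pruned_from[i])
    label_table = None
    if meta["has_labels"]:
        label_table = LabelTable(
            probs=[arrays[f"label_probs_{j}"] for j in range(k)],
            assigned=[arrays[f"label_assigned_{j}"].astype(np.int64)
                      for j in range(k)],
            n_classes=meta["n_classes"],
        )
    model = ResomModel(maps=maps, act_params=act_params, laterals=laterals,
                       label_table=label_table)
    if meta.get("is_results"):
        return ReSOMResults(model=model, estimator=None, seed=meta["seed"],
                            alphas=meta["fit_alphas"],
                            quantization_errors=meta["quantization_errors"])
    return model


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class MapConfig:
    """Per-map hyperparameters as read from a config file."""

    width: int
    height: int
    alpha: float | str | None = "auto"
    eps_i: float = 0.5
    eps_f: float = 0.01
    sigma_i: float | None = None   # None -> max(width, height) / 2
    sigma_f: float = 0.5

    def schedule(self, t_f: int) -> AnnealSchedule:
        sigma_i = max(self.width, self.height) / 2.0 if self.sigma_i is None else self.sigma_i
        return AnnealSchedule(eps_i=self.eps_i, eps_f=self.eps_f,
                              sigma_i=sigma_i, sigma_f=self.sigma_f, t_f=t_f)


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run.

    Every downstream invariant (schedule bounds, coefficient ranges,
    generator geometry) is checked at load time by constructing the objects
    it configures, so a bad config fails before any compute starts.
    """

    maps: list[MapConfig]
    epochs: int = 5
    mu: float = 1.0
    seed: int = 0
    keep_fraction: float = 1.0
    labeling_mode: str = "unimodal"
    c1: list[float] | None = None
    c2: list[list[float]] | None = None
    n_classes: int | None = None
    generator: GeneratorSpec | None = None

    def __post_init__(self) -> None:
        if not self.maps:
            raise ValueError("config must define at least one map")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.mu < 0:
            raise ValueError("mu must be nonnegative")
        if not (0.0 < self.keep_fraction <= 1.0):
            raise ValueError("keep_fraction must be in (0, 1]")
        if self.labeling_mode not in ("unimodal", "divergence", "mixed"):
            raise ValueError(f"unknown labeling mode {self.labeling_mode!r}")
        if self.labeling_mode == "mixed" and (self.c1 is None or self.c2 is None):
            raise ValueError("mixed labeling requires explicit c1 and c2")
        for mc in self.maps:
            mc.schedule(t_f=1)        # raises on bad bounds
            if mc.alpha not in (None, "auto"):
                ActivationParams(alpha=float(mc.alpha))
        self.coefficients(k=len(self.maps))

    def coefficients(self, k: int) -> LabelingCoefficients:
        if self.labeling_mode == "unimodal":
            return LabelingCoefficients.unimodal(k)
        if self.labeling_mode == "divergence":
            return LabelingCoefficients.divergence(k)
        return LabelingCoefficients.mixed(self.c1, np.asarray(self.c2, dtype=float))

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        raw = dict(raw)
        maps = [MapConfig(**m) for m in raw.pop("maps")]
        gen = raw.pop("generator", None)
        labeling = raw.pop("labeling", {})
        return cls(
            maps=maps,
            generator=GeneratorSpec(**_listify_spec(gen)) if gen else None,
            labeling_mode=labeling.get("mode", "unimodal"),
            c1=labeling.get("c1"),
            c2=labeling.get("c2"),
            **raw,
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)


def _listify_spec(gen: dict[str, Any]) -> dict[str, Any]:
    """YAML lists -> the tuple fields GeneratorSpec expects."""
    gen = dict(gen)
    for key in ("dims", "cluster_spread"):
        if key in gen:
            gen[key] = tuple(gen[key])
    if "confusion_pairs" in gen:
        gen["confusion_pairs"] = tuple(
            tuple(tuple(p) for p in pairs) for pairs in gen["confusion_pairs"]
        )
    return gen
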