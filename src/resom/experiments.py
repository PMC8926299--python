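"""Desk-scale fusion and pruning experiments on the synthetic benchmark.

These runs reproduce, at small scale, the two qualitative behaviours the
architecture is built for: multimodal fusion beating every single modality
when the modalities confuse *different* class pairs, and accuracy surviving
aggressive pruning of the weakest lateral connections.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .hebbian import nonzero_fraction
from .model import ReSOM
from .synthetic import GeneratorSpec, generate

__all__ = ["fusion_experiment"]


def fusion_experiment(
    n_seeds: int = 10,
    seed: int = 0,
    spec: GeneratorSpec | None = None,
    grid_shape: tuple[int, int] = (10, 10),
    epochs: int = 5,
    mu: float = 1.0,
    keep_fraction: float = 0.1,
) -> pd.DataFrame:
    """Run the two-modality benchmark across ``n_seeds`` replicates.

    Each replicate regenerates the synthetic study (fresh data seed), fits a
    ReSOM (maps, laterals, unimodal label table), and measures on the test
    split: each modality's plain post-labeled SOM accuracy, the fused ReSOM
    accuracy, and the fused accuracy after pruning the laterals down to
    ``keep_fraction`` of their nonzero weights.

    Returns a DataFrame with one row per replicate and columns
    ``acc_mod<j>``, ``best_unimodal``, ``resom``, ``resom_pruned``.
    """
    base = GeneratorSpec() if spec is None else spec
    rows = []
    for r in range(n_seeds):
        data_seed = (seed + 9973 * r) % (2**31 - 1)
        train, label, test = generate(replace(base, seed=data_seed))
        est = ReSOM(train, [grid_shape] * base.k, mu=mu, epochs=epochs)
        res = est.fit(label_data=label, n_classes=base.n_classes,
                      seed=data_seed)
        row = {}
        uni = []
        for j in range(base.k):
            acc = res.unimodal(j).evaluate(test.select_modalities([j])).accuracy
            row[f"acc_mod{j}"] = acc
            uni.append(acc)
        row["best_unimodal"] = max(uni)
        row["resom"] = res.evaluate(test).accuracy
        row["resom_pruned"] = res.prune(keep_fraction).evaluate(test).accuracy
        row["nonzero_fraction"] = float(np.mean(
            [nonzero_fraction(lat) for lat in res.model.laterals.values()]))
        rows.append(row)
    return pd.DataFrame(rows, index=pd.RangeIndex(n_seeds, name="replicate"))
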