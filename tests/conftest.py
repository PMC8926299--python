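import numpy as np
import pytest

from resom import GeneratorSpec, ReSOM, generate
from resom.experiments import fusion_experiment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_benchmark():
    """A small but non-trivial two-modality problem plus a fitted network."""
    spec = GeneratorSpec(n_train=400, n_label=100, n_test=200, seed=7)
    train, label, test = generate(spec)
    res = ReSOM(train, [(6, 6), (6, 6)], epochs=3).fit(
        label_data=label, n_classes=spec.n_classes, seed=7
    )
    return spec, train, label, test, res


@pytest.fixture(scope="session")
def fusion_runs():
    """The full-scale fusion/pruning study: 10 replicates at the default
    study conditions (2,000 train / 200 label / 500 test, 10x10 maps)."""
    return fusion_experiment(n_seeds=10, seed=0)
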