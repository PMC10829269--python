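import numpy as np
import pytest

from predictefc import SynthConfig, generate_dataset
from predictefc.rakel_core import BaseClassifierSpec
from predictefc.synthetic import generate_worked_example


@pytest.fixture(scope="session")
def worked_example():
    """8 proteins, 3 classes, 5 terms; hand-auditable."""
    return generate_worked_example()


@pytest.fixture(scope="session")
def separable_corpus():
    """Small exclusive-signal corpus: every term determines its class."""
    ds, truth = generate_dataset(
        SynthConfig(n_proteins=300, L=7, exclusivity=1.0, noise_terms=0.0,
                    n_shared_terms=0, multi_label_rate=0.03, seed=42)
    )
    return ds, truth


@pytest.fixture(scope="session")
def noisy_corpus():
    """Default-regime corpus: shared terms, leakage, noise."""
    ds, truth = generate_dataset(SynthConfig(n_proteins=400, seed=7))
    return ds, truth


@pytest.fixture
def rf_small():
    return BaseClassifierSpec("random_forest", {"n_trees": 30})


def random_label_sets(rng: np.random.Generator, n: int, L: int, allow_empty_pred=True):
    """Random (true, pred) labelset pairs; true sets always nonempty."""
    true, pred = [], []
    for _ in range(n):
        t = rng.random(L) < rng.uniform(0.1, 0.6)
        if not t.any():
            t[rng.integers(L)] = True
        p = rng.random(L) < rng.uniform(0.0, 0.6)
        if not allow_empty_pred and not p.any():
            p[rng.integers(L)] = True
        true.append(frozenset(int(j + 1) for j in np.flatnonzero(t)))
        pred.append(frozenset(int(j + 1) for j in np.flatnonzero(p)))
    return true, pred
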