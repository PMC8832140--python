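import numpy as np
import pytest

from normbench import (
    CountMatrix,
    GroupAssignment,
    SyntheticSpec,
    fixture_small,
    generate_paired_study,
)


@pytest.fixture(scope="session")
def small_study():
    """Deterministic 50-marker x 12-sample paired study."""
    return fixture_small()


@pytest.fixture(scope="session")
def study54():
    """A 54-sample synthetic study matching the motivating design size."""
    spec = SyntheticSpec(n_markers=150, n_per_group=27, seed=7)
    study, _ = generate_paired_study(spec)
    return study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(counts, prefix_m="m", prefix_s="s"):
    counts = np.asarray(counts, dtype=float)
    g, n = counts.shape
    return CountMatrix(
        tuple(f"{prefix_m}{i}" for i in range(g)),
        tuple(f"{prefix_s}{j}" for j in range(n)),
        counts,
    )


def make_groups(cm: CountMatrix, split=None):
    n = cm.n_samples
    split = n // 2 if split is None else split
    return GroupAssignment(cm.sample_ids,
                           tuple(["A"] * split + ["B"] * (n - split)))
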