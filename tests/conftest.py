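import numpy as np
import pandas as pd
import pytest

from enhrev import CountMatrix


def nb_counts(rng, mean, alpha, size):
    """NB draws with var = mu + alpha mu^2."""
    mean = np.asarray(mean, dtype=float)
    if alpha < 1e-8:
        return rng.poisson(np.broadcast_to(mean, size))
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mean), size=size)


def two_group_matrix(counts, groups=("Chow", "HFD")):
    """Wrap a features x (2*n) count array as a CountMatrix, n per group."""
    n_samples = counts.shape[1]
    per = n_samples // 2
    meta = pd.DataFrame(
        {
            "group": [groups[0]] * per + [groups[1]] * (n_samples - per),
            "replicate": list(range(1, per + 1)) * 2,
        },
        index=[f"s{i}" for i in range(n_samples)],
    )
    df = pd.DataFrame(
        counts,
        columns=meta.index,
        index=[f"f{i}" for i in range(counts.shape[0])],
    )
    return CountMatrix(df, meta)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
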