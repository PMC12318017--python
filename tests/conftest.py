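import numpy as np
import pytest

import teamfuse as tf


@pytest.fixture(scope="session")
def small_session():
    """2v2, 30 s session with nominal sensor corruption."""
    cfg = tf.SimConfig(n_athletes_per_team=2, duration_s=30.0, seed=11)
    return tf.simulate_session(cfg)


@pytest.fixture(scope="session")
def clean_session():
    """2v2, 30 s session with every stochastic term off."""
    cfg = tf.SimConfig(n_athletes_per_team=2, duration_s=30.0, seed=11).noiseless()
    return tf.simulate_session(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def brute_force_dtw(x, y):
    """Exhaustive minimum over all admissible monotone warping paths."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n, m = len(x), len(y)
    best = {}

    def rec(i, j):
        if (i, j) in best:
            return best[(i, j)]
        d = abs(x[i] - y[j])
        if i == 0 and j == 0:
            val = d
        elif i == 0:
            val = d + rec(0, j - 1)
        elif j == 0:
            val = d + rec(i - 1, 0)
        else:
            val = d + min(rec(i - 1, j), rec(i - 1, j - 1), rec(i, j - 1))
        best[(i, j)] = val
        return val

    return rec(n - 1, m - 1)
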