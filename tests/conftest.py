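import numpy as np
import pytest

from slsbayes import (
    DesignConfig,
    TruthConfig,
    error_level_to_sigma2_u,
    generate_dataset,
    prior_treatment,
)


def make_step_trace(plateaus, n_per=120, noise=0.0, seed=0, spikes=None):
    """Synthetic staircase trace: buffer, levels..., buffer.

    ``plateaus`` are the full plateau values including both buffers.
    ``spikes`` is an optional list of (plateau_index, offset_within, value).
    Returns (time_s, intensity).
    """
    rng = np.random.default_rng(seed)
    y = np.concatenate([np.full(n_per, v, dtype=float) for v in plateaus])
    if noise > 0:
        y += rng.normal(0.0, noise, size=y.size)
    if spikes:
        for seg, off, val in spikes:
            y[seg * n_per + off] = val
    t = np.arange(y.size, dtype=float)
    return t, y


@pytest.fixture
def small_dataset():
    """One condition, one replicate, 5% concentration error, A2 = 1e-4."""
    truth = TruthConfig(A2=(1e-4,), sigma2_u=error_level_to_sigma2_u(5.0))
    return generate_dataset(truth, DesignConfig(replicates=1), seed=11), truth


@pytest.fixture
def informative_priors(small_dataset):
    _, truth = small_dataset
    return prior_treatment("informative", truth.sigma2_u)
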