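"""Shared fixtures: small generative configurations used across modules."""

import numpy as np
import pytest

from panelgvar.simulate import SimConfig, generate_population


def make_config(
    p=4,
    n=500,
    T=6,
    cross=((1, 0, 0.25),),
    binarize=False,
    missing=0.0,
    seed=0,
    between_scale=0.3,
    covariate_effects=None,
):
    """A stationary test configuration with modest autocorrelations and the
    requested planted cross-lagged edges (target, source, weight)."""
    rng = np.random.default_rng(seed + 1000)
    B = np.diag(rng.uniform(0.05, 0.15, p))
    for i, j, w in cross:
        B[i, j] = w
    W = np.eye(p)
    W[p - 1, p - 2] = W[p - 2, p - 1] = 0.15
    quant = np.full(p, 0.75) if binarize else None
    return SimConfig(
        n_individuals=n,
        temporal_matrix=B,
        contemporaneous_pcor=W,
        between_cov=between_scale * np.eye(p),
        n_waves=T,
        covariate_effects=covariate_effects or {},
        binarize_quantiles=quant,
        missing_wave_rate=missing,
        seed=seed,
    )


@pytest.fixture
def small_config():
    return make_config()


@pytest.fixture
def small_panel(small_config):
    return generate_population(small_config)
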