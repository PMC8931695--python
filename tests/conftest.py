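import numpy as np
import pandas as pd
import pytest

from stoplatent import (NeuroGenConfig, PhenotypeGenConfig, SSTGenConfig,
                        generate_betas, generate_symptoms)
from stoplatent.simulate import _default_ri_blocks


@pytest.fixture(scope="session")
def default_symptoms_10k():
    """Default 4-class symptom draw, n=10,000 (shared across recovery tests)."""
    cfg = PhenotypeGenConfig(seed=101)
    table, labels = generate_symptoms(cfg, 10_000)
    return table, labels, cfg


@pytest.fixture(scope="session")
def ri_betas_5k():
    """Single-group response-inhibition betas at the published loadings."""
    cfg = NeuroGenConfig(
        factor_blocks=_default_ri_blocks(),
        group_latent_means=np.zeros((1, 1)),
        site_sd=0.0,
        seed=202,
    )
    betas = generate_betas(cfg, np.zeros(5000, dtype=int))
    return betas, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def make_group_betas(alphas, n_per_group, seed, loadings=(0.91, 0.86, 0.68, 0.51),
                     intercept_shift=None):
    """Two-or-more-group single-factor betas with optional intercept shift.

    ``intercept_shift`` = (group index, indicator index, shift) injects a
    scalar-invariance violation.
    """
    rng = np.random.default_rng(seed)
    lam = np.asarray(loadings, float)
    rows, groups = [], []
    for g, (alpha, n) in enumerate(zip(alphas, n_per_group)):
        eta = alpha + rng.standard_normal(n)
        eps = rng.standard_normal((n, lam.size)) * np.sqrt(1 - lam**2)
        Y = eta[:, None] * lam[None, :] + eps
        if intercept_shift is not None and intercept_shift[0] == g:
            Y[:, intercept_shift[1]] += intercept_shift[2]
        rows.append(Y)
        groups.extend([f"g{g}"] * n)
    cols = [f"region_{j}" for j in range(lam.size)]
    Y = pd.DataFrame(np.vstack(rows), columns=cols)
    cats = [f"g{g}" for g in range(len(alphas))]
    return Y, pd.Categorical(groups, categories=cats), cols
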