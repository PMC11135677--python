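import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from urbantol.grid import GridSpec
from urbantol.pipeline import run_synthetic_study


@pytest.fixture(scope="session")
def study():
    """One full synthetic-study pipeline run under the default conditions.

    Session-scoped: several invariant suites inspect the same run.
    """
    return run_synthetic_study(seed=1)


@pytest.fixture
def unit_grid():
    """A tiny 4x4 grid in plain grid units (no CRS), cell size 1."""
    return GridSpec(n_rows=4, n_cols=4, cell_size=1.0, origin=(0.0, 0.0), crs=None)


def binomial_loglik(alpha, beta, k, E, x):
    """Binomial log-likelihood surface, broadcastable over (alpha, beta)."""
    eta = alpha[..., None] + beta[..., None] * x
    p = expit(eta)
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return (k * np.log(p) + (E - k) * np.log1p(-p)).sum(axis=-1)


def grid_search_slope(k, E, x, span=8.0, coarse=0.1, refinements=6):
    """Brute-force MLE of (alpha, beta) for k ~ Binom(E, expit(a + b x)).

    Independent of the GLM route: an exhaustive coarse grid over the
    parameter plane followed by successive local grid refinements, down to
    a resolution well below 1e-4.
    """
    k = np.asarray(k, float)
    E = np.asarray(E, float)
    x = np.asarray(x, float)
    a_lo, a_hi, b_lo, b_hi = -span, span, -span, span
    step = coarse
    best = (0.0, 0.0)
    for _ in range(refinements + 1):
        alphas = np.arange(a_lo, a_hi + step / 2, step)
        betas = np.arange(b_lo, b_hi + step / 2, step)
        A, B = np.meshgrid(alphas, betas, indexing="ij")
        ll = binomial_loglik(A, B, k, E, x)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        best = (alphas[i], betas[j])
        a_lo, a_hi = best[0] - 2 * step, best[0] + 2 * step
        b_lo, b_hi = best[1] - 2 * step, best[1] + 2 * step
        step /= 5.0
    return best


def make_binomial_rows(species_id, k, E, cell_ids=None, group="g"):
    """Assemble a binomial-table fragment for one species."""
    k = np.asarray(k)
    if cell_ids is None:
        cell_ids = np.arange(len(k))
    return pd.DataFrame({
        "species_id": species_id,
        "group": group,
        "cell_id": np.asarray(cell_ids),
        "k": k,
        "E": np.asarray(E),
    })
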