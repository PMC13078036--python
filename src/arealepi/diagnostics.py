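"""Residual diagnostics: overdispersion and zero inflation.

Both tests are parametric-bootstrap checks against the fitted model, in the
style of simulation-based residual diagnostics for hierarchical count
models: simulate replicate datasets from the fitted means, compare the
observed statistic with its simulation distribution, and report a
two-sided bootstrap p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DispersionTest",
    "ZeroInflationTest",
    "dispersion_test",
    "zero_inflation_test",
    "fit_poisson_glm",
]


@dataclass
class DispersionTest:
    statistic: float
    p_value: float
    n_sim: int


@dataclass
class ZeroInflationTest:
    observed_zeros: int
    expected_zeros: float
    p_value: float
    n_sim: int


def _simulate(rng: np.random.Generator, mu: np.ndarray, r: float | None) -> np.ndarray:
    if r is None or np.isinf(r):
        return rng.poisson(mu)
    return rng.negative_binomial(r, r / (r + mu))


def dispersion_test(
    y: np.ndarray, mu: np.ndarray, n_sim: int = 250, seed: int | None = None
) -> DispersionTest:
    """Overdispersion check on a Poisson fit.

    The statistic is the observed sum of squared Pearson residuals divided
    by the mean of the same quantity over ``n_sim`` Poisson datasets
    simulated from the fitted means; values well above 1 indicate
    overdispersion.  p is two-sided from the bootstrap rank.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    rng = np.random.default_rng(seed)
    d_obs = float(np.sum((y - mu) ** 2 / mu))
    sims = np.empty(n_sim)
    for k in range(n_sim):
        ys = rng.poisson(mu)
        sims[k] = np.sum((ys - mu) ** 2 / mu)
    stat = d_obs / sims.mean()
    ge = int((sims >= d_obs).sum())
    le = int((sims <= d_obs).sum())
    p = min(1.0, 2.0 * min(1 + ge, 1 + le) / (n_sim + 1))
    return DispersionTest(statistic=float(stat), p_value=float(p), n_sim=n_sim)


def zero_inflation_test(
    y: np.ndarray,
    mu: np.ndarray,
    r: float | None = None,
    n_sim: int = 250,
    seed: int | None = None,
) -> ZeroInflationTest:
    """Excess-zero check against the fitted (Poisson or NB) model.

    Compares the observed number of zero counts with its parametric
    bootstrap distribution; the p-value doubles the smaller tail
    probability (capped at 1), so a fitted model that reproduces its own
    zeros gives p near 1.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    rng = np.random.default_rng(seed)
    z_obs = int((y == 0).sum())
    sims = np.empty(n_sim)
    for k in range(n_sim):
        sims[k] = (_simulate(rng, mu, r) == 0).sum()
    ge = int((sims >= z_obs).sum())
    le = int((sims <= z_obs).sum())
    p = min(1.0, 2.0 * min(1 + ge, 1 + le) / (n_sim + 1))
    return ZeroInflationTest(
        observed_zeros=z_obs,
        expected_zeros=float(sims.mean()),
        p_value=float(p),
        n_sim=n_sim,
    )


def fit_poisson_glm(panel: pd.DataFrame, terms: list[str]):
    """Standard (fixed-effects only) Poisson GLM with log expected-count
    offset — the baseline whose residuals feed the dispersion test.

    Returns the statsmodels results object; fitted means are ``.mu``.
    """
    import statsmodels.api as sm

    from .design import build_design

    x, _ = build_design(panel, terms)
    keep = ~np.isnan(x).any(axis=1)
    x = sm.add_constant(x[keep])
    y = panel.loc[keep, "cases"].to_numpy(dtype=float)
    offset = np.log(panel.loc[keep, "expected"].to_numpy(dtype=float))
    model = sm.GLM(y, x, family=sm.families.Poisson(), offset=offset)
    return model.fit()
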