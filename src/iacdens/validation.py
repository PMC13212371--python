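"""Parameter-recovery simulations: the estimator-validation loops.

Each routine generates synthetic cohorts under known truths, re-estimates
with the package's own fitters, and summarizes recovery: mean estimates
across seeds and Wald-interval coverage across replicates.  These are the
workhorses behind the repository's reproducibility script and the
recovery tests.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .cohort import (
    COVARIATE_ORDER,
    DEFAULT_LINEAR_BETAS,
    DEFAULT_LOG_ODDS,
    DEFAULT_TARGET_SPEARMAN,
    CovariateSpec,
    EffectSpec,
    simulate_cohort,
    simulate_covariates,
    simulate_density_volume_pairs,
    simulate_linear_outcome,
    simulate_ordinal_outcome,
)
from .stats import _spearman, fit_linear_standardized, fit_proportional_odds

__all__ = [
    "ordinal_recovery",
    "ordinal_ci_coverage",
    "spearman_recovery",
    "linear_recovery",
    "linear_ci_coverage",
]


def _child_seeds(base_seed: int, n: int) -> list:
    ss = np.random.SeedSequence(base_seed)
    return [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(n)]


def ordinal_recovery(
    n: int = 2040,
    n_seeds: int = 20,
    base_seed: int = 0,
    effects: Optional[EffectSpec] = None,
) -> pd.DataFrame:
    """Refit the proportional-odds model on ``n_seeds`` synthetic cohorts.

    Returns one row per covariate with the generating odds ratio, the
    mean and SD of the estimated odds ratios across seeds, and the mean
    coefficient on the log scale.
    """
    effects = effects or EffectSpec()
    terms = list(effects.log_odds)
    ors = np.empty((n_seeds, len(terms)))
    for i, seed in enumerate(_child_seeds(base_seed, n_seeds)):
        table = simulate_cohort(n=n, seed=seed, effects=effects)
        fit = fit_proportional_odds(table[terms], table["density_category"].to_numpy())
        if not fit.converged:
            raise RuntimeError(f"ordinal fit failed to converge for seed {seed}")
        ors[i] = fit.odds_ratios
    return pd.DataFrame(
        {
            "term": terms,
            "true_or": [float(np.exp(effects.log_odds[t])) for t in terms],
            "mean_or": ors.mean(axis=0),
            "sd_or": ors.std(axis=0, ddof=1),
            "mean_coef": np.log(ors).mean(axis=0),
            "n": n,
            "n_seeds": n_seeds,
        }
    )


def ordinal_ci_coverage(
    n: int = 2040,
    n_reps: int = 200,
    base_seed: int = 1,
    effects: Optional[EffectSpec] = None,
) -> pd.DataFrame:
    """Empirical coverage of the 95% Wald interval for each odds ratio."""
    effects = effects or EffectSpec()
    terms = list(effects.log_odds)
    truth = np.array([effects.log_odds[t] for t in terms])
    hits = np.zeros(len(terms))
    for seed in _child_seeds(base_seed, n_reps):
        table = simulate_cohort(n=n, seed=seed, effects=effects)
        fit = fit_proportional_odds(table[terms], table["density_category"].to_numpy())
        z = 1.959963984540054
        lo = fit.coef - z * fit.se
        hi = fit.coef + z * fit.se
        hits += (lo <= truth) & (truth <= hi)
    return pd.DataFrame(
        {"term": terms, "coverage": hits / n_reps, "n_reps": n_reps, "n": n}
    )


def spearman_recovery(
    n: int = 2040,
    n_seeds: int = 50,
    base_seed: int = 2,
    target: float = DEFAULT_TARGET_SPEARMAN,
) -> Tuple[np.ndarray, float]:
    """Sample Spearman rho per seed for copula pairs; returns (rhos, mean)."""
    rhos = np.empty(n_seeds)
    for i, seed in enumerate(_child_seeds(base_seed, n_seeds)):
        pairs = simulate_density_volume_pairs(n, target_spearman=target, seed=seed)
        rhos[i] = _spearman(
            pairs["ln_density"].to_numpy(), pairs["ln_volume_plus1"].to_numpy()
        )
    return rhos, float(rhos.mean())


def linear_recovery(
    n: int = 2040,
    n_seeds: int = 20,
    base_seed: int = 3,
    betas: Optional[Dict[str, float]] = None,
) -> pd.DataFrame:
    """OLS refits of synthetic standardized ln-density outcomes."""
    betas = dict(DEFAULT_LINEAR_BETAS if betas is None else betas)
    terms = list(betas)
    est = np.empty((n_seeds, len(terms)))
    for i, seed in enumerate(_child_seeds(base_seed, n_seeds)):
        ss = np.random.SeedSequence(seed)
        g_cov, g_out = (np.random.default_rng(c) for c in ss.spawn(2))
        cov = simulate_covariates(CovariateSpec(), n, g_cov)
        y = simulate_linear_outcome(cov, betas, g_out)
        fit = fit_linear_standardized(cov[terms], y)
        est[i] = fit.coef
    return pd.DataFrame(
        {
            "term": terms,
            "true_beta": [betas[t] for t in terms],
            "mean_beta": est.mean(axis=0),
            "sd_beta": est.std(axis=0, ddof=1),
            "n": n,
            "n_seeds": n_seeds,
        }
    )


def linear_ci_coverage(
    n: int = 2040,
    n_reps: int = 200,
    base_seed: int = 4,
    betas: Optional[Dict[str, float]] = None,
    term: str = "hypertension",
) -> float:
    """Empirical 95%-CI coverage for one linear-model coefficient."""
    betas = dict(DEFAULT_LINEAR_BETAS if betas is None else betas)
    terms = list(betas)
    j = terms.index(term)
    truth = betas[term]
    hits = 0
    for seed in _child_seeds(base_seed, n_reps):
        ss = np.random.SeedSequence(seed)
        g_cov, g_out = (np.random.default_rng(c) for c in ss.spawn(2))
        cov = simulate_covariates(CovariateSpec(), n, g_cov)
        y = simulate_linear_outcome(cov, betas, g_out)
        fit = fit_linear_standardized(cov[terms], y)
        if fit.ci_low[j] <= truth <= fit.ci_high[j]:
            hits += 1
    return hits / n_reps
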