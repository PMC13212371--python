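"""Synthetic cohort generator for the inference testbed.

Simulates a community-dwelling older-adult cohort with the covariate
marginals of the source population (age 69.7 +/- 6.8 years truncated at
55, 51.9% female, 74.2% hypertensive, ...), a 7-level ordinal maximum
calcification-density outcome generated under a proportional-odds model
with specified log-odds effects, rank-correlated ln-density / ln-volume
pairs via a Gaussian copula, and artery-level Kockelkoren scores with
log-normal per-subtype density distributions.

Covariates are drawn independently: the source publication reports only
marginal distributions, so no joint structure is imposed.  This is a
deliberate simplification — adequate for estimator-recovery testing,
not for emulating real confounding.

All randomness flows from one master seed through spawned substreams, so
each component is independently reproducible and a fixed seed yields a
bit-identical cohort table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "BINARY_PREVALENCES",
    "CONTINUOUS_MARGINALS",
    "DEFAULT_LOG_ODDS",
    "DEFAULT_CUTPOINTS",
    "DEFAULT_TARGET_SPEARMAN",
    "SUBTYPE_SCORE_RANGES",
    "SUBTYPE_DENSITY_QUARTILES",
    "SUBTYPE_WEIGHTS",
    "CovariateSpec",
    "EffectSpec",
    "simulate_covariates",
    "simulate_ordinal_outcome",
    "simulate_density_volume_pairs",
    "simulate_subtype_arteries",
    "simulate_cohort",
    "lognormal_params_from_quartiles",
]

_Z75 = sps.norm.ppf(0.75)  # 0.6744897501960817

#: Binary covariate prevalences in the emulated population.
BINARY_PREVALENCES: Dict[str, float] = {
    "female": 0.519,
    "ever_smoking": 0.697,  # former 54.4% + current 15.3%
    "obesity": 0.241,
    "hypertension": 0.742,
    "diabetes": 0.112,
    "lipid_med": 0.244,
    "chd": 0.092,
    "cva": 0.063,
    "scanner_64": 1691 / 2464,
}

#: Continuous covariates: (mean, sd, lower truncation bound).
CONTINUOUS_MARGINALS: Dict[str, Tuple[float, float, float]] = {
    "age": (69.7, 6.8, 55.0),  # cohort enrolled participants aged >= 55
    "non_hdl": (4.2, 1.0, 1.0),  # mmol/L; truncated to a plausible floor
}

COVARIATE_ORDER = (
    "age",
    "female",
    "ever_smoking",
    "obesity",
    "hypertension",
    "diabetes",
    "non_hdl",
    "lipid_med",
    "chd",
    "cva",
    "scanner_64",
)

#: Generating coefficients on the latent logistic scale: natural logs of
#: the adjusted common odds ratios observed for each determinant of the
#: maximum-density category (age 1.07/y, female 0.65, smoking 1.35,
#: obesity 1.16, hypertension 1.59, diabetes 1.40, non-HDL 1.14/mmol/L,
#: lipid-lowering medication 1.58, CHD 2.59, CVA 1.56, 64-slice 0.94).
DEFAULT_LOG_ODDS: Dict[str, float] = {
    "age": float(np.log(1.07)),
    "female": float(np.log(0.65)),
    "ever_smoking": float(np.log(1.35)),
    "obesity": float(np.log(1.16)),
    "hypertension": float(np.log(1.59)),
    "diabetes": float(np.log(1.40)),
    "non_hdl": float(np.log(1.14)),
    "lipid_med": float(np.log(1.58)),
    "chd": float(np.log(2.59)),
    "cva": float(np.log(1.56)),
    "scanner_64": float(np.log(0.94)),
}

#: Default cutpoints alpha_1..alpha_6 of the proportional-odds generator.
#: The published category frequencies are shown only graphically, so these
#: are free parameters: they were fixed once as the latent-scale quantiles
#: that give marginal category probabilities (8, 14, 16, 22, 16, 14, 10)%
#: under the default covariate marginals and effects above (every category
#: probability >= 2%, so fits never face empty categories).
DEFAULT_CUTPOINTS: Tuple[float, ...] = (
    3.2510,
    4.4862,
    5.3272,
    6.3156,
    7.1355,
    8.2486,
)

#: Population rank correlation between ln-density and ln-volume.
DEFAULT_TARGET_SPEARMAN = 0.67

#: Generating coefficients for the continuous outcome model: effect of
#: each covariate on the *standardized* ln mean density (SDs of ln(HU)
#: per unit of the covariate; age per year, non-HDL per mmol/L).
DEFAULT_LINEAR_BETAS: Dict[str, float] = {
    "age": 0.02,
    "female": -0.26,
    "ever_smoking": 0.17,
    "obesity": 0.03,
    "hypertension": 0.21,
    "diabetes": 0.18,
    "non_hdl": 0.08,
    "lipid_med": 0.23,
    "chd": 0.51,
    "cva": 0.13,
    "scanner_64": -0.08,
}

#: Marginals for the density/volume pair: (median, q1, q3) on the raw
#: scale; density in HU (232, IQR 189-287), volume in mm^3 (67, IQR 22-189,
#: stored with the +1 mm^3 offset before the log).
DENSITY_QUARTILES = (232.0, 189.0, 287.0)
VOLUME_QUARTILES = (67.0, 22.0, 189.0)

#: Kockelkoren score ranges and artery-level mixture weights per subtype
#: (intimal 20.5%, ambiguous 56.6%, medial 23.0% of scored carotids).
SUBTYPE_SCORE_RANGES = {"intimal": (0, 4), "ambiguous": (5, 8), "medial": (9, 19)}
SUBTYPE_WEIGHTS = {"intimal": 0.205, "ambiguous": 0.566, "medial": 0.230}
#: Artery-level mean-density (median, q1, q3) per subtype, HU.
SUBTYPE_DENSITY_QUARTILES = {
    "intimal": (210.0, 179.0, 264.0),
    "ambiguous": (255.0, 198.0, 310.0),
    "medial": (294.0, 230.0, 351.0),
}


@dataclass
class CovariateSpec:
    binary: Dict[str, float] = field(default_factory=lambda: dict(BINARY_PREVALENCES))
    continuous: Dict[str, Tuple[float, float, float]] = field(
        default_factory=lambda: dict(CONTINUOUS_MARGINALS)
    )

    def validate(self) -> None:
        for name, p in self.binary.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence of {name!r} must lie in [0, 1], got {p}")
        for name, (mean, sd, lower) in self.continuous.items():
            if sd <= 0:
                raise ValueError(f"sd of {name!r} must be positive, got {sd}")


@dataclass
class EffectSpec:
    """Latent-scale coefficients and cutpoints of the ordinal generator."""

    log_odds: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LOG_ODDS))
    cutpoints: Tuple[float, ...] = DEFAULT_CUTPOINTS

    def validate(self) -> None:
        cp = tuple(self.cutpoints)
        if any(b <= a for a, b in zip(cp, cp[1:])):
            raise ValueError(f"cutpoints must be strictly increasing: {cp}")
        for name, b in self.log_odds.items():
            if not np.isfinite(b):
                raise ValueError(f"coefficient for {name!r} is not finite")

    @property
    def n_categories(self) -> int:
        return len(self.cutpoints) + 1


def lognormal_params_from_quartiles(median: float, q1: float, q3: float):
    """(mu, sigma) of the log-normal with the given median and quartiles.

    sigma is matched to the IQR on the log scale: sigma = ln(q3/q1)/(2 z_75).
    """
    if not 0 < q1 < median < q3:
        raise ValueError("need 0 < q1 < median < q3")
    mu = float(np.log(median))
    sigma = float((np.log(q3) - np.log(q1)) / (2.0 * _Z75))
    return mu, sigma


def simulate_covariates(
    spec: CovariateSpec, n: int, seed: Optional[int | np.random.Generator] = None
) -> pd.DataFrame:
    """Independent draws of every covariate from its stated marginal."""
    if n < 1:
        raise ValueError("n must be >= 1")
    spec.validate()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cols: Dict[str, np.ndarray] = {}
    for name, (mean, sd, lower) in spec.continuous.items():
        a = (lower - mean) / sd
        cols[name] = sps.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)
    for name, p in spec.binary.items():
        cols[name] = (rng.random(n) < p).astype(np.int64)
    order = [c for c in COVARIATE_ORDER if c in cols] + [
        c for c in cols if c not in COVARIATE_ORDER
    ]
    return pd.DataFrame({c: cols[c] for c in order})


def simulate_ordinal_outcome(
    covariates: pd.DataFrame,
    effects: EffectSpec,
    seed: Optional[int | np.random.Generator] = None,
) -> np.ndarray:
    """Draw the ordinal category 1..K under the proportional-odds model.

    The latent score is u = x'beta + eps with standard-logistic eps;
    category k is assigned when alpha_{k-1} < u <= alpha_k, which is
    equivalent to P(Y <= k | x) = logistic(alpha_k - x'beta).
    """
    effects.validate()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    missing = [c for c in effects.log_odds if c not in covariates.columns]
    if missing:
        raise ValueError(f"covariate table lacks columns {missing}")
    eta = np.zeros(len(covariates))
    for name, beta in effects.log_odds.items():
        eta += beta * covariates[name].to_numpy(dtype=float)
    u = eta + rng.logistic(size=len(covariates))
    return np.searchsorted(np.asarray(effects.cutpoints), u, side="left") + 1


def simulate_linear_outcome(
    covariates: pd.DataFrame,
    betas: Optional[Dict[str, float]] = None,
    seed: Optional[int | np.random.Generator] = None,
) -> np.ndarray:
    """Standardized ln-density outcome under the linear determinants model.

    y = x'beta + eps with normal noise scaled so the outcome has unit
    variance (the betas are on the standardized-outcome scale, so the
    systematic part must leave room for the residual).
    """
    betas = dict(DEFAULT_LINEAR_BETAS if betas is None else betas)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    missing = [c for c in betas if c not in covariates.columns]
    if missing:
        raise ValueError(f"covariate table lacks columns {missing}")
    eta = np.zeros(len(covariates))
    for name, b in betas.items():
        eta += b * covariates[name].to_numpy(dtype=float)
    var_eta = float(np.var(eta))
    if var_eta >= 0.95:
        raise ValueError(
            f"systematic variance {var_eta:.3f} leaves no room for unit-variance noise"
        )
    sigma = np.sqrt(1.0 - var_eta)
    return eta + rng.normal(0.0, sigma, size=len(covariates))


def simulate_density_volume_pairs(
    n: int,
    target_spearman: float = DEFAULT_TARGET_SPEARMAN,
    density_quartiles: Tuple[float, float, float] = DENSITY_QUARTILES,
    volume_quartiles: Tuple[float, float, float] = VOLUME_QUARTILES,
    seed: Optional[int | np.random.Generator] = None,
) -> pd.DataFrame:
    """Rank-correlated (ln_density, ln_volume_plus1) pairs via Gaussian copula.

    For a bivariate normal, the population Spearman correlation is
    rho_S = (6/pi) * arcsin(r/2); inverting, the Pearson parameter is set
    to r = 2 sin(pi rho_S / 6) so the copula's rank correlation equals the
    target exactly.  Margins are then transformed to log-normals with the
    requested median/IQR (monotone transforms, so the rank correlation is
    preserved).
    """
    if not abs(target_spearman) < 1.0:
        raise ValueError(f"|target_spearman| must be < 1, got {target_spearman}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    r = 2.0 * np.sin(np.pi * target_spearman / 6.0)
    cov = np.array([[1.0, r], [r, 1.0]])
    z = rng.multivariate_normal(np.zeros(2), cov, size=n, method="cholesky")
    mu_d, sg_d = lognormal_params_from_quartiles(*density_quartiles)
    med_v, q1_v, q3_v = volume_quartiles
    # +1 mm^3 offset applied before the log, matching the volume transform
    mu_v, sg_v = lognormal_params_from_quartiles(med_v + 1.0, q1_v + 1.0, q3_v + 1.0)
    return pd.DataFrame(
        {
            "ln_density": mu_d + sg_d * z[:, 0],
            "ln_volume_plus1": mu_v + sg_v * z[:, 1],
        }
    )


def simulate_subtype_arteries(
    n_arteries: int,
    weights: Optional[Dict[str, float]] = None,
    density_quartiles: Optional[Dict[str, Tuple[float, float, float]]] = None,
    seed: Optional[int | np.random.Generator] = None,
) -> pd.DataFrame:
    """Artery-level Kockelkoren scores and mean densities per subtype.

    Scores are uniform within each subtype's range; densities are
    log-normal with the subtype's median and IQR-matched sigma.
    """
    weights = dict(SUBTYPE_WEIGHTS if weights is None else weights)
    density_quartiles = dict(
        SUBTYPE_DENSITY_QUARTILES if density_quartiles is None else density_quartiles
    )
    total = sum(weights.values())
    # published percentages carry rounding error (they sum to 100.1%);
    # renormalize within that slack, reject anything further off
    if not np.isclose(total, 1.0, atol=0.01):
        raise ValueError(f"subtype weights must sum to 1, got {total}")
    weights = {k: v / total for k, v in weights.items()}
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    labels = list(weights)
    assignment = rng.choice(len(labels), size=n_arteries, p=[weights[l] for l in labels])
    scores = np.empty(n_arteries, dtype=np.int64)
    dens = np.empty(n_arteries, dtype=float)
    for i, label in enumerate(labels):
        sel = assignment == i
        lo, hi = SUBTYPE_SCORE_RANGES[label]
        scores[sel] = rng.integers(lo, hi + 1, size=sel.sum())
        mu, sigma = lognormal_params_from_quartiles(*density_quartiles[label])
        dens[sel] = np.exp(rng.normal(mu, sigma, size=sel.sum()))
    return pd.DataFrame(
        {
            "artery_index": np.arange(n_arteries),
            "kockelkoren_score": scores,
            "subtype_true": [labels[a] for a in assignment],
            "mean_hu": dens,
        }
    )


def simulate_cohort(
    n: int = 2040,
    seed: int = 0,
    covariate_spec: Optional[CovariateSpec] = None,
    effects: Optional[EffectSpec] = None,
    target_spearman: float = DEFAULT_TARGET_SPEARMAN,
) -> pd.DataFrame:
    """Full cohort table: covariates, ordinal density category, copula pairs.

    One master seed spawns independent substreams for covariates, the
    ordinal outcome, and the density/volume pairs, so each component is
    reproducible in isolation.
    """
    covariate_spec = covariate_spec or CovariateSpec()
    effects = effects or EffectSpec()
    ss = np.random.SeedSequence(seed)
    s_cov, s_ord, s_pair = ss.spawn(3)
    cov = simulate_covariates(covariate_spec, n, np.random.default_rng(s_cov))
    cat = simulate_ordinal_outcome(cov, effects, np.random.default_rng(s_ord))
    pairs = simulate_density_volume_pairs(
        n, target_spearman, seed=np.random.default_rng(s_pair)
    )
    out = cov.copy()
    out.insert(0, "participant_id", [f"P{i:05d}" for i in range(n)])
    out["density_category"] = cat
    out["ln_density"] = pairs["ln_density"].to_numpy()
    out["ln_volume_plus1"] = pairs["ln_volume_plus1"].to_numpy()
    out.attrs["seed"] = seed
    return out
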