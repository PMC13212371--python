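"""Self-implemented inference chain for calcification density analyses.

Four estimators drive the analysis of maximum-density categories and
continuous ln-transformed density/volume measurements:

* tie-aware Spearman rank correlation with a seeded percentile-bootstrap
  confidence interval;
* a proportional-odds (cumulative logit) ordinal regression,
  P(Y <= k | x) = logistic(alpha_k - x'beta), fitted by Newton-Raphson
  with step-halving on reparameterized cutpoints (alpha_1 plus log-gaps)
  so the optimization is unconstrained, with Wald intervals from the
  observed information; exp(beta) is the common odds ratio, > 1 meaning
  higher odds of a *higher* density category;
* OLS on a z-scored ln outcome (the "per SD increase" convention:
  the outcome is standardized, covariates stay on their natural scale),
  solved by QR factorization with classical homoskedastic intervals;
* the sensitivity restriction to participants free of prevalent coronary
  heart disease, cerebrovascular accidents and lipid-lowering medication.

The proportional-odds likelihood uses analytic gradient and Hessian; the
log-likelihood is guaranteed non-decreasing across iterations by step
halving, and each fit records its iteration path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "OrdinalFit",
    "LinearFit",
    "spearman_with_ci",
    "fit_proportional_odds",
    "fit_linear_standardized",
    "restrict_sensitivity",
    "ln_transform",
    "describe_cohort",
    "SENSITIVITY_EXCLUSION_COLUMNS",
]

SENSITIVITY_EXCLUSION_COLUMNS = ("chd", "cva", "lipid_med")

_Z95 = 1.959963984540054


# --------------------------------------------------------------------------
# Spearman correlation with bootstrap CI
# --------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    spearman_rho: float
    ci_low: float
    ci_high: float
    n: int
    n_boot: int
    seed: Optional[int]
    degenerate: bool = False  # constant margin: rho undefined


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of mid-ranks (tie-aware)."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        return np.nan
    return float((rx * ry).sum() / denom)


def spearman_with_ci(
    x: Sequence[float],
    y: Sequence[float],
    n_boot: int = 1000,
    seed: Optional[int] = None,
) -> CorrelationResult:
    """Tie-aware Spearman rho with a percentile-bootstrap 95% CI.

    Bootstrap resamples participants (pairs) with replacement; resamples
    with a constant margin are skipped, and an all-constant input is
    returned flagged as degenerate rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1D samples")
    if x.size < 10:
        raise ValueError(f"need n >= 10 paired observations, got {x.size}")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values are not allowed")
    n = x.size
    rho = _spearman(x, y)
    if np.isnan(rho):
        return CorrelationResult(np.nan, np.nan, np.nan, n, 0, seed, degenerate=True)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boots[b] = _spearman(x[idx], y[idx])
    boots = boots[~np.isnan(boots)]
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return CorrelationResult(rho, float(lo), float(hi), n, n_boot, seed)


# --------------------------------------------------------------------------
# Proportional-odds ordinal regression
# --------------------------------------------------------------------------

@dataclass
class OrdinalFit:
    terms: Tuple[str, ...]
    coef: np.ndarray  # beta, latent-logit scale
    se: np.ndarray
    cutpoints: np.ndarray  # alpha_1..alpha_{K-1}
    cutpoint_se: np.ndarray
    odds_ratios: np.ndarray  # exp(beta)
    or_ci_low: np.ndarray
    or_ci_high: np.ndarray
    loglik: float
    n: int
    n_categories: int
    converged: bool
    n_iter: int
    ll_path: np.ndarray = field(repr=False, default=None)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "coef": self.coef,
                "se": self.se,
                "odds_ratio": self.odds_ratios,
                "ci_low": self.or_ci_low,
                "ci_high": self.or_ci_high,
                "p_value": 2 * sps.norm.sf(np.abs(self.coef / self.se)),
            }
        )


def _logistic_cdf(a: np.ndarray) -> np.ndarray:
    from scipy.special import expit

    return expit(a)


def _po_ll_grad_hess(alpha, beta, X, y, K, want_hess=True):
    """Log-likelihood, gradient and Hessian in the (alpha, beta) space."""
    n, p = X.shape
    eta = X @ beta
    alpha_ext = np.concatenate(([-np.inf], alpha, [np.inf]))
    a_u = alpha_ext[y] - eta  # upper cut for each obs (y in 1..K)
    a_l = alpha_ext[y - 1] - eta
    F_u = np.where(np.isinf(a_u), 1.0, _logistic_cdf(a_u))
    F_l = np.where(np.isinf(a_l), 0.0, _logistic_cdf(a_l))
    P = F_u - F_l
    if np.any(P <= 0):
        return -np.inf, None, None
    ll = float(np.log(P).sum())

    f_u = np.where(np.isinf(a_u), 0.0, F_u * (1.0 - F_u))
    f_l = np.where(np.isinf(a_l), 0.0, F_l * (1.0 - F_l))
    fp_u = f_u * (1.0 - 2.0 * F_u)  # f'(a) = f(a)(1-2F(a))
    fp_l = f_l * (1.0 - 2.0 * F_l)

    du = f_u / P
    dl = f_l / P
    d_eta = -(du - dl)  # d logP / d eta

    m = K - 1
    grad = np.zeros(m + p)
    upper_idx = y - 1  # alpha index used as upper bound (valid when y < K)
    lower_idx = y - 2  # alpha index used as lower bound (valid when y > 1)
    has_u = y < K
    has_l = y > 1
    np.add.at(grad, upper_idx[has_u], du[has_u])
    np.add.at(grad, lower_idx[has_l], -dl[has_l])
    grad[m:] = X.T @ d_eta

    if not want_hess:
        return ll, grad, None

    # per-obs second derivatives
    h_uu = fp_u / P - du**2
    h_ll = -fp_l / P - dl**2
    h_ul = du * dl
    h_ee = (fp_u - fp_l) / P - (du - dl) ** 2
    h_ue = -fp_u / P + du * (du - dl)
    h_le = fp_l / P - dl * (du - dl)

    H = np.zeros((m + p, m + p))
    # alpha-alpha block
    np.add.at(H, (upper_idx[has_u], upper_idx[has_u]), h_uu[has_u])
    np.add.at(H, (lower_idx[has_l], lower_idx[has_l]), h_ll[has_l])
    both = has_u & has_l
    np.add.at(H, (upper_idx[both], lower_idx[both]), h_ul[both])
    np.add.at(H, (lower_idx[both], upper_idx[both]), h_ul[both])
    # alpha-beta block
    for k in range(m):
        sel_u = has_u & (upper_idx == k)
        sel_l = has_l & (lower_idx == k)
        row = np.zeros(p)
        if sel_u.any():
            row += h_ue[sel_u] @ X[sel_u]
        if sel_l.any():
            row += h_le[sel_l] @ X[sel_l]
        H[k, m:] = row
        H[m:, k] = row
    # beta-beta block
    H[m:, m:] = (X * h_ee[:, None]).T @ X
    return ll, grad, H


def _theta_to_alpha(theta_cut: np.ndarray) -> np.ndarray:
    alpha = np.empty_like(theta_cut)
    alpha[0] = theta_cut[0]
    if len(theta_cut) > 1:
        alpha[1:] = theta_cut[0] + np.cumsum(np.exp(theta_cut[1:]))
    return alpha


def _alpha_to_theta(alpha: np.ndarray) -> np.ndarray:
    theta = np.empty_like(alpha)
    theta[0] = alpha[0]
    if len(alpha) > 1:
        theta[1:] = np.log(np.diff(alpha))
    return theta


def _cut_jacobian(theta_cut: np.ndarray) -> np.ndarray:
    """J[k, j] = d alpha_k / d theta_j (lower-triangular)."""
    m = len(theta_cut)
    J = np.zeros((m, m))
    J[:, 0] = 1.0
    for j in range(1, m):
        J[j:, j] = np.exp(theta_cut[j])
    return J


def fit_proportional_odds(
    design: pd.DataFrame | np.ndarray,
    y: Sequence[int],
    max_iter: int = 100,
    grad_tol: float = 1e-8,
    terms: Optional[Sequence[str]] = None,
) -> OrdinalFit:
    """Maximum-likelihood proportional-odds fit by Newton-Raphson.

    ``y`` holds ordinal categories coded 1..K; every category must be
    observed at least once (collapse sparse categories upstream).  The
    cutpoints are optimized as (alpha_1, log successive gaps) so ordering
    is maintained without constraints; standard errors come from the
    observed information at the optimum in the natural (alpha, beta)
    parameterization.
    """
    if isinstance(design, pd.DataFrame):
        terms = tuple(design.columns) if terms is None else tuple(terms)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        terms = tuple(terms) if terms is not None else tuple(
            f"x{j}" for j in range(X.shape[1])
        )
    y = np.asarray(y, dtype=int)
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("y length must match the design")
    cats = np.unique(y)
    K = int(cats.max())
    if cats.min() < 1:
        raise ValueError("categories must be coded 1..K")
    if K < 2:
        raise ValueError("need at least two outcome categories")
    missing_cats = sorted(set(range(1, K + 1)) - set(cats.tolist()))
    if missing_cats:
        raise ValueError(
            f"categories {missing_cats} are unobserved; collapse categories before fitting"
        )
    const_cols = [terms[j] for j in range(p) if np.ptp(X[:, j]) == 0]
    if const_cols:
        raise ValueError(f"constant (separation-inducing) columns: {const_cols}")

    # start: beta = 0, cutpoints at the empirical cumulative logits
    freq = np.array([(y <= k).mean() for k in range(1, K)])
    freq = np.clip(freq, 1e-6, 1 - 1e-6)
    alpha0 = np.log(freq / (1 - freq))
    alpha0 = np.maximum.accumulate(alpha0 + np.arange(K - 1) * 1e-9)
    theta = np.concatenate([_alpha_to_theta(alpha0), np.zeros(p)])
    m = K - 1

    ll_path = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        alpha = _theta_to_alpha(theta[:m])
        beta = theta[m:]
        ll, g_nat, H_nat = _po_ll_grad_hess(alpha, beta, X, y, K)
        ll_path.append(ll)

        J = _cut_jacobian(theta[:m])
        T = np.eye(m + p)
        T[:m, :m] = J
        g = T.T @ g_nat
        H = T.T @ H_nat @ T
        # curvature of the reparameterization: d^2 alpha_k / d theta_j^2
        for j in range(1, m):
            H[j, j] += g_nat[j:m].sum() * np.exp(theta[j])

        sup_g = np.max(np.abs(g))
        if sup_g < grad_tol:
            converged = True
            break
        # stalled at the optimum: the likelihood can no longer improve at
        # float64 resolution and the gradient is already tiny relative to
        # the likelihood scale
        if (
            len(ll_path) >= 2
            and abs(ll_path[-1] - ll_path[-2]) <= 1e-12 * (abs(ll) + 1.0)
            and sup_g < 1e-5
        ):
            converged = True
            break

        try:
            step = np.linalg.solve(-H, g)
        except np.linalg.LinAlgError:
            step = g  # fall back to gradient ascent

        # step-halving: never accept a decrease in log-likelihood
        scale = 1.0
        for _ in range(40):
            cand = theta + scale * step
            ll_new, _, _ = _po_ll_grad_hess(
                _theta_to_alpha(cand[:m]), cand[m:], X, y, K, want_hess=False
            )
            if np.isfinite(ll_new) and ll_new >= ll:
                break
            scale *= 0.5
        else:
            converged = np.max(np.abs(g)) < 1e-5
            break
        theta = cand

    alpha = _theta_to_alpha(theta[:m])
    beta = theta[m:]
    ll, g_nat, H_nat = _po_ll_grad_hess(alpha, beta, X, y, K)
    cov = np.linalg.inv(-H_nat)  # observed information
    se_all = np.sqrt(np.diag(cov))
    se_alpha, se_beta = se_all[:m], se_all[m:]
    or_ = np.exp(beta)
    return OrdinalFit(
        terms=terms,
        coef=beta,
        se=se_beta,
        cutpoints=alpha,
        cutpoint_se=se_alpha,
        odds_ratios=or_,
        or_ci_low=np.exp(beta - _Z95 * se_beta),
        or_ci_high=np.exp(beta + _Z95 * se_beta),
        loglik=ll,
        n=n,
        n_categories=K,
        converged=converged,
        n_iter=it,
        ll_path=np.asarray(ll_path),
    )


# --------------------------------------------------------------------------
# Linear regression on the standardized ln outcome
# --------------------------------------------------------------------------

@dataclass
class LinearFit:
    terms: Tuple[str, ...]
    coef: np.ndarray  # per SD of the ln outcome
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    intercept: float
    residual_sd: float
    r_squared: float
    n: int

    def summary_frame(self) -> pd.DataFrame:
        t = self.coef / self.se
        df = self.n - len(self.terms) - 1
        return pd.DataFrame(
            {
                "term": self.terms,
                "beta": self.coef,
                "se": self.se,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p_value": 2 * sps.t.sf(np.abs(t), df),
            }
        )


def fit_linear_standardized(
    design: pd.DataFrame | np.ndarray,
    y: Sequence[float],
    terms: Optional[Sequence[str]] = None,
) -> LinearFit:
    """OLS of the z-scored outcome on natural-scale covariates.

    The outcome is standardized to mean 0, SD 1 (sample SD, ddof=1), so a
    coefficient reads "SDs of the ln outcome per unit of the covariate".
    Solved via QR; rank deficiency is rejected naming the collinear
    columns.  Classical homoskedastic t-intervals.
    """
    if isinstance(design, pd.DataFrame):
        terms = tuple(design.columns) if terms is None else tuple(terms)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        terms = tuple(terms) if terms is not None else tuple(
            f"x{j}" for j in range(X.shape[1])
        )
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations, got n={n}, p={p}")
    sd_y = y.std(ddof=1)
    if sd_y == 0:
        raise ValueError("outcome is constant; cannot standardize")
    z = (y - y.mean()) / sd_y

    Xd = np.column_stack([np.ones(n), X])
    Q, R = np.linalg.qr(Xd)
    diag = np.abs(np.diag(R))
    bad = diag < max(n, p + 1) * np.finfo(float).eps * diag.max()
    if bad.any():
        names = ["intercept"] + list(terms)
        raise ValueError(
            f"rank-deficient design; collinear columns: {[names[j] for j in np.where(bad)[0]]}"
        )
    coef_full = np.linalg.solve(R, Q.T @ z)
    resid = z - Xd @ coef_full
    dof = n - (p + 1)
    s2 = float(resid @ resid) / dof
    Rinv = np.linalg.inv(R)
    cov = s2 * (Rinv @ Rinv.T)
    se_full = np.sqrt(np.diag(cov))
    tcrit = sps.t.ppf(0.975, dof)
    coef, se = coef_full[1:], se_full[1:]
    ss_tot = float(((z - z.mean()) ** 2).sum())
    return LinearFit(
        terms=terms,
        coef=coef,
        se=se,
        ci_low=coef - tcrit * se,
        ci_high=coef + tcrit * se,
        intercept=float(coef_full[0]),
        residual_sd=float(np.sqrt(s2)),
        r_squared=1.0 - float(resid @ resid) / ss_tot,
        n=n,
    )


# --------------------------------------------------------------------------
# Sensitivity restriction, transforms, descriptives
# --------------------------------------------------------------------------

def restrict_sensitivity(cohort: pd.DataFrame) -> Tuple[pd.DataFrame, int]:
    """Drop participants with prevalent CHD, CVA or lipid-lowering use.

    Returns ``(restricted, n_removed)``.
    """
    missing = [c for c in SENSITIVITY_EXCLUSION_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort lacks required columns {missing}")
    flags = cohort[list(SENSITIVITY_EXCLUSION_COLUMNS)].astype(bool)
    keep = ~flags.any(axis=1)
    restricted = cohort.loc[keep].reset_index(drop=True)
    return restricted, int((~keep).sum())


def ln_transform(values: Sequence[float], offset: float = 0.0) -> np.ndarray:
    """Natural log after an additive offset (+1 mm^3 for volumes, 0 for HU)."""
    values = np.asarray(values, dtype=float)
    shifted = values + offset
    if np.any(shifted <= 0):
        bad = values[shifted <= 0][:5]
        raise ValueError(f"values non-positive after offset {offset}: {bad}")
    return np.log(shifted)


def describe_cohort(
    cohort: pd.DataFrame,
    kinds: Optional[Dict[str, str]] = None,
    skewed: Sequence[str] = (),
) -> pd.DataFrame:
    """Baseline-characteristics table: mean (SD), median [IQR] or n (%).

    ``kinds`` maps column -> {"binary", "continuous", "skewed"}; columns
    not listed are inferred (values within {0, 1} count as binary).
    """
    rows = []
    kinds = dict(kinds or {})
    for col in skewed:
        kinds[col] = "skewed"
    for col in cohort.columns:
        s = cohort[col]
        if not np.issubdtype(s.dtype, np.number):
            continue
        kind = kinds.get(col)
        if kind is None:
            kind = "binary" if set(np.unique(s)) <= {0, 1} else "continuous"
        if kind == "binary":
            count = int(s.sum())
            pct = 100.0 * count / len(s)
            rows.append(
                {"variable": col, "kind": kind, "stat1": count, "stat2": pct,
                 "summary": f"{count} ({pct:.1f})"}
            )
        elif kind == "skewed":
            q1, med, q3 = np.percentile(s, [25, 50, 75])
            rows.append(
                {"variable": col, "kind": kind, "stat1": med, "stat2": q3 - q1,
                 "summary": f"{med:.1f} ({q1:.1f}-{q3:.1f})"}
            )
        else:
            mean, sd = float(s.mean()), float(s.std(ddof=1)) if len(s) > 1 else 0.0
            rows.append(
                {"variable": col, "kind": kind, "stat1": mean, "stat2": sd,
                 "summary": f"{mean:.1f} ({sd:.1f})"}
            )
    return pd.DataFrame(rows)
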