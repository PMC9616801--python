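"""Gaussian encoding model for silencing effects.

Predicts a target neuron's spike count Rs during a source-silencing window
from its own control-trial count Rc in the matching window plus one cell
property d (cortical depth, receptive-field distance, session mean rate, or
a selectivity index):

    Rs ~ Normal(mu, sigma),
    mu = d*bd + d^2*b2d + Rc*bc + Rc^2*b2c + d*Rc*bi + b0,

against a null model with the activity terms only
(mu0 = Rc*bc + Rc^2*b2c + b0).  Both are fit by iteratively reweighted
least squares (Gaussian GLM).  Model performance is the 20-fold
cross-validated excess log-likelihood of the full over the null model,
in bits per observation; above-chance performance is a one-sided Wilcoxon
signed-rank test across folds.

The covariate is z-scored internally for conditioning (the quadratic and
interaction columns otherwise correlate heavily); reported coefficients are
mapped back to the raw covariate scale, so the fit is invariant to affine
rescaling of d.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = ["GLMResult", "fit_effect_glm", "excess_loglik", "CrossValPerformance"]

LOG2E = float(np.log2(np.e))


@dataclass
class GLMResult:
    coefficients: dict  # beta0, beta_c, beta_2c, beta_d, beta_2d, beta_i
    sigma: float
    covariate: str = "d"
    null: bool = False


def _design(rc: np.ndarray, d: np.ndarray | None):
    cols = [np.ones_like(rc), rc, rc**2]
    names = ["beta0", "beta_c", "beta_2c"]
    if d is not None:
        cols += [d, d**2, d * rc]
        names += ["beta_d", "beta_2d", "beta_i"]
    return np.column_stack(cols), names


def _fit_irls(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    model = sm.GLM(y, X, family=sm.families.Gaussian())
    return np.asarray(model.fit().params)


def fit_effect_glm(
    rs: np.ndarray,
    rc: np.ndarray,
    covariate: np.ndarray | None,
    covariate_name: str = "d",
    min_obs: int = 50,
) -> GLMResult:
    """Fit the full (or, with ``covariate=None``, the null) encoding model.

    Observations are (neuron, trial) pairs at a given silencing window,
    pooled across windows by the caller.  Raises on singular designs with a
    condition-number report.
    """
    rs = np.asarray(rs, dtype=float)
    rc = np.asarray(rc, dtype=float)
    if rs.size < min_obs:
        raise ValueError(f"need at least {min_obs} observations, got {rs.size}")
    d = None
    mu_d = sd_d = None
    if covariate is not None:
        d_raw = np.asarray(covariate, dtype=float)
        mu_d, sd_d = d_raw.mean(), d_raw.std()
        if sd_d == 0:
            raise ValueError("degenerate covariate (zero variance)")
        d = (d_raw - mu_d) / sd_d
    X, names = _design(rc, d)
    cond = np.linalg.cond(X.T @ X)
    if cond > 1e12:
        raise ValueError(f"singular design matrix (condition number {cond:.3g})")
    beta = _fit_irls(rs, X)
    resid = rs - X @ beta
    sigma = float(np.sqrt(np.mean(resid**2)))
    coef = dict(zip(names, map(float, beta)))
    if d is not None:
        coef = _unstandardize(coef, mu_d, sd_d)
    else:
        coef.update(beta_d=0.0, beta_2d=0.0, beta_i=0.0)
    return GLMResult(coef, sigma, covariate_name, null=covariate is None)


def _unstandardize(c: dict, mu: float, sd: float) -> dict:
    """Map coefficients of the z-scored covariate back to the raw scale."""
    bd, b2d, bi = c["beta_d"], c["beta_2d"], c["beta_i"]
    return dict(
        beta0=c["beta0"] - bd * mu / sd + b2d * mu**2 / sd**2,
        beta_c=c["beta_c"] - bi * mu / sd,
        beta_2c=c["beta_2c"],
        beta_d=bd / sd - 2 * b2d * mu / sd**2,
        beta_2d=b2d / sd**2,
        beta_i=bi / sd,
    )


def predict(result: GLMResult, rc: np.ndarray, covariate: np.ndarray | None) -> np.ndarray:
    c = result.coefficients
    rc = np.asarray(rc, dtype=float)
    mu = c["beta0"] + c["beta_c"] * rc + c["beta_2c"] * rc**2
    if covariate is not None:
        d = np.asarray(covariate, dtype=float)
        mu = mu + c["beta_d"] * d + c["beta_2d"] * d**2 + c["beta_i"] * d * rc
    return mu


@dataclass
class CrossValPerformance:
    bits_per_trial: np.ndarray  # one value per test fold
    p_value: float  # one-sided signed-rank, H1: performance > 0
    k_folds: int
    full: GLMResult | None = None
    null: GLMResult | None = None
    meta: dict = field(default_factory=dict)


def excess_loglik(
    rs: np.ndarray,
    rc: np.ndarray,
    covariate: np.ndarray,
    covariate_name: str = "d",
    k_folds: int = 20,
    seed: int | np.random.Generator = 0,
) -> CrossValPerformance:
    """Cross-validated excess log-likelihood of the full over the null model.

    Observations are shuffled into ``k_folds`` folds (seeded).  On each
    training fold both models are fit; sigma for the test likelihood is the
    training residual SD of the respective model.  Per test fold the
    performance is ``(log2 L_full - log2 L_null) / N_test`` bits/trial.
    """
    rng = np.random.default_rng(seed)
    rs = np.asarray(rs, dtype=float)
    rc = np.asarray(rc, dtype=float)
    d = np.asarray(covariate, dtype=float)
    n = rs.size
    folds = np.array_split(rng.permutation(n), k_folds)
    perf = []
    for fold in folds:
        if fold.size < 2:
            raise ValueError("fold with fewer than 2 observations")
        tr = np.setdiff1d(np.arange(n), fold)
        full = fit_effect_glm(rs[tr], rc[tr], d[tr], covariate_name, min_obs=10)
        null = fit_effect_glm(rs[tr], rc[tr], None, covariate_name, min_obs=10)
        ll_full = stats.norm.logpdf(rs[fold], predict(full, rc[fold], d[fold]), max(full.sigma, 1e-12)).sum()
        ll_null = stats.norm.logpdf(rs[fold], predict(null, rc[fold], None), max(null.sigma, 1e-12)).sum()
        perf.append(LOG2E * (ll_full - ll_null) / fold.size)
    perf = np.asarray(perf)
    if np.allclose(perf, 0.0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(perf, alternative="greater").pvalue)
    full_all = fit_effect_glm(rs, rc, d, covariate_name)
    null_all = fit_effect_glm(rs, rc, None, covariate_name)
    return CrossValPerformance(perf, p, k_folds, full_all, null_all)
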