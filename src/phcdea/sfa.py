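"""Stage 2: stochastic-frontier regression of input slacks on environment.

Each input's total slack S is regressed on the environmental covariates Z
with a composed error,

    S_i = Z_i' beta + v_i + u_i,     v ~ N(0, sigma_v^2),  u ~ N+(0, sigma_u^2),

where u >= 0 is one-sided "managerial inefficiency" (slack a unit carries
beyond what its environment explains) and v is symmetric noise.  Because
slack is a bad, the one-sided term enters with a plus sign (cost-frontier
orientation).  The model is parameterized by sigma^2 = sigma_v^2 + sigma_u^2
and gamma = sigma_u^2 / sigma^2 in [0, 1); the marginal density of
eps = v + u is

    f(eps) = (2 / sigma) phi(eps / sigma) Phi(eps * lambda / sigma),

with lambda = sigma_u / sigma_v, which collapses to the Gaussian regression
likelihood as gamma -> 0.  Residuals are split by the JLMS conditional
expectation E[u | eps], and the fitted environment effect plus noise are
levelled across units by the max-based adjustment

    X^A = X + [max f(Z) - f(Z)] + [max v_hat - v_hat],

which puts every unit in the least favourable observed environment with the
worst observed luck, so stage-3 DEA scores reflect management alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

_GAMMA_GRID = np.arange(0.05, 1.0, 0.10)
#: 5% critical value of the 50:50 chi2(0)/chi2(1) mixture (one-sided LR test)
MIXED_CHI2_CRIT_5PCT = 2.7055


@dataclass
class SFAFit:
    """MLE of one input's slack frontier and its residual decomposition."""

    input_name: str
    beta: np.ndarray            # intercept first
    sigma_sq: float
    gamma: float
    loglik: float
    loglik_ols: float
    lr_stat: float
    converged: bool
    beta_se: np.ndarray | None
    obs: pd.DataFrame           # dmu, year, slack, fitted, eps, cond_mu, nu_hat

    @property
    def sigma_v(self) -> float:
        return float(np.sqrt(self.sigma_sq * (1.0 - self.gamma)))

    @property
    def sigma_u(self) -> float:
        return float(np.sqrt(self.sigma_sq * self.gamma))


def _design(env: np.ndarray) -> np.ndarray:
    env = np.asarray(env, dtype=float)
    return np.column_stack([np.ones(len(env)), env])


def sfa_loglikelihood(beta, sigma_sq, gamma, slacks, design) -> float:
    """Log-likelihood of the composed-error slack frontier.

    ``design`` must already carry the intercept column.  Valid for
    gamma in [0, 1); at gamma = 0 this is exactly the Gaussian regression
    log-likelihood with variance sigma_sq.
    """
    beta = np.asarray(beta, dtype=float)
    slacks = np.asarray(slacks, dtype=float)
    design = np.asarray(design, dtype=float)
    if not (np.all(np.isfinite(beta)) and np.isfinite(sigma_sq) and np.isfinite(gamma)):
        raise ValueError("nonfinite parameters")
    if not (0.0 <= gamma < 1.0) or sigma_sq <= 0.0:
        raise ValueError("require sigma_sq > 0 and gamma in [0, 1)")
    if design.shape != (len(slacks), len(beta)):
        raise ValueError("dimension mismatch")
    sigma = np.sqrt(sigma_sq)
    lam = np.sqrt(gamma / (1.0 - gamma))
    eps = slacks - design @ beta
    z = eps / sigma
    return float(np.sum(np.log(2.0) - np.log(sigma)
                        + stats.norm.logpdf(z) + stats.norm.logcdf(lam * z)))


def _ols(slacks, design):
    beta, *_ = np.linalg.lstsq(design, slacks, rcond=None)
    resid = slacks - design @ beta
    n = len(slacks)
    s2 = float(resid @ resid) / n
    ll = -0.5 * n * (np.log(2 * np.pi * s2) + 1.0)
    return beta, s2, ll


def fit_sfa(slacks, env, *, input_name: str = "input", dmu=None, year=None,
            max_restarts: int = 3, gamma_max: float = 0.99) -> SFAFit:
    """Maximum-likelihood fit of the slack frontier for one input.

    Optimizes over (beta, ln sigma^2, logit gamma) so the variance and
    share constraints hold by construction; starts from OLS with a grid of
    gamma values (moment-matched sigma^2 and a mean-of-half-normal
    intercept correction) and keeps the best converged optimum.

    ``gamma_max`` bounds the inefficiency variance share away from 1.
    DEA slack vectors carry an atom of exact zeros (the efficient units),
    and as gamma -> 1 the likelihood degenerates onto a flat lower-envelope
    fit with beta -> 0; an interior bound keeps the frontier slope
    identified, at the price of reporting gamma_max instead of 1 when the
    noise share is genuinely negligible.
    """
    slacks = np.asarray(slacks, dtype=float)
    design = _design(env)
    n, k = design.shape
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} observations, got {n}")
    if np.linalg.matrix_rank(design) < k:
        raise ValueError("environment design matrix is rank deficient")

    if np.ptp(slacks) < 1e-12 * max(1.0, abs(slacks[0])):
        # constant slack (e.g. all units efficient): frontier is flat, no
        # inefficiency or noise to attribute — degenerate fit, zero adjustment
        fitted = np.full(n, slacks.mean())
        obs = pd.DataFrame({
            "dmu": dmu if dmu is not None else np.arange(n),
            "year": year if year is not None else np.zeros(n, dtype=int),
            "slack": slacks, "fitted": fitted, "eps": slacks - fitted,
            "cond_mu": np.zeros(n), "nu_hat": slacks - fitted})
        beta0 = np.r_[slacks.mean(), np.zeros(k - 1)]
        return SFAFit(input_name=input_name, beta=beta0, sigma_sq=1e-12,
                      gamma=0.0, loglik=0.0, loglik_ols=0.0, lr_stat=0.0,
                      converged=True, beta_se=None, obs=obs)
    beta_ols, s2_ols, ll_ols = _ols(slacks, design)
    scale = max(np.sqrt(s2_ols), 1e-12)

    def unpack(p):
        beta = p[:k]
        sigma_sq = np.exp(p[k]) * scale ** 2
        gamma = gamma_max / (1.0 + np.exp(-p[k + 1]))
        return beta, sigma_sq, gamma

    def nll(p):
        beta, sigma_sq, gamma = unpack(p)
        try:
            return -sfa_loglikelihood(beta, sigma_sq, gamma, slacks, design)
        except (ValueError, FloatingPointError):
            return np.inf

    best = None
    starts = []
    for g0 in _GAMMA_GRID:
        # Var(eps) = sigma^2 (1 - 2 gamma / pi); E[eps] = sqrt(2 gamma sigma^2 / pi)
        s2_0 = s2_ols / (1.0 - 2.0 * g0 / np.pi)
        b0 = beta_ols.copy()
        b0[0] -= np.sqrt(2.0 * g0 * s2_0 / np.pi)
        q = min(g0 / gamma_max, 1.0 - 1e-9)
        starts.append(np.r_[b0, np.log(s2_0 / scale ** 2), np.log(q / (1 - q))])
    converged = False
    for attempt in range(max_restarts):
        for p0 in starts:
            res = optimize.minimize(nll, p0, method="Nelder-Mead",
                                    options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-12})
            res = optimize.minimize(nll, res.x, method="BFGS",
                                    options={"maxiter": 500, "gtol": 1e-8})
            if best is None or res.fun < best.fun - 1e-12:
                best = res
                converged = bool(np.isfinite(res.fun))
        if best is not None and -best.fun >= ll_ols - 1e-6:
            break
        starts = [p + 0.1 * np.random.default_rng(attempt).standard_normal(len(p))
                  for p in starts]
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"SFA fit for {input_name!r} failed to converge "
                           f"after {max_restarts} restart rounds")

    beta, sigma_sq, gamma = unpack(best.x)
    loglik = -float(best.fun)
    # MLE must weakly dominate its gamma=0 special case
    if loglik < ll_ols - 1e-9:
        beta, sigma_sq, gamma, loglik = beta_ols, s2_ols, 0.0, ll_ols
    lr = max(0.0, 2.0 * (loglik - ll_ols))

    fitted = design @ beta
    eps = slacks - fitted
    sigma_v, sigma_u = np.sqrt(sigma_sq * (1 - gamma)), np.sqrt(sigma_sq * gamma)
    cond_mu = jlms_conditional_mu(eps, sigma_v, sigma_u)
    obs = pd.DataFrame({
        "dmu": dmu if dmu is not None else np.arange(n),
        "year": year if year is not None else np.zeros(n, dtype=int),
        "slack": slacks, "fitted": fitted, "eps": eps,
        "cond_mu": cond_mu, "nu_hat": eps - cond_mu})
    return SFAFit(input_name=input_name, beta=beta, sigma_sq=float(sigma_sq),
                  gamma=float(gamma), loglik=loglik, loglik_ols=ll_ols,
                  lr_stat=lr, converged=converged,
                  beta_se=_hessian_se(best.x, nll, unpack, k), obs=obs)


def _hessian_se(p_opt, nll, unpack, k):
    """Delta-free std errors for beta from a central-difference Hessian."""
    d = len(p_opt)
    h = 1e-4 * np.maximum(np.abs(p_opt), 1.0)
    H = np.zeros((d, d))
    for i in range(d):
        for j in range(i, d):
            ei = np.eye(d)[i] * h[i]
            ej = np.eye(d)[j] * h[j]
            H[i, j] = H[j, i] = (nll(p_opt + ei + ej) - nll(p_opt + ei - ej)
                                 - nll(p_opt - ei + ej) + nll(p_opt - ei - ej)) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov)[:k], 0.0, None))
        return se
    except np.linalg.LinAlgError:
        return None


def lr_test_gamma(fit: SFAFit, alpha: float = 0.05):
    """One-sided LR test of gamma = 0 against the mixed chi2 null.

    Under the null the LR statistic is distributed as a 50:50 mixture of a
    point mass at zero and chi2(1); the p-value is 0.5 * P(chi2_1 > LR).
    """
    lr = fit.lr_stat
    p = 1.0 if lr <= 0 else 0.5 * stats.chi2.sf(lr, df=1)
    return lr, p, bool(lr > MIXED_CHI2_CRIT_5PCT) if alpha == 0.05 else bool(p < alpha)


def jlms_conditional_mu(eps, sigma_v: float, sigma_mu: float):
    """JLMS conditional mean E[u | eps] for the eps = v + u composition.

    With mu* = eps sigma_u^2 / sigma^2 and sigma*^2 = sigma_u^2 sigma_v^2
    / sigma^2, E[u|eps] = mu* + sigma* phi(mu*/sigma*) / Phi(mu*/sigma*).
    Strictly positive and increasing in eps; zero when sigma_mu = 0.
    """
    eps = np.asarray(eps, dtype=float)
    if not np.all(np.isfinite(eps)):
        raise ValueError("nonfinite residual")
    if sigma_v <= 0 or sigma_mu < 0:
        raise ValueError("require sigma_v > 0 and sigma_mu >= 0")
    if sigma_mu == 0:
        return np.zeros_like(eps)
    s2 = sigma_v ** 2 + sigma_mu ** 2
    mu_star = eps * sigma_mu ** 2 / s2
    sig_star = sigma_mu * sigma_v / np.sqrt(s2)
    a = mu_star / sig_star
    # phi/Phi via log-space for stability deep in the left tail
    ratio = np.exp(stats.norm.logpdf(a) - stats.norm.logcdf(a))
    return mu_star + sig_star * ratio


@dataclass
class AdjustedPanel:
    """Environment/noise-levelled panel plus the fits that produced it."""

    panel: object               # PanelDataset with adjusted inputs
    fits: dict                  # input name -> SFAFit


def fit_all_inputs(slack_table: pd.DataFrame, panel) -> dict:
    """One SFA per input, pooled over all DMU-years of the panel."""
    env_df = panel.sorted_data()
    env = env_df[list(panel.env_cols)].to_numpy(dtype=float)
    fits = {}
    for name in panel.input_cols:
        sl = slack_table[slack_table["input"] == name].merge(
            env_df[["dmu", "year"]].assign(_ord=np.arange(len(env_df))),
            on=["dmu", "year"]).sort_values("_ord")
        fits[name] = fit_sfa(sl["slack"].to_numpy(), env, input_name=name,
                             dmu=sl["dmu"].to_numpy(), year=sl["year"].to_numpy())
    return fits


def adjust_inputs(panel, fits: dict) -> AdjustedPanel:
    """Max-based input adjustment: X^A = X + [max f - f] + [max v - v].

    Maxima are taken over the pooled DMU-year sample per input, so the
    adjusted input is never below the observed one and is unchanged exactly
    at an observation attaining both maxima.
    """
    missing = set(panel.input_cols) - set(fits)
    if missing:
        raise ValueError(f"no SFA fit for inputs: {sorted(missing)}")
    df = panel.sorted_data().copy()
    for name in panel.input_cols:
        fit = fits[name]
        obs = fit.obs.set_index(["dmu", "year"])
        idx = pd.MultiIndex.from_frame(df[["dmu", "year"]])
        f = obs.loc[idx, "fitted"].to_numpy()
        nu = obs.loc[idx, "nu_hat"].to_numpy()
        df[name] = df[name].to_numpy() + (f.max() - f) + (nu.max() - nu)
    return AdjustedPanel(panel=panel.with_inputs(df), fits=fits)
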