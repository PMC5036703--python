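"""Model comparison and checking.

Component-wise WAIC, posterior predictive checks with a chi-square
discrepancy, posterior sign probabilities with their marginal Bayes-factor
conversion, and the locally weighted factor-vs-risk summaries used to read
threshold effects off the fitted latent scores.
"""

from __future__ import annotations

import warnings
from collections import OrderedDict

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp

from .sem import PosteriorDraws

__all__ = [
    "waic",
    "posterior_predictive_check",
    "sign_probability",
    "marginal_bayes_factor",
    "factor_risk_curve",
    "fit_report",
]


def waic(draws: PosteriorDraws, component: str):
    """Widely applicable information criterion for one likelihood component.

    ``WAIC = -2 (lppd - p_waic)`` with ``lppd = sum_cells log mean_draws
    exp(ll)`` (log-sum-exp stabilised) and ``p_waic = sum_cells
    var_draws(ll)``.  Cells are the per-(practice, indicator) observations
    of the component; lower WAIC means better fit.

    Returns ``(waic, lppd, p_waic)``.
    """
    if component not in draws.pointwise_ll:
        raise KeyError(
            f"component '{component}' has no stored pointwise log-likelihood "
            f"(available: {sorted(draws.pointwise_ll)})"
        )
    ll = draws.pointwise_ll[component]
    n_draws = ll.shape[0] * ll.shape[1]
    flat = ll.reshape(n_draws, -1)
    lppd = float(np.sum(logsumexp(flat, axis=0) - np.log(n_draws)))
    p_waic = float(np.sum(np.var(flat, axis=0))) if n_draws > 1 else 0.0
    return -2.0 * (lppd - p_waic), lppd, p_waic


def _parse_variable(draws: PosteriorDraws, table, variable: str):
    """Resolve a variable name ('Y', 'Z1'..'ZJ', 'W1'..'WK') to its pieces."""
    if variable == "Y":
        return ("Y", None)
    if len(variable) >= 2 and variable[0] in ("Z", "W") and variable[1:].isdigit():
        idx = int(variable[1:]) - 1
        limit = table.J if variable[0] == "Z" else table.K
        if 0 <= idx < limit:
            if variable[0] == "W" and "G" not in draws.draws:
                raise KeyError("access indicators were not part of the fitted model")
            return (variable[0], idx)
    raise KeyError(f"unknown variable '{variable}'; use 'Y', 'Z1'..'Z{table.J}', 'W1'..'W{table.K}'")


def posterior_predictive_check(draws: PosteriorDraws, table, variable: str, seed: int = 0) -> float:
    """Posterior predictive p-value for one observed variable.

    For each retained draw the variable is replicated from its likelihood
    given that draw's parameters and latents, and a chi-square discrepancy
    ``T(x; theta) = sum_i (x_i - E[x_i|theta])^2 / Var(x_i|theta)`` is
    compared between replicate and observation.  The p-value is the
    proportion of draws with ``T(rep) >= T(obs)``; values near 0 or 1
    indicate misfit, the satisfactory band being roughly (0.1, 0.9).
    """
    kind, idx = _parse_variable(draws, table, variable)
    rng = np.random.default_rng(seed)
    if kind == "Y":
        nu = draws.stacked("nu")  # (n, I)
        mu = table.E[None, :] * nu
        obs = table.Y[None, :].astype(float)
        rep = rng.poisson(mu).astype(float)
        var = np.maximum(mu, 1e-12)
    else:
        if kind == "Z":
            den, num = table.N[:, idx], table.Z[:, idx]
            icept = draws.stacked("delta")[:, idx]
            load = draws.stacked("lam")[:, idx]
            factor = draws.stacked("F")
            eff = draws.stacked("eps")[:, :, idx]
        else:
            den, num = table.V[:, idx], table.W[:, idx]
            icept = draws.stacked("eta")[:, idx]
            load = draws.stacked("kappa")[:, idx]
            factor = draws.stacked("G")
            eff = draws.stacked("e")[:, :, idx]
        p = expit(icept[:, None] + load[:, None] * factor + eff)
        mu = den[None, :] * p
        var = np.maximum(den[None, :] * p * (1.0 - p), 1e-12)
        obs = num[None, :].astype(float)
        rep = rng.binomial(den[None, :].astype(np.int64), p).astype(float)
    t_obs = np.sum((obs - mu) ** 2 / var, axis=1)
    t_rep = np.sum((rep - mu) ** 2 / var, axis=1)
    return float(np.mean(t_rep >= t_obs))


def sign_probability(draws: PosteriorDraws, coefficient: str) -> float:
    """Posterior probability that a sampled coefficient is negative."""
    if coefficient not in draws.draws:
        raise KeyError(f"coefficient '{coefficient}' was not sampled")
    flat = draws.stacked(coefficient)
    return float(np.mean(flat < 0.0))


def marginal_bayes_factor(p_sign: float) -> float:
    """Posterior odds ``p / (1 - p)`` for a coefficient's sign.

    Under a sign-neutral prior (prior odds 1) the posterior odds of, say, a
    negative effect are the marginal Bayes factor for that direction.
    Monte Carlo estimates of exactly 0 or 1 produce 0/inf with a warning,
    since they only bound the true odds.
    """
    if not 0.0 <= p_sign <= 1.0:
        raise ValueError("sign probability must lie in [0, 1]")
    if p_sign in (0.0, 1.0):
        warnings.warn(
            "sign probability at the Monte Carlo limit (0 or 1); the Bayes factor "
            "is only bounded by the number of posterior draws",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("inf") if p_sign == 1.0 else 0.0
    return p_sign / (1.0 - p_sign)


def factor_risk_curve(draws: PosteriorDraws, factor: str = "F", frac: float = 2.0 / 3.0) -> pd.DataFrame:
    """Posterior-mean factor score vs relative risk with a LOWESS smooth.

    Returns one row per practice, sorted by score, with columns ``score``,
    ``nu`` (posterior means) and ``smooth`` (tricube-weighted local linear
    fit with span ``frac``).
    """
    if factor not in ("F", "G"):
        raise ValueError("factor must be 'F' or 'G'")
    if factor not in draws.draws:
        raise ValueError(f"factor '{factor}' is not part of the fitted model")
    from statsmodels.nonparametric.smoothers_lowess import lowess

    score = draws.stacked(factor).mean(axis=0)
    nu = draws.stacked("nu").mean(axis=0)
    order = np.argsort(score)
    sm = lowess(nu[order], score[order], frac=frac, return_sorted=False)
    return pd.DataFrame(
        {
            "practice_id": np.asarray(draws.meta["practice_id"])[order],
            "score": score[order],
            "nu": nu[order],
            "smooth": sm,
        }
    ).set_index("practice_id")


def fit_report(draws: PosteriorDraws, table, ppc_seed: int = 0) -> dict:
    """Assemble the standard criticism bundle for a fitted model.

    Returns a dict with per-component WAIC, the grid of posterior
    predictive p-values, sign probabilities for the outcome coefficients,
    and their marginal Bayes factors (for the direction favoured by the
    posterior).
    """
    report: dict = {"waic": {}, "ppc": OrderedDict(), "sign_probs": {}, "bayes_factors": {}}
    for comp in draws.pointwise_ll:
        w, lppd, p = waic(draws, comp)
        report["waic"][comp] = {"waic": round(w, 1), "lppd": lppd, "p_waic": p}
    variables = ["Y"] + [f"Z{j + 1}" for j in range(table.J)]
    if "G" in draws.draws:
        variables += [f"W{k + 1}" for k in range(table.K)]
    for var in variables:
        report["ppc"][var] = round(posterior_predictive_check(draws, table, var, seed=ppc_seed), 3)
    for name in draws.meta.get("gamma_names", []):
        if name == "gamma0":
            continue
        p_neg = sign_probability(draws, name)
        report["sign_probs"][name] = {"negative": round(p_neg, 3), "positive": round(1 - p_neg, 3)}
        p_dir = max(p_neg, 1.0 - p_neg)
        if p_dir < 1.0:
            report["bayes_factors"][name] = {
                "direction": "negative" if p_neg >= 0.5 else "positive",
                "bf": round(marginal_bayes_factor(p_dir), 1),
            }
    return report
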