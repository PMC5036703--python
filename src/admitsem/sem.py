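"""Model fitting by adaptive Metropolis-within-Gibbs MCMC.

The joint posterior factorises over practices given the global parameters,
so all latent blocks (factor scores, overdispersion effects, scale-mixture
weights) are updated with vectorised element-wise random-walk proposals;
global parameters get scalar random-walk updates, with scales sampled on
the log scale and the factor correlation on the Fisher-z scale (Jacobians
included).  Proposal step sizes are tuned during burn-in by Robbins-Monro
adaptation toward standard acceptance targets and frozen afterwards, so the
post-burn-in chain is a valid Markov chain.

The overdispersion effects are parameterised non-centred (``eps = sigma_j *
eps_raw`` etc.) because their hierarchical SDs can sit near zero, where
centred random-walk updates mix poorly.

The user-facing surface is :class:`AdmissionsSEM` (build from a
:class:`~admitsem.data.PracticeTable`) whose :meth:`~AdmissionsSEM.fit`
returns :class:`SEMResults` carrying the posterior draws, summaries,
diagnostics, and model-criticism methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import PracticeTable, compute_expected_counts, standardize_covariates
from .likelihood import (
    COEF_LABELS,
    LatentState,
    ModelConfig,
    ModelParameters,
    bivariate_latent_logpdf,
    linear_predictor_nu,
    log_prior,
    pointwise_loglik,
)

__all__ = [
    "PosteriorDraws",
    "run_mcmc",
    "initialize_chain",
    "convergence_report",
    "posterior_summaries",
    "AdmissionsSEM",
    "SEMResults",
]


# ---------------------------------------------------------------------------
# posterior draw container
# ---------------------------------------------------------------------------


@dataclass
class PosteriorDraws:
    """Retained MCMC samples.

    ``draws[name]`` has shape ``(chains, n_kept)`` for scalars and
    ``(chains, n_kept, ...)`` for vector parameters and latent blocks.
    ``pointwise_ll[component]`` holds per-draw pointwise log-likelihoods
    (the WAIC cells).  Burn-in iterations are excluded.
    """

    draws: dict
    pointwise_ll: dict
    meta: dict

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_kept(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws for ``name`` with chains concatenated along the first axis."""
        arr = self.draws[name]
        return arr.reshape(-1, *arr.shape[2:])

    def scalar_names(self) -> list[str]:
        return [k for k, v in self.draws.items() if v.ndim == 2]

    def expand_scalars(self, include_latents: bool = False) -> dict:
        """Flatten vector parameters to ``name[j]`` scalar chains."""
        out = {}
        latent_keys = {"F", "G", "u", "eps", "e", "omega", "nu"}
        for name, arr in self.draws.items():
            if name in latent_keys and not include_latents:
                continue
            if arr.ndim == 2:
                out[name] = arr
            elif arr.ndim == 3:
                for j in range(arr.shape[2]):
                    out[f"{name}[{j + 1}]"] = arr[:, :, j]
        return out


# ---------------------------------------------------------------------------
# internal chain machinery
# ---------------------------------------------------------------------------


def _bin_kern(Z, N, lp):
    return Z * lp - N * np.logaddexp(0.0, lp)


_SCALAR_TARGET = 0.44  # optimal acceptance for 1-D random-walk updates
_JOINT_TARGET = 0.35


class _Chain:
    def __init__(self, table: PracticeTable, config: ModelConfig, rng: np.random.Generator):
        self.table = table
        self.config = config
        self.rng = rng
        self.model_id = config.model_id
        self.ll_scale = 0.0 if config.prior_only else 1.0
        self.I, self.J, self.K = table.I, table.J, table.K
        self.Z = table.Z.astype(float)
        self.N = table.N.astype(float)
        self.W = table.W.astype(float)
        self.V = table.V.astype(float)
        self.Y = table.Y.astype(float)
        self.E = table.E.astype(float)
        self.D = table.D
        self.M = table.Mrate
        self.S1 = table.S1
        self.S2 = table.S2
        self.fixed = dict(config.fixed)
        self._init_state()
        self._init_steps()
        self.acc: dict[str, list] = {}

    # -- state -----------------------------------------------------------
    def _init_state(self) -> None:
        rng, I, J, K = self.rng, self.I, self.J, self.K
        jit = lambda size=None: rng.normal(0.0, 0.01, size)
        pooled_q = (self.Z.sum(axis=0) + 0.5) / (self.N.sum(axis=0) + 1.0)
        pooled_a = (self.W.sum(axis=0) + 0.5) / (self.V.sum(axis=0) + 1.0)
        logit = lambda p: np.log(p / (1.0 - p))
        s = {
            "delta": logit(pooled_q),
            "lam": np.concatenate([[1.0], np.ones(J - 1) + jit(J - 1)]),
            "sigma": np.full(J, 0.1),
            "eta": logit(pooled_a),
            "kappa": np.concatenate([[1.0], np.ones(max(K - 1, 0)) + jit(max(K - 1, 0))]),
            "tau": np.full(K, 0.1),
            "alpha": 0.1,
            "sigma_F": 0.1,
            "sigma_G": 0.1,
            "rho": 0.0,
        }
        for g in ("gamma0", "gamma_F", "gamma_D", "gamma_G", "gamma_M"):
            s[g] = float(jit())
        for b in ("beta1", "beta2", "beta3", "beta4"):
            s[b] = float(jit())
        self.s = s
        self.F = rng.normal(0.0, 0.1, I)
        self.G = rng.normal(0.0, 0.1, I)
        self.eps_raw = np.zeros((I, J))
        self.e_raw = np.zeros((I, K))
        self.u_raw = np.zeros(I)
        self.omega = np.ones(I)
        for name, val in self.fixed.items():
            if name in ("F", "G", "omega"):
                setattr(self, name, np.asarray(val, dtype=float).copy())
            elif name in ("eps", "e", "u"):
                pass  # handled by the effective-value accessors
            elif name in s:
                s[name] = np.asarray(val, dtype=float).copy() if np.ndim(val) else float(val)
            else:
                raise ValueError(f"unknown fixed quantity '{name}'")

    def _init_steps(self) -> None:
        I, J, K = self.I, self.J, self.K
        self.step = {
            "eps": np.full((I, J), 0.5),
            "e": np.full((I, K), 0.5),
            "u": np.full(I, 0.5),
            "F": np.full(I, 0.3),
            "G": np.full(I, 0.3),
            "delta": np.full(J, 0.1),
            "lam": np.full(J, 0.1),
            "sigma": np.full(J, 0.3),
            "eta": np.full(K, 0.1),
            "kappa": np.full(K, 0.1),
            "tau": np.full(K, 0.3),
        }
        for name in ("gamma0", "gamma_F", "gamma_D", "gamma_G", "gamma_M", "alpha",
                     "beta1", "beta2", "beta3", "beta4", "sigma_F", "sigma_G", "rho"):
            self.step[name] = 0.1

    # -- effective latents ------------------------------------------------
    @property
    def eps(self) -> np.ndarray:
        if "eps" in self.fixed:
            return np.asarray(self.fixed["eps"], dtype=float)
        return self.s["sigma"][None, :] * self.eps_raw

    @property
    def e(self) -> np.ndarray:
        if "e" in self.fixed:
            return np.asarray(self.fixed["e"], dtype=float)
        return self.s["tau"][None, :] * self.e_raw

    @property
    def u(self) -> np.ndarray:
        if "u" in self.fixed:
            return np.asarray(self.fixed["u"], dtype=float)
        return self.s["alpha"] * self.u_raw

    # -- current predictors ----------------------------------------------
    def _lognu(self, **over):
        s = self.s
        g0 = over.get("gamma0", s["gamma0"])
        gF = over.get("gamma_F", s["gamma_F"])
        F = over.get("F", self.F)
        lin = g0 + gF * F
        if self.model_id >= 2:
            lin = lin + over.get("gamma_D", s["gamma_D"]) * self.D
            lin = lin + over.get("gamma_M", s["gamma_M"]) * self.M
        if self.model_id >= 3:
            lin = lin + over.get("gamma_G", s["gamma_G"]) * over.get("G", self.G)
        return lin + over.get("u", self.u)

    def _pois_kern(self, lognu):
        with np.errstate(over="ignore"):
            return self.Y * lognu - self.E * np.exp(lognu)

    def _mean_F(self, beta1=None):
        if self.model_id == 1:
            return 0.0
        b1 = self.s["beta1"] if beta1 is None else beta1
        return b1 * self.D

    def _mean_G(self, beta2=None, beta3=None, beta4=None):
        s = self.s
        return (
            (s["beta2"] if beta2 is None else beta2) * self.D
            + (s["beta3"] if beta3 is None else beta3) * self.S1
            + (s["beta4"] if beta4 is None else beta4) * self.S2
        )

    def _latent_prior_sum(self, F=None, G=None, sigma_F=None, sigma_G=None, rho=None,
                          beta1=None, beta2=None, beta3=None, beta4=None):
        """Sum over practices of the structural density of the factor scores."""
        s = self.s
        F = self.F if F is None else F
        sF = s["sigma_F"] if sigma_F is None else sigma_F
        mF = self._mean_F(beta1)
        if self.model_id < 3:
            return float(np.sum(-np.log(sF) - 0.5 * ((F - mF) / sF) ** 2))
        G = self.G if G is None else G
        sG = s["sigma_G"] if sigma_G is None else sigma_G
        r = s["rho"] if rho is None else rho
        mG = self._mean_G(beta2, beta3, beta4)
        return float(np.sum(bivariate_latent_logpdf(F, G, mF, mG, sF, sG, r, self.omega)))

    # -- adaptation --------------------------------------------------------
    def _adapt(self, name, accepted, t, target):
        gain = 1.0 / (t + 10.0) ** 0.6
        if np.ndim(self.step[name]):
            self.step[name] = self.step[name] * np.exp(2.0 * gain * (accepted - target))
            np.clip(self.step[name], 1e-4, 20.0, out=self.step[name])
        else:
            self.step[name] = float(np.clip(
                self.step[name] * np.exp(2.0 * gain * (np.mean(accepted) - target)), 1e-5, 20.0))

    def _track(self, name, accepted):
        rec = self.acc.setdefault(name, [0, 0])
        if isinstance(accepted, (bool, np.bool_)):
            rec[0] += bool(accepted)
            rec[1] += 1
        else:
            rec[0] += int(np.count_nonzero(accepted))
            rec[1] += accepted.size

    # -- latent updates ----------------------------------------------------
    def _update_eps(self, t, adapt):
        if "eps" in self.fixed:
            return
        s = self.s
        base = s["delta"][None, :] + s["lam"][None, :] * self.F[:, None]
        cur = self.eps_raw
        prop = cur + self.step["eps"] * self.rng.standard_normal(cur.shape)
        sig = s["sigma"][None, :]
        dll = 0.5 * (cur**2 - prop**2)
        if self.ll_scale:
            dll = dll + (
                _bin_kern(self.Z, self.N, base + sig * prop) - _bin_kern(self.Z, self.N, base + sig * cur)
            )
        acc = np.log(self.rng.uniform(size=cur.shape)) < dll
        self.eps_raw = np.where(acc, prop, cur)
        self._track("eps", acc)
        if adapt:
            self._adapt("eps", acc, t, _SCALAR_TARGET)

    def _update_e(self, t, adapt):
        if "e" in self.fixed:
            return
        s = self.s
        base = s["eta"][None, :] + s["kappa"][None, :] * self.G[:, None]
        cur = self.e_raw
        prop = cur + self.step["e"] * self.rng.standard_normal(cur.shape)
        tau = s["tau"][None, :]
        dll = 0.5 * (cur**2 - prop**2)
        if self.ll_scale:
            dll = dll + (
                _bin_kern(self.W, self.V, base + tau * prop) - _bin_kern(self.W, self.V, base + tau * cur)
            )
        acc = np.log(self.rng.uniform(size=cur.shape)) < dll
        self.e_raw = np.where(acc, prop, cur)
        self._track("e", acc)
        if adapt:
            self._adapt("e", acc, t, _SCALAR_TARGET)

    def _update_u(self, t, adapt):
        if "u" in self.fixed:
            return
        cur = self.u_raw
        prop = cur + self.step["u"] * self.rng.standard_normal(cur.shape)
        a = self.s["alpha"]
        dll = 0.5 * (cur**2 - prop**2)
        if self.ll_scale:
            ln0 = self._lognu()
            ln1 = ln0 + a * (prop - cur)
            dll = dll + (self._pois_kern(ln1) - self._pois_kern(ln0))
        acc = np.log(self.rng.uniform(size=cur.shape)) < dll
        self.u_raw = np.where(acc, prop, cur)
        self._track("u", acc)
        if adapt:
            self._adapt("u", acc, t, _SCALAR_TARGET)

    def _update_factors(self, t, adapt):
        s = self.s
        upd_F = "F" not in self.fixed
        upd_G = "G" not in self.fixed and self.model_id >= 3
        if not (upd_F or upd_G):
            return
        Fp = self.F + self.step["F"] * self.rng.standard_normal(self.I) if upd_F else self.F
        Gp = self.G + self.step["G"] * self.rng.standard_normal(self.I) if upd_G else self.G
        dll = np.zeros(self.I)
        if upd_F:
            base = s["delta"][None, :] + self.eps
            lam = s["lam"][None, :]
            dll += self.ll_scale * (
                _bin_kern(self.Z, self.N, base + lam * Fp[:, None])
                - _bin_kern(self.Z, self.N, base + lam * self.F[:, None])
            ).sum(axis=1)
        if upd_G:
            base = s["eta"][None, :] + self.e
            kap = s["kappa"][None, :]
            dll += self.ll_scale * (
                _bin_kern(self.W, self.V, base + kap * Gp[:, None])
                - _bin_kern(self.W, self.V, base + kap * self.G[:, None])
            ).sum(axis=1)
        if self.ll_scale:
            ln0 = self._lognu()
            ln1 = ln0 + s["gamma_F"] * (Fp - self.F)
            if self.model_id >= 3:
                ln1 = ln1 + s["gamma_G"] * (Gp - self.G)
            dll += self._pois_kern(ln1) - self._pois_kern(ln0)
        mF = self._mean_F()
        if self.model_id < 3:
            sF = s["sigma_F"]
            dll += -0.5 * ((Fp - mF) / sF) ** 2 + 0.5 * ((self.F - mF) / sF) ** 2
        else:
            mG = self._mean_G()
            dll += bivariate_latent_logpdf(Fp, Gp, mF, mG, s["sigma_F"], s["sigma_G"], s["rho"], self.omega)
            dll -= bivariate_latent_logpdf(self.F, self.G, mF, mG, s["sigma_F"], s["sigma_G"], s["rho"], self.omega)
        acc = np.log(self.rng.uniform(size=self.I)) < dll
        if upd_F:
            self.F = np.where(acc, Fp, self.F)
        if upd_G:
            self.G = np.where(acc, Gp, self.G)
        self._track("factors", acc)
        if adapt:
            target = _JOINT_TARGET if (upd_F and upd_G) else _SCALAR_TARGET
            if upd_F:
                self._adapt("F", acc, t, target)
            if upd_G:
                self._adapt("G", acc, t, target)

    def _update_omega(self):
        # Conjugate Gibbs draw: Gamma(df/2 + 1, (df + q_i)/2)
        if self.model_id != 4 or "omega" in self.fixed:
            return
        s = self.s
        rF = (self.F - self._mean_F()) / s["sigma_F"]
        rG = (self.G - self._mean_G()) / s["sigma_G"]
        q = (rF**2 - 2.0 * s["rho"] * rF * rG + rG**2) / (1.0 - s["rho"] ** 2)
        df = self.config.df
        self.omega = self.rng.gamma(shape=df / 2.0 + 1.0, scale=2.0 / (df + q))

    # -- global parameter updates -----------------------------------------
    def _coef_prior_delta(self, new, old):
        cs = self.config.coef_prior_sd
        return 0.5 * (old**2 - new**2) / cs**2

    def _update_gammas(self, t, adapt):
        covs = {"gamma0": 1.0, "gamma_F": self.F, "gamma_D": self.D,
                "gamma_G": self.G, "gamma_M": self.M}
        ln = self._lognu()
        kern = self._pois_kern(ln)
        for name in self.config.gamma_names:
            if name in self.fixed:
                continue
            cur = self.s[name]
            prop = cur + self.step[name] * self.rng.standard_normal()
            ln1 = ln + (prop - cur) * covs[name]
            kern1 = self._pois_kern(ln1)
            dll = np.sum(kern1 - kern) if self.ll_scale else 0.0
            dll += self._coef_prior_delta(prop, cur)
            acc = np.log(self.rng.uniform()) < dll
            if acc:
                self.s[name] = prop
                ln, kern = ln1, kern1
            self._track(name, acc)
            if adapt:
                self._adapt(name, acc, t, _SCALAR_TARGET)

    def _update_alpha(self, t, adapt):
        if "alpha" in self.fixed:
            return
        cur = self.s["alpha"]
        prop = cur * np.exp(self.step["alpha"] * self.rng.standard_normal())
        ss = self.config.scale_prior_sd
        dll = 0.5 * (cur**2 - prop**2) / ss**2 + (np.log(prop) - np.log(cur))
        if self.ll_scale and "u" not in self.fixed:
            ln0 = self._lognu()
            ln1 = ln0 + (prop - cur) * self.u_raw
            dll += np.sum(self._pois_kern(ln1) - self._pois_kern(ln0))
        acc = np.log(self.rng.uniform()) < dll
        if acc:
            self.s["alpha"] = prop
        self._track("alpha", acc)
        if adapt:
            self._adapt("alpha", acc, t, _SCALAR_TARGET)

    def _update_measurement(self, block, t, adapt):
        """Column-wise updates of intercepts, free loadings, and SDs."""
        s = self.s
        if block == "quality":
            Znum, Nden, raw = self.Z, self.N, self.eps_raw
            icept, load, sd, factor = "delta", "lam", "sigma", self.F
            shared = self.config.shared_quality_sd
            eff_fixed = "eps" in self.fixed
        else:
            Znum, Nden, raw = self.W, self.V, self.e_raw
            icept, load, sd, factor = "eta", "kappa", "tau", self.G
            shared = self.config.shared_access_sd
            eff_fixed = "e" in self.fixed
        ncol = Znum.shape[1]
        eff = (self.eps if block == "quality" else self.e)

        # intercepts (vectorised over columns)
        if icept not in self.fixed:
            cur = s[icept]
            prop = cur + self.step[icept] * self.rng.standard_normal(ncol)
            base = s[load][None, :] * factor[:, None] + eff
            dll = self.ll_scale * (
                _bin_kern(Znum, Nden, prop[None, :] + base) - _bin_kern(Znum, Nden, cur[None, :] + base)
            ).sum(axis=0) + self._coef_prior_delta(prop, cur)
            acc = np.log(self.rng.uniform(size=ncol)) < dll
            s[icept] = np.where(acc, prop, cur)
            self._track(icept, acc)
            if adapt:
                self._adapt(icept, acc, t, _SCALAR_TARGET)

        # free loadings (anchor column 0 stays at 1)
        if load not in self.fixed and ncol > 1:
            cur = s[load]
            prop = cur + self.step[load] * self.rng.standard_normal(ncol)
            prop[0] = cur[0]
            base = s[icept][None, :] + eff
            dll = self.ll_scale * (
                _bin_kern(Znum, Nden, base + prop[None, :] * factor[:, None])
                - _bin_kern(Znum, Nden, base + cur[None, :] * factor[:, None])
            ).sum(axis=0) + self._coef_prior_delta(prop, cur)
            dll[0] = -np.inf
            acc = np.log(self.rng.uniform(size=ncol)) < dll
            s[load] = np.where(acc, prop, cur)
            self._track(load, acc[1:])
            if adapt:
                self._adapt(load, np.concatenate([[_SCALAR_TARGET], acc[1:].astype(float)]), t, _SCALAR_TARGET)

        # overdispersion SDs (log-scale; non-centred, so they move the likelihood)
        if sd not in self.fixed and not eff_fixed:
            ss = self.config.scale_prior_sd
            cur = s[sd]
            base = s[icept][None, :] + s[load][None, :] * factor[:, None]
            if shared:
                prop_val = float(cur[0] * np.exp(self.step[sd][0] * self.rng.standard_normal()))
                prop = np.full(ncol, prop_val)
                dll = self.ll_scale * float(
                    (_bin_kern(Znum, Nden, base + prop[None, :] * raw)
                     - _bin_kern(Znum, Nden, base + cur[None, :] * raw)).sum()
                ) + 0.5 * (cur[0]**2 - prop_val**2) / ss**2 + (np.log(prop_val) - np.log(cur[0]))
                acc = np.log(self.rng.uniform()) < dll
                if acc:
                    s[sd] = prop
                self._track(sd, acc)
                if adapt:
                    self._adapt(sd, np.full(ncol, float(acc)), t, _SCALAR_TARGET)
            else:
                prop = cur * np.exp(self.step[sd] * self.rng.standard_normal(ncol))
                dll = self.ll_scale * (
                    _bin_kern(Znum, Nden, base + prop[None, :] * raw)
                    - _bin_kern(Znum, Nden, base + cur[None, :] * raw)
                ).sum(axis=0)
                dll += 0.5 * (cur**2 - prop**2) / ss**2 + (np.log(prop) - np.log(cur))
                acc = np.log(self.rng.uniform(size=ncol)) < dll
                s[sd] = np.where(acc, prop, cur)
                self._track(sd, acc)
                if adapt:
                    self._adapt(sd, acc, t, _SCALAR_TARGET)

    def _update_betas(self, t, adapt):
        names = []
        if self.model_id >= 2:
            names.append("beta1")
        if self.model_id >= 3:
            names += ["beta2", "beta3", "beta4"]
        cur_prior = self._latent_prior_sum()
        for name in names:
            if name in self.fixed:
                continue
            cur = self.s[name]
            prop = cur + self.step[name] * self.rng.standard_normal()
            prop_prior = self._latent_prior_sum(**{name: prop})
            dll = prop_prior - cur_prior + self._coef_prior_delta(prop, cur)
            acc = np.log(self.rng.uniform()) < dll
            if acc:
                self.s[name] = prop
                cur_prior = prop_prior
            self._track(name, acc)
            if adapt:
                self._adapt(name, acc, t, _SCALAR_TARGET)

    def _update_structural_scales(self, t, adapt):
        ss = self.config.scale_prior_sd
        scale_names = ["sigma_F"] + (["sigma_G"] if self.model_id >= 3 else [])
        cur_prior = self._latent_prior_sum()
        for name in scale_names:
            if name in self.fixed:
                continue
            cur = self.s[name]
            prop = cur * np.exp(self.step[name] * self.rng.standard_normal())
            prop_prior = self._latent_prior_sum(**{name: prop})
            dll = prop_prior - cur_prior
            dll += 0.5 * (cur**2 - prop**2) / ss**2 + (np.log(prop) - np.log(cur))
            acc = np.log(self.rng.uniform()) < dll
            if acc:
                self.s[name] = prop
                cur_prior = prop_prior
            self._track(name, acc)
            if adapt:
                self._adapt(name, acc, t, _SCALAR_TARGET)
        if self.model_id < 3 and "sigma_F" not in self.fixed and "F" not in self.fixed:
            self._update_sigmaF_interweaved(t, adapt)
        if self.model_id >= 3 and "rho" not in self.fixed:
            cur = self.s["rho"]
            z = np.arctanh(cur) + self.step["rho"] * self.rng.standard_normal()
            prop = float(np.tanh(z))
            dll = self._latent_prior_sum(rho=prop) - cur_prior
            dll += np.log1p(-prop**2) - np.log1p(-cur**2)  # Fisher-z Jacobian
            acc = np.log(self.rng.uniform()) < dll
            if acc:
                self.s["rho"] = prop
            self._track("rho", acc)
            if adapt:
                self._adapt("rho", acc, t, _SCALAR_TARGET)

    def _update_sigmaF_interweaved(self, t, adapt):
        """Joint rescaling of (sigma_F, F) holding the standardized residuals fixed.

        Complements the centred sigma_F update: near sigma_F = 0 the centred
        chain is funnel-shaped and a log-scale move on sigma_F alone cannot
        descend.  Rescaling F with sigma_F leaves the structural prior
        invariant (the Jacobian cancels it exactly), so the acceptance ratio
        involves only the data likelihood through F, the half-normal prior,
        and the log-random-walk Jacobian.
        """
        s = self.s
        cur = s["sigma_F"]
        prop = cur * np.exp(self.step["sigma_F"] * self.rng.standard_normal())
        mF = self._mean_F()
        Fp = mF + (prop / cur) * (self.F - mF)
        ss = self.config.scale_prior_sd
        dll = 0.5 * (cur**2 - prop**2) / ss**2 + (np.log(prop) - np.log(cur))
        if self.ll_scale:
            base = s["delta"][None, :] + self.eps
            lam = s["lam"][None, :]
            dll += float((
                _bin_kern(self.Z, self.N, base + lam * Fp[:, None])
                - _bin_kern(self.Z, self.N, base + lam * self.F[:, None])
            ).sum())
            ln0 = self._lognu()
            dll += float(np.sum(self._pois_kern(ln0 + s["gamma_F"] * (Fp - self.F)) - self._pois_kern(ln0)))
        acc = np.log(self.rng.uniform()) < dll
        if acc:
            s["sigma_F"] = prop
            self.F = Fp
        self._track("sigma_F_iw", acc)

    # -- one full scan ------------------------------------------------------
    def scan(self, t: int, adapt: bool) -> None:
        self._update_eps(t, adapt)
        if self.model_id >= 3:
            self._update_e(t, adapt)
        self._update_u(t, adapt)
        self._update_factors(t, adapt)
        self._update_omega()
        self._update_gammas(t, adapt)
        self._update_alpha(t, adapt)
        self._update_measurement("quality", t, adapt)
        if self.model_id >= 3:
            self._update_measurement("access", t, adapt)
        self._update_betas(t, adapt)
        self._update_structural_scales(t, adapt)

    # -- snapshots ----------------------------------------------------------
    def current_params(self) -> ModelParameters:
        s = self.s
        return ModelParameters(
            gamma0=float(s["gamma0"]), gamma_F=float(s["gamma_F"]),
            gamma_D=float(s["gamma_D"]), gamma_G=float(s["gamma_G"]),
            gamma_M=float(s["gamma_M"]), alpha=float(s["alpha"]),
            delta=s["delta"].copy(), lam=s["lam"].copy(), sigma=np.asarray(s["sigma"]).copy(),
            eta=s["eta"].copy(), kappa=s["kappa"].copy(), tau=np.asarray(s["tau"]).copy(),
            beta1=float(s["beta1"]), beta2=float(s["beta2"]),
            beta3=float(s["beta3"]), beta4=float(s["beta4"]),
            sigma_F=float(s["sigma_F"]), sigma_G=float(s["sigma_G"]),
            rho=float(s["rho"]), df=self.config.df,
        )

    def current_latents(self) -> LatentState:
        return LatentState(F=self.F.copy(), G=self.G.copy(), eps=self.eps.copy(),
                           e=self.e.copy(), u=self.u.copy(), omega=self.omega.copy())

    def log_posterior(self) -> float:
        params = self.current_params()
        lp = log_prior(params, self.config)
        if not np.isfinite(lp):
            return -np.inf
        lp += self._latent_prior_sum()
        lp += -0.5 * float(np.sum(self.eps_raw**2) + np.sum(self.e_raw**2) + np.sum(self.u_raw**2))
        if self.ll_scale:
            pw = pointwise_loglik(params, self.current_latents(), self.table, self.model_id)
            lp += sum(float(np.sum(v)) for v in pw.values())
        return float(lp)


def initialize_chain(table: PracticeTable, config: ModelConfig, seed: int):
    """Initial parameter and latent values with a finite log-posterior.

    Indicator intercepts start at pooled empirical logits with a
    (x+0.5)/(n+1) continuity correction (so all-zero columns stay finite);
    factor scores start at zero plus jitter, scales at 0.1, coefficients at
    zero plus jitter.  Re-jitters up to 100 times if the log-posterior is
    non-finite.
    """
    rng = np.random.default_rng(seed)
    for _ in range(100):
        chain = _Chain(table, config, rng)
        if np.isfinite(chain.log_posterior()):
            return chain.current_params(), chain.current_latents()
    raise RuntimeError("could not find initial values with finite log-posterior")


_SCALAR_PARAMS = ("gamma0", "gamma_F", "gamma_D", "gamma_G", "gamma_M", "alpha",
                  "beta1", "beta2", "beta3", "beta4", "sigma_F", "sigma_G", "rho")


def _recorded_names(config: ModelConfig, K: int):
    scalars = list(config.gamma_names) + ["alpha", "sigma_F"]
    if config.model_id >= 2:
        scalars.append("beta1")
    if config.has_access:
        scalars += ["beta2", "beta3", "beta4", "sigma_G", "rho"]
    vectors = ["delta", "lam", "sigma"]
    if config.has_access:
        vectors += ["eta", "kappa", "tau"]
    return scalars, vectors


def run_mcmc(
    table: PracticeTable,
    config: ModelConfig,
    chains: int = 4,
    iterations: int = 20_000,
    burn_in: int = 10_000,
    seed: int = 0,
    thin: int = 5,
    progress_callback=None,
) -> PosteriorDraws:
    """Fit a model variant by adaptive Metropolis-within-Gibbs.

    ``table`` must carry expected counts and standardized covariates (the
    :class:`AdmissionsSEM` front-end arranges both).  Identical arguments
    produce identical draws.  Retained draws are the post-burn-in
    iterations thinned by ``thin``; adaptation runs only during burn-in.
    """
    if iterations <= burn_in:
        raise ValueError("iterations must exceed burn_in")
    if table.E is None:
        raise ValueError("table has no expected counts; call compute_expected_counts first")
    n_keep = (iterations - burn_in) // thin
    if n_keep < 1:
        raise ValueError("no draws retained; reduce thin or burn_in")
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(chains)]
    scalars, vectors = _recorded_names(config, table.K)
    all_draws: dict[str, list] = {}
    all_ll: dict[str, list] = {}
    acc_rates = {}
    for c in range(chains):
        rng = np.random.default_rng(seeds[c])
        chain = _Chain(table, config, rng)
        if not np.isfinite(chain.log_posterior()):
            for _ in range(100):
                chain = _Chain(table, config, rng)
                if np.isfinite(chain.log_posterior()):
                    break
            else:
                raise RuntimeError("initialization failed: non-finite log-posterior after 100 re-draws")
        rec: dict[str, list] = {k: [] for k in scalars + vectors + ["F", "G", "u", "eps", "e", "omega", "nu"]}
        ll_rec: dict[str, list] = {}
        for t in range(iterations):
            chain.scan(t, adapt=t < burn_in)
            if t >= burn_in and (t - burn_in) % thin == 0:
                params = chain.current_params()
                latents = chain.current_latents()
                for k in scalars:
                    rec[k].append(float(chain.s[k]))
                for k in vectors:
                    rec[k].append(np.asarray(chain.s[k], dtype=float).copy())
                rec["F"].append(latents.F)
                rec["G"].append(latents.G)
                rec["u"].append(latents.u)
                rec["eps"].append(latents.eps)
                rec["e"].append(latents.e)
                rec["omega"].append(latents.omega)
                rec["nu"].append(linear_predictor_nu(params, latents, table, config.model_id))
                pw = pointwise_loglik(params, latents, table, config.model_id)
                for comp, arr in pw.items():
                    ll_rec.setdefault(comp, []).append(arr)
            if progress_callback is not None and (t + 1) % 1000 == 0:
                progress_callback(c, t + 1)
        if not config.has_access:
            rec.pop("G"), rec.pop("e")
        if config.model_id != 4:
            rec.pop("omega")
        for k, v in rec.items():
            all_draws.setdefault(k, []).append(np.asarray(v))
        for k, v in ll_rec.items():
            all_ll.setdefault(k, []).append(np.asarray(v))
        acc_rates[f"chain{c}"] = {k: (a / n if n else np.nan) for k, (a, n) in chain.acc.items()}
    draws = {k: np.stack(v) for k, v in all_draws.items()}
    pointwise_ll = {k: np.stack(v) for k, v in all_ll.items()}
    meta = {
        "seed": seed,
        "chain_seeds": seeds,
        "chains": chains,
        "iterations": iterations,
        "burn_in": burn_in,
        "thin": thin,
        "model_id": config.model_id,
        "gamma_names": list(config.gamma_names),
        "acceptance_rates": acc_rates,
        "practice_id": list(table.practice_id),
    }
    return PosteriorDraws(draws=draws, pointwise_ll=pointwise_ll, meta=meta)


# ---------------------------------------------------------------------------
# diagnostics and summaries
# ---------------------------------------------------------------------------


def convergence_report(draws: PosteriorDraws) -> pd.DataFrame:
    """Split-R-hat, effective sample size and Monte Carlo SE per parameter.

    Parameters with R-hat above 1.05 (or undefined R-hat from degenerate
    chains) are flagged.  With a single chain R-hat is unavailable but ESS
    is still computed.
    """
    import arviz as az

    scalars = draws.expand_scalars()
    rows = []
    for name, arr in scalars.items():
        sd = float(np.std(arr))
        if sd == 0.0:
            rows.append((name, np.nan, np.nan, 0.0, True, "constant draws"))
            continue
        ess = float(az.ess(arr))
        mcse = sd / np.sqrt(max(ess, 1.0))
        if arr.shape[0] >= 2:
            rhat = float(az.rhat(arr))
            flagged = (not np.isfinite(rhat)) or rhat > 1.05
            note = "" if np.isfinite(rhat) else "R-hat undefined"
        else:
            rhat, flagged, note = np.nan, False, "single chain"
        rows.append((name, rhat, ess, mcse, flagged, note))
    return pd.DataFrame(rows, columns=["parameter", "rhat", "ess", "mcse", "flagged", "note"]).set_index("parameter")


def posterior_summaries(draws: PosteriorDraws) -> pd.DataFrame:
    """Mean, SD and central 95% interval per parameter (linear-interpolated quantiles)."""
    rows = {}
    for name, arr in draws.expand_scalars().items():
        flat = arr.reshape(-1)
        rows[name] = {
            "mean": float(np.mean(flat)),
            "sd": float(np.std(flat, ddof=1)) if flat.size > 1 else 0.0,
            "2.5%": float(np.quantile(flat, 0.025)),
            "97.5%": float(np.quantile(flat, 0.975)),
        }
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# model / results front-end
# ---------------------------------------------------------------------------


class AdmissionsSEM:
    """Structural equation model for admissions with latent quality/access.

    Parameters
    ----------
    table : PracticeTable
        Validated practice data.  Covariates are standardized internally
        (the record is kept for back-transformation); if no expected counts
        are present they are constructed from ``expected_basis``.
    config : ModelConfig, optional
        Model variant and priors; defaults to the full structural model
        (model 3).
    """

    def __init__(self, table: PracticeTable, config: ModelConfig | None = None,
                 expected_basis: str = "diabetes_register"):
        self.config = config or ModelConfig()
        if table.E is None:
            table = compute_expected_counts(table, expected_basis)
        self.raw_table = table
        self.table, self.standardization = standardize_covariates(table)

    @classmethod
    def from_csv(cls, path, config: ModelConfig | None = None, schema: dict | None = None,
                 expected_basis: str = "diabetes_register") -> "AdmissionsSEM":
        from .data import read_practice_table

        return cls(read_practice_table(path, schema), config, expected_basis)

    @classmethod
    def from_dataframe(cls, df, config: ModelConfig | None = None, schema: dict | None = None,
                       expected_basis: str = "diabetes_register") -> "AdmissionsSEM":
        return cls(PracticeTable.from_dataframe(df, schema), config, expected_basis)

    def fit(self, chains: int = 4, iterations: int = 20_000, burn_in: int = 10_000,
            thin: int = 5, seed: int = 0, progress_callback=None) -> "SEMResults":
        draws = run_mcmc(self.table, self.config, chains=chains, iterations=iterations,
                         burn_in=burn_in, seed=seed, thin=thin,
                         progress_callback=progress_callback)
        return SEMResults(self, draws)


class SEMResults:
    """Posterior draws plus summaries, diagnostics, and criticism methods."""

    def __init__(self, model: AdmissionsSEM, draws: PosteriorDraws):
        self.model = model
        self.draws = draws

    # -- tables -----------------------------------------------------------
    def posterior_summaries(self) -> pd.DataFrame:
        return posterior_summaries(self.draws)

    def convergence_report(self) -> pd.DataFrame:
        return convergence_report(self.draws)

    def coefficient_table(self) -> pd.DataFrame:
        """Outcome-model coefficients with sign probabilities (report layout)."""
        from .criticism import sign_probability

        rows = []
        for name in self.model.config.gamma_names:
            flat = self.draws.stacked(name)
            p_neg = sign_probability(self.draws, name)
            rows.append({
                "label": COEF_LABELS[name], "symbol": name,
                "mean": float(np.mean(flat)), "sd": float(np.std(flat, ddof=1)),
                "2.5%": float(np.quantile(flat, 0.025)),
                "97.5%": float(np.quantile(flat, 0.975)),
                "Pr(positive)": 1.0 - p_neg, "Pr(negative)": p_neg,
            })
        flat = self.draws.stacked("alpha")
        rows.append({
            "label": COEF_LABELS["alpha"], "symbol": "alpha",
            "mean": float(np.mean(flat)), "sd": float(np.std(flat, ddof=1)),
            "2.5%": float(np.quantile(flat, 0.025)),
            "97.5%": float(np.quantile(flat, 0.975)),
            "Pr(positive)": np.nan, "Pr(negative)": np.nan,
        })
        return pd.DataFrame(rows).set_index("label")

    def loading_table(self) -> pd.DataFrame:
        """Measurement-model loadings and structural coefficients."""
        specs = [("lambda", "lam", self.model.table.J)]
        if self.model.config.has_access:
            specs.append(("kappa", "kappa", self.model.table.K))
        rows = []
        for label, key, n in specs:
            arr = self.draws.stacked(key)
            for j in range(n):
                flat = arr[:, j]
                rows.append({
                    "parameter": f"{label}[{j + 1}]",
                    "mean": float(np.mean(flat)),
                    "2.5%": float(np.quantile(flat, 0.025)),
                    "97.5%": float(np.quantile(flat, 0.975)),
                })
        extra = []
        if self.model.config.model_id >= 2:
            extra.append("beta1")
        if self.model.config.has_access:
            extra += ["beta2", "beta3", "beta4", "rho"]
        for name in extra:
            flat = self.draws.stacked(name)
            rows.append({
                "parameter": name,
                "mean": float(np.mean(flat)),
                "2.5%": float(np.quantile(flat, 0.025)),
                "97.5%": float(np.quantile(flat, 0.975)),
            })
        return pd.DataFrame(rows).set_index("parameter")

    def factor_scores(self) -> pd.DataFrame:
        """Posterior mean/SD of the latent scores per practice."""
        out = {"practice_id": self.draws.meta["practice_id"]}
        F = self.draws.stacked("F")
        out["F_mean"], out["F_sd"] = F.mean(axis=0), F.std(axis=0, ddof=1)
        if "G" in self.draws.draws:
            G = self.draws.stacked("G")
            out["G_mean"], out["G_sd"] = G.mean(axis=0), G.std(axis=0, ddof=1)
        nu = self.draws.stacked("nu")
        out["nu_mean"] = nu.mean(axis=0)
        return pd.DataFrame(out).set_index("practice_id")

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            f"Admissions SEM (model {cfg.model_id}), I={self.model.table.I} practices, "
            f"J={self.model.table.J} quality / K={self.model.table.K} access indicators",
            f"chains={self.draws.n_chains}, kept draws per chain={self.draws.n_kept}",
            "",
            "Outcome regression (log relative risk of emergency admission):",
            self.coefficient_table().round(3).to_string(),
            "",
            "Measurement and structural parameters:",
            self.loading_table().round(3).to_string(),
        ]
        return "\n".join(lines)

    # -- criticism (delegating) --------------------------------------------
    def waic(self, component: str):
        from .criticism import waic

        return waic(self.draws, component)

    def ppc(self, variable: str) -> float:
        from .criticism import posterior_predictive_check

        return posterior_predictive_check(self.draws, self.model.table, variable)

    def sign_probability(self, coefficient: str) -> float:
        from .criticism import sign_probability

        return sign_probability(self.draws, coefficient)

    def bayes_factor(self, coefficient: str, direction: str = "negative") -> float:
        from .criticism import marginal_bayes_factor, sign_probability

        p = sign_probability(self.draws, coefficient)
        if direction == "positive":
            p = 1.0 - p
        return marginal_bayes_factor(p)

    def factor_risk_curve(self, factor: str = "F") -> pd.DataFrame:
        from .criticism import factor_risk_curve

        return factor_risk_curve(self.draws, factor)

    def fit_report(self) -> dict:
        from .criticism import fit_report

        return fit_report(self.draws, self.model.table)

    def aggregate_scores(self, crosswalk, factor: str = "G", per_draw: bool = True):
        from .geography import aggregate_to_areas

        if factor not in self.draws.draws:
            raise ValueError(f"factor '{factor}' not present in this model's draws")
        scores = self.draws.stacked(factor) if per_draw else self.draws.stacked(factor).mean(axis=0)
        return aggregate_to_areas(scores, crosswalk, practice_id=self.draws.meta["practice_id"])

    def plot_factor_risk(self, factor: str = "F", ax=None):
        """Scatter of posterior-mean factor score vs relative risk with LOWESS."""
        import matplotlib.pyplot as plt

        curve = self.factor_risk_curve(factor)
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(curve["score"], curve["nu"], s=12, alpha=0.7)
        ax.plot(curve["score"], curve["smooth"], color="C1")
        ax.set_xlabel("latent quality score F" if factor == "F" else "latent poor-access score G")
        ax.set_ylabel("emergency admission relative risk (posterior mean)")
        return ax
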