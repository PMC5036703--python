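"""Synthetic practice-table generator mirroring the study's data structure.

The generator emulates a two-CCG study population: by default 90 GP
practices, four binomial clinical quality indicators with heterogeneous
register denominators, four patient-survey access indicators, correlated
bivariate latent quality/access factors with covariate-driven means, and an
overdispersed Poisson admissions outcome.  It exists so that every
downstream stage (fitting, criticism, aggregation) is testable without the
undeposited study data, and to drive parameter-recovery experiments.

Covariates are drawn on their natural scales (income-deprivation share,
age-standardised morbidity rate, FTE GPs per 1000 patients, list size in
000s, with deprivation and morbidity correlated at 0.7) but the structural
and outcome coefficients are applied to *internally standardized* versions,
matching the standardization the fitting pipeline performs — so published
coefficient values used as truths are recoverable on the same scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .data import CrosswalkMatrix, PracticeTable
from .likelihood import LatentState, ModelParameters, default_study_parameters

__all__ = [
    "CovariateConfig",
    "DenominatorConfig",
    "GeneratorConfig",
    "SimulationResult",
    "generate_covariates",
    "generate_latents",
    "generate_indicators",
    "generate_outcome",
    "generate_crosswalk",
    "simulate_practice_table",
]


@dataclass
class CovariateConfig:
    """Distributions of the practice covariates (natural scales)."""

    mean_D: float = 0.20      # income-deprivation score (share)
    sd_D: float = 0.08
    mean_M: float = 6.0       # age-standardised diabetes rate (per 100)
    sd_M: float = 1.5
    corr_D_M: float = 0.7     # deprivation-morbidity correlation
    mean_S1: float = 0.58     # FTE GPs per 1000 patients
    sd_S1: float = 0.15
    mean_S2: float = 7.0      # list size in 000s
    sd_S2: float = 3.0


@dataclass
class DenominatorConfig:
    """Uniform-integer ranges for indicator denominators."""

    quality_min: int = 50
    quality_max: int = 600
    access_min: int = 50
    access_max: int = 200

    def __post_init__(self) -> None:
        if self.quality_min < 1 or self.access_min < 1:
            raise ValueError("denominator minimum must be >= 1")


@dataclass
class GeneratorConfig:
    """Study-condition defaults: I=90 practices, J=K=4 indicators.

    ``true_params`` defaults to the published full-model posterior means
    (see :func:`~admitsem.likelihood.default_study_parameters`).
    ``factor_family`` selects bivariate normal factors or the Student-t
    scale mixture (df taken from ``true_params.df``, default 4).
    ``admission_rate`` sets the expected admissions per register patient
    used to build the exposure ``E``.
    """

    I: int = 90
    J: int = 4
    K: int = 4
    true_params: ModelParameters | None = None
    denominators: DenominatorConfig = field(default_factory=DenominatorConfig)
    covariates: CovariateConfig = field(default_factory=CovariateConfig)
    factor_family: str = "normal"
    admission_rate: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.I < 2:
            raise ValueError("need at least two practices")
        if self.factor_family not in ("normal", "student_t"):
            raise ValueError("factor_family must be 'normal' or 'student_t'")
        if self.true_params is None:
            self.true_params = default_study_parameters(self.J, self.K)
        if self.factor_family == "student_t" and self.true_params.df <= 2:
            raise ValueError("Student-t df must exceed 2")


@dataclass
class SimulationResult:
    """A simulated dataset with its generating truth attached."""

    table: PracticeTable
    latents: LatentState
    params: ModelParameters
    covariates_std: dict


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def generate_covariates(config: GeneratorConfig, rng: np.random.Generator):
    """Draw raw covariates and their standardized versions.

    Returns ``(raw, std)`` dicts with keys D, Mrate, S1, S2.  Supply and
    list-size draws are clipped away from zero (they are physical
    quantities).
    """
    c = config.covariates
    cov = np.array(
        [
            [c.sd_D**2, c.corr_D_M * c.sd_D * c.sd_M],
            [c.corr_D_M * c.sd_D * c.sd_M, c.sd_M**2],
        ]
    )
    dm = rng.multivariate_normal([c.mean_D, c.mean_M], cov, size=config.I)
    raw = {
        "D": np.clip(dm[:, 0], 0.005, None),
        "Mrate": np.clip(dm[:, 1], 0.5, None),
        "S1": np.clip(rng.normal(c.mean_S1, c.sd_S1, config.I), 0.1, None),
        "S2": np.clip(rng.normal(c.mean_S2, c.sd_S2, config.I), 0.5, None),
    }
    std = {k: _standardize(v) for k, v in raw.items()}
    return raw, std


def generate_latents(config: GeneratorConfig, covariates_std: dict, rng: np.random.Generator):
    """Draw (F, G, omega) from the structural model.

    Means are ``beta1*D`` for quality and ``beta2*D + beta3*S1 + beta4*S2``
    for poor access; the covariance is ``Sigma/omega_i`` where ``omega_i=1``
    (normal family) or Gamma(df/2, df/2) (Student-t family).
    """
    p = config.true_params
    if not (p.sigma_F > 0 and p.sigma_G > 0 and -1 < p.rho < 1):
        raise ValueError("latent covariance is not positive definite")
    I = config.I
    if config.factor_family == "student_t":
        omega = rng.gamma(shape=p.df / 2.0, scale=2.0 / p.df, size=I)
    else:
        omega = np.ones(I)
    meanF = p.beta1 * covariates_std["D"]
    meanG = (
        p.beta2 * covariates_std["D"]
        + p.beta3 * covariates_std["S1"]
        + p.beta4 * covariates_std["S2"]
    )
    z = rng.standard_normal((I, 2))
    # Cholesky of [[1, rho], [rho, 1]] applied to scaled draws
    a = np.sqrt(1.0 - p.rho**2)
    scale = 1.0 / np.sqrt(omega)
    F = meanF + p.sigma_F * scale * z[:, 0]
    G = meanG + p.sigma_G * scale * (p.rho * z[:, 0] + a * z[:, 1])
    return F, G, omega


def generate_indicators(config: GeneratorConfig, F: np.ndarray, G: np.ndarray, rng: np.random.Generator):
    """Draw the binomial indicator blocks given the latent factors.

    Returns ``(Z, N, W, V, eps, e)`` where ``eps``/``e`` are the logit-scale
    overdispersion effects actually used.
    """
    p = config.true_params
    d = config.denominators
    I, J, K = config.I, config.J, config.K
    N = rng.integers(d.quality_min, d.quality_max + 1, size=(I, J))
    V = rng.integers(d.access_min, d.access_max + 1, size=(I, K))
    eps = rng.standard_normal((I, J)) * p.sigma[None, :]
    e = rng.standard_normal((I, K)) * p.tau[None, :]
    pi = expit(p.delta[None, :] + p.lam[None, :] * F[:, None] + eps)
    pw = expit(p.eta[None, :] + p.kappa[None, :] * G[:, None] + e)
    Z = rng.binomial(N, pi)
    W = rng.binomial(V, pw)
    return Z, N, W, V, eps, e


def generate_outcome(
    config: GeneratorConfig,
    F: np.ndarray,
    G: np.ndarray,
    covariates_std: dict,
    E: np.ndarray,
    rng: np.random.Generator,
):
    """Draw admissions ``Y ~ Poisson(E * nu)`` with overdispersed log risk.

    ``log nu = g0 + gF*F + gD*D + gG*G + gM*Mrate + u``; nested model
    variants are obtained by zeroing the relevant true coefficients.
    """
    p = config.true_params
    u = rng.standard_normal(config.I) * p.alpha
    lognu = (
        p.gamma0
        + p.gamma_F * F
        + p.gamma_D * covariates_std["D"]
        + p.gamma_G * G
        + p.gamma_M * covariates_std["Mrate"]
        + u
    )
    Y = rng.poisson(np.asarray(E) * np.exp(lognu))
    return Y, u


def simulate_practice_table(config: GeneratorConfig, seed: int | None = None) -> SimulationResult:
    """Generate a full practice table under the configured truth.

    The expected count is ``E_i = admission_rate * register_i`` with the
    register taken as the per-practice mean quality denominator, so the
    simulated relative risks are interpretable against a fixed exposure.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    raw, std = generate_covariates(config, rng)
    F, G, omega = generate_latents(config, std, rng)
    Z, N, W, V, eps, e = generate_indicators(config, F, G, rng)
    register = N.mean(axis=1)
    E = config.admission_rate * register
    Y, u = generate_outcome(config, F, G, std, E, rng)
    table = PracticeTable(
        practice_id=[f"P{i + 1:03d}" for i in range(config.I)],
        Z=Z,
        N=N,
        W=W,
        V=V,
        Y=Y,
        E=E,
        D=raw["D"],
        Mrate=raw["Mrate"],
        S1=raw["S1"],
        S2=raw["S2"],
    )
    latents = LatentState(F=F, G=G, eps=eps, e=e, u=u, omega=omega)
    return SimulationResult(table=table, latents=latents, params=config.true_params.copy(), covariates_std=std)


def generate_crosswalk(config: GeneratorConfig, L: int, seed: int | None = None, max_serving: int = 4) -> CrosswalkMatrix:
    """Row-stochastic L x I area-by-practice population-share matrix.

    Each area's population is split across a small random subset of
    practices (1..max_serving) with Dirichlet shares — the sparse support
    typical of neighbourhood-to-practice registration patterns.
    """
    if L < 1:
        raise ValueError("need at least one area")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    I = config.I
    w = np.zeros((L, I))
    for l in range(L):
        n_serving = int(rng.integers(1, min(max_serving, I) + 1))
        practices = rng.choice(I, size=n_serving, replace=False)
        w[l, practices] = rng.dirichlet(np.ones(n_serving))
    return CrosswalkMatrix(
        area_id=[f"A{l + 1:04d}" for l in range(L)],
        practice_id=[f"P{i + 1:03d}" for i in range(I)],
        weights=w,
    )
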