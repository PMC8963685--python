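"""Synthetic target populations and TND samples with latent truth.

Two generating mechanisms mirror the structure under which the negative
control method is designed to work (the DAG with unmeasured confounder U,
NCE Z, NCO W, auxiliary illness D and outcome-dependent selection S):

* a **binary** world — binary U, Z, W, D with a log-linear risk model
  ``Y | A, U ~ Bernoulli(exp(η0Y + β0 A + ηUY U))`` and selection possible
  only when at least one of Y, W, D equals one;
* a **continuous** world — standard-normal U and X, logistic treatment,
  Gaussian NCE and NCO, log-linear risk
  ``Y | A, U, X ~ Bernoulli(exp(μ0Y + β0 A + μUY U + μXY X + μUXY U X))``
  and selection possible only when Y or D is nonzero.

Selection probabilities depend on (Y, W, D) only, so treatment-independent
sampling (S ⫫ A | Y, U, W, D, X) holds by construction.  Both generators
expose the latent variables (U, D, S) for oracle computations; they are
stripped when a :class:`~tndbridge.sample.TNDSample` is extracted.

Default parameter values are calibrated so that the target-population
infection prevalence among the unvaccinated is ≈0.75 % (binary) and
≈0.34 % (continuous), with a vaccinated-arm prevalence of ≈0.72 % in the
binary world at β0 = −0.357 (risk ratio 0.7).  See ``docs/methods.md`` for
the calibration details and what these defaults do and do not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .bridge import BridgeModel, CellProbabilities, closed_form_binary_bridge
from .sample import TNDSample

__all__ = [
    "BinaryDGPConfig",
    "ContinuousDGPConfig",
    "PopulationFrame",
    "simulate_binary_population",
    "simulate_continuous_population",
    "select_tnd_sample",
    "oracle_bridge_binary",
    "oracle_bridge_continuous",
    "bridge_table",
    "true_inverse_propensity",
    "prevalence_report",
    "PrevalenceReport",
]


def _check_prob(name, *vals):
    for v in vals:
        if not 0.0 <= float(v) <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]; got {v}")


# Binary-world risk-model calibration.  With P(A=1|U) = (0.15, 0.85) and
# P(U=1) = 0.5, the marginal confounding ratio r = E[g(U)|A=1]/E[g(U)|A=0]
# determines the confounder risk effect exp(eta_uy) in closed form; r is
# matched to the target prevalences (0.75 % unvaccinated; vaccinated-arm
# prevalence r·exp(β0)·0.75 %), keeping every stratum risk ≈ 1 % so the
# rare-infection condition that licenses estimating the bridge from
# test-negative controls holds comfortably.
_R_CONFOUND = 48 / 35
_E_UY = (_R_CONFOUND * 0.85 - 0.15) / (0.85 - _R_CONFOUND * 0.15)
_ETA_UY = float(np.log(_E_UY))
_ETA_0Y_RARE = float(np.log(0.0075 / (0.85 + 0.15 * _E_UY)))


@dataclass(frozen=True)
class BinaryDGPConfig:
    """Binary-world generator.  All parameters are probabilities or
    log-linear risk coefficients.

    The defaults reproduce an unvaccinated prevalence of exactly 0.75 %
    and a marginal confounding ratio E[g(U)|A=1]/E[g(U)|A=0] = 48/35, so
    the vaccinated-arm prevalence at β0 = −0.357 is 0.72 % and the maximal
    stratum risk stays near 1 % (rare in every stratum).
    """

    beta0: float = -0.693
    p_u: float = 0.5
    #: P(A=1 | U=u) for u = 0, 1
    p_a_given_u: tuple[float, float] = (0.15, 0.85)
    #: P(Z=1 | A=a, U=u) indexed [a][u]; the NCE must proxy U strongly for
    #: the bridge to stay well behaved under this much confounding
    p_z_given_au: tuple[tuple[float, float], tuple[float, float]] = (
        (0.05, 0.95), (0.05, 0.95))
    #: P(W=1 | U=u)
    p_w_given_u: tuple[float, float] = (0.1, 0.6)
    #: P(D=1 | U=u)
    p_d_given_u: tuple[float, float] = (0.2, 0.35)
    eta_0y: float = _ETA_0Y_RARE
    eta_uy: float = _ETA_UY
    #: P(S=1 | Y=1) and P(S=1 | Y=0, W=1 or D=1); zero when Y=W=D=0
    p_select_case: float = 0.5
    p_select_symptomatic: float = 0.012
    n: int = 1_000_000
    seed: Optional[int] = None

    def __post_init__(self):
        _check_prob("p_u", self.p_u)
        _check_prob("p_a_given_u", *self.p_a_given_u)
        _check_prob("p_z_given_au", *self.p_z_given_au[0], *self.p_z_given_au[1])
        _check_prob("p_w_given_u", *self.p_w_given_u)
        _check_prob("p_d_given_u", *self.p_d_given_u)
        _check_prob("selection", self.p_select_case, self.p_select_symptomatic)
        if self.n < 1:
            raise ValueError("population size must be positive")
        max_risk = np.exp(self.eta_0y + max(self.beta0, 0.0) + self.eta_uy)
        if max_risk > 1.0:
            raise ValueError(
                f"invalid log-linear risk model: maximal stratum risk "
                f"{max_risk:.4f} exceeds 1")

    def replace(self, **kw) -> "BinaryDGPConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class ContinuousDGPConfig:
    """Continuous-world generator: U, X ~ N(0,1) independent; logistic
    treatment; Gaussian NCE/NCO; log-linear risk; logistic auxiliary
    illness D.  ``mu_uz`` must be nonzero for a bridge to exist."""

    beta0: float = -0.693
    #: effect-modification slope: the log RR at covariate level x is
    #: beta0 + beta_x * x (0 = homogeneous effect)
    beta_x: float = 0.0
    # treatment A | U, X ~ Bernoulli(expit(mu_0a + mu_ua U + mu_xa X))
    mu_0a: float = 0.0
    mu_ua: float = 1.0
    mu_xa: float = 0.3
    # NCE Z | A, U, X ~ N(mu_0z + mu_az A + mu_uz U + mu_xz X, sigma_z^2)
    mu_0z: float = 0.0
    mu_az: float = 0.3
    mu_uz: float = 1.5
    mu_xz: float = 0.2
    sigma_z: float = 1.0
    # NCO W | U, X ~ N(mu_0w + mu_uw U + mu_xw X, sigma_w^2)
    mu_0w: float = 0.0
    mu_uw: float = 1.0
    mu_xw: float = 0.3
    sigma_w: float = 1.0
    # outcome Y | A, U, X ~ Bernoulli(exp(mu_0y + beta0 A + mu_uy U
    #                                     + mu_xy X + mu_uxy U X)).
    # mu_0y and mu_uy are calibrated by Gauss-Hermite quadrature so the
    # unvaccinated prevalence is 0.34 % and the marginal confounding ratio
    # matches the vaccinated-arm calibration target (r ~ 1.303); the
    # risk-validity tail probability is ~3e-22 per subject.
    mu_0y: float = -5.605894705865258
    mu_uy: float = 0.23398928827806034
    mu_xy: float = 0.25
    mu_uxy: float = 0.05
    # auxiliary illness D | U, X ~ Bernoulli(expit(nu_0 + nu_u U + nu_x X))
    nu_0: float = -2.2
    nu_u: float = 0.6
    nu_x: float = 0.3
    #: P(S=1 | Y=1) and P(S=1 | Y=0, D=1); zero when Y=D=0
    p_select_case: float = 0.5
    p_select_symptomatic: float = 0.05
    n: int = 1_000_000
    seed: Optional[int] = None

    def __post_init__(self):
        if self.mu_uz == 0.0:
            raise ValueError("mu_uz must be nonzero for a bridge to exist")
        if self.sigma_z <= 0 or self.sigma_w <= 0:
            raise ValueError("sigma_z and sigma_w must be positive")
        _check_prob("selection", self.p_select_case, self.p_select_symptomatic)
        if self.n < 1:
            raise ValueError("population size must be positive")

    def replace(self, **kw) -> "ContinuousDGPConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class PopulationFrame:
    """Full target population including latent variables.

    ``data`` holds one row per subject with columns ``u, a, z, w, d, y, s``
    (plus ``x`` in the continuous world).  The latent columns ``u, d, s``
    exist only here; :func:`select_tnd_sample` strips them.
    """

    data: pd.DataFrame
    setting: str
    config: object

    @property
    def n(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def _rng(config, seed):
    if seed is None:
        seed = config.seed
    return np.random.default_rng(seed)


def simulate_binary_population(config: BinaryDGPConfig,
                               seed: Optional[int] = None) -> PopulationFrame:
    """Draw a binary-world population of size ``config.n``.

    Sampling order follows the causal factorisation
    U → (A|U) → (Z|A,U), (W|U), (D|U), (Y|A,U) → (S|Y,W,D);
    reproducible bit-for-bit from the seed.
    """
    rng = _rng(config, seed)
    n = config.n
    u = (rng.random(n) < config.p_u).astype(np.int8)
    pa = np.asarray(config.p_a_given_u)[u]
    a = (rng.random(n) < pa).astype(np.int8)
    pz = np.asarray(config.p_z_given_au)[a, u]
    z = (rng.random(n) < pz).astype(np.int8)
    w = (rng.random(n) < np.asarray(config.p_w_given_u)[u]).astype(np.int8)
    d = (rng.random(n) < np.asarray(config.p_d_given_u)[u]).astype(np.int8)
    risk = np.exp(config.eta_0y + config.beta0 * a + config.eta_uy * u)
    y = (rng.random(n) < risk).astype(np.int8)
    p_sel = np.where(y == 1, config.p_select_case,
                     np.where((w == 1) | (d == 1),
                              config.p_select_symptomatic, 0.0))
    s = (rng.random(n) < p_sel).astype(np.int8)
    df = pd.DataFrame({"u": u, "a": a, "z": z, "w": w, "d": d, "y": y, "s": s})
    return PopulationFrame(df, "binary", config)


def simulate_continuous_population(config: ContinuousDGPConfig,
                                   seed: Optional[int] = None
                                   ) -> PopulationFrame:
    """Draw a continuous-world population of size ``config.n``.

    The log-linear risk model is only valid where the modelled risk is ≤ 1;
    the draw errors out if any subject violates this (the defaults make the
    violation probability ≈ 5e−9 per subject).
    """
    rng = _rng(config, seed)
    n = config.n
    u = rng.standard_normal(n)
    x = rng.standard_normal(n)
    lin_a = config.mu_0a + config.mu_ua * u + config.mu_xa * x
    a = (rng.random(n) < 1.0 / (1.0 + np.exp(-lin_a))).astype(np.int8)
    z = (config.mu_0z + config.mu_az * a + config.mu_uz * u
         + config.mu_xz * x + config.sigma_z * rng.standard_normal(n))
    w = (config.mu_0w + config.mu_uw * u + config.mu_xw * x
         + config.sigma_w * rng.standard_normal(n))
    log_rr = config.beta0 + config.beta_x * x
    risk = np.exp(config.mu_0y + log_rr * a + config.mu_uy * u
                  + config.mu_xy * x + config.mu_uxy * u * x)
    n_bad = int(np.sum(risk > 1.0))
    if n_bad:
        raise ValueError(
            f"invalid risk configuration: {n_bad} subject(s) have modelled "
            "infection risk > 1")
    y = (rng.random(n) < risk).astype(np.int8)
    lin_d = config.nu_0 + config.nu_u * u + config.nu_x * x
    d = (rng.random(n) < 1.0 / (1.0 + np.exp(-lin_d))).astype(np.int8)
    p_sel = np.where(y == 1, config.p_select_case,
                     np.where(d == 1, config.p_select_symptomatic, 0.0))
    s = (rng.random(n) < p_sel).astype(np.int8)
    df = pd.DataFrame({"u": u, "x": x, "a": a, "z": z, "w": w,
                       "d": d, "y": y, "s": s})
    return PopulationFrame(df, "continuous", config)


def select_tnd_sample(pop: PopulationFrame) -> TNDSample:
    """Rows with S = 1, exporting only (A, Y, Z, W, X).

    The latent columns (U, D, S) never reach estimation code paths.
    """
    sel = pop.data[pop.data["s"] == 1]
    if not len(sel):
        raise ValueError("no subjects were selected into the TND sample")
    x = sel[["x"]].to_numpy() if "x" in sel.columns else None
    return TNDSample(a=sel["a"].to_numpy(), y=sel["y"].to_numpy(),
                     z=sel["z"].to_numpy(), w=sel["w"].to_numpy(), x=x)


# ---------------------------------------------------------------------------
# analytic oracle bridges
# ---------------------------------------------------------------------------

def _binary_cells(config: BinaryDGPConfig) -> CellProbabilities:
    """Exact p_{za.u} = P(Z=z, A=a | U=u) from the generator parameters."""
    p = np.zeros((2, 2, 2))
    for uu in (0, 1):
        for aa in (0, 1):
            p_a = config.p_a_given_u[uu] if aa == 1 else 1 - config.p_a_given_u[uu]
            for zz in (0, 1):
                p_z = config.p_z_given_au[aa][uu]
                p[zz, aa, uu] = (p_z if zz == 1 else 1 - p_z) * p_a
    return CellProbabilities(p)


def oracle_bridge_binary(config: BinaryDGPConfig) -> BridgeModel:
    """True bridge q(a, z) from the generator, as a saturated-binary model.

    Satisfies E[q(a, Z) | A=a, U=u] · P(A=a | U=u) = 1 exactly for both u.
    """
    cells = _binary_cells(config)
    q0 = closed_form_binary_bridge(cells, 0)
    q1 = closed_form_binary_bridge(cells, 1)
    tau = np.array([q0[0], q0[1] - q0[0], q1[0] - q0[0],
                    q1[1] - q1[0] - q0[1] + q0[0]])
    return BridgeModel(family="saturated-binary", tau=tau)


def bridge_table(model: BridgeModel) -> np.ndarray:
    """Evaluate a saturated-binary bridge on the four (a, z) cells;
    returns q[a, z]."""
    a = np.array([0, 0, 1, 1], dtype=float)
    z = np.array([0, 1, 0, 1], dtype=float)
    return model(a, z).reshape(2, 2)


def oracle_bridge_continuous(config: ContinuousDGPConfig) -> BridgeModel:
    """Analytic logistic-form bridge for the continuous world.

    With logistic treatment and Gaussian NCE, matching exponential moments
    of Z against 1/P(A=a | U, X) via the normal moment generating function
    gives

        τ2 = μUA/μUZ,
        τ3 = μXA − μXZ μUA/μUZ,
        τ0 = μ0A − μUA μ0Z/μUZ − σZ² μUA² / (2 μUZ²),
        τ1 = σZ² μUA²/μUZ² − μUA μAZ/μUZ.
    """
    if config.mu_uz == 0.0:
        raise ValueError("no bridge exists when mu_uz = 0 (NCE carries no "
                         "information about the confounder)")
    r = config.mu_ua / config.mu_uz
    s2 = config.sigma_z ** 2
    tau0 = config.mu_0a - r * config.mu_0z - s2 * r ** 2 / 2.0
    tau1 = s2 * r ** 2 - r * config.mu_az
    tau2 = r
    tau3 = config.mu_xa - config.mu_xz * r
    return BridgeModel(family="logistic-form",
                       tau=np.array([tau0, tau1, tau2, tau3]), n_x=1)


def true_inverse_propensity(pop: PopulationFrame, config=None) -> np.ndarray:
    """Exact Q(A, U, X) = 1 / P(A | U, X) per subject, using latent U.

    Only meaningful inside simulations (the infeasible IPTW oracle).
    """
    config = config if config is not None else pop.config
    df = pop.data
    if pop.setting == "binary":
        p1 = np.asarray(config.p_a_given_u)[df["u"].to_numpy()]
    else:
        lin = (config.mu_0a + config.mu_ua * df["u"].to_numpy()
               + config.mu_xa * df["x"].to_numpy())
        p1 = 1.0 / (1.0 + np.exp(-lin))
    p_obs = np.where(df["a"].to_numpy() == 1, p1, 1.0 - p1)
    return 1.0 / p_obs


# ---------------------------------------------------------------------------
# prevalence diagnostics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrevalenceReport:
    prevalence_unvaccinated: float
    prevalence_vaccinated: float
    #: empirical rare-outcome bound: max stratum-specific risk over coarse
    #: (A, W, U[, X]) strata
    delta_hat: float
    n_strata: int


def prevalence_report(pop: PopulationFrame, n_bins: int = 3) -> PrevalenceReport:
    """Infection prevalence by arm and an empirical rare-outcome bound δ̂.

    δ̂ is the maximum of P̂(Y=1 | stratum) over coarse strata of
    (A, W, U, X); continuous variables are cut into ``n_bins`` quantile
    bins.  A small δ̂ supports estimating the bridge from test-negative
    controls alone.
    """
    df = pop.data
    y, a = df["y"].to_numpy(), df["a"].to_numpy()
    p0 = float(y[a == 0].mean()) if (a == 0).any() else np.nan
    p1 = float(y[a == 1].mean()) if (a == 1).any() else np.nan

    def coarse(col):
        v = df[col]
        if v.nunique() <= n_bins:
            return v
        return pd.qcut(v, n_bins, labels=False, duplicates="drop")

    keys = [df["a"], coarse("w"), coarse("u")]
    if "x" in df.columns:
        keys.append(coarse("x"))
    grouped = df.groupby(keys, observed=True)["y"].mean()
    delta = float(grouped.max()) if len(grouped) else float("nan")
    if not np.any(y):
        delta = 0.0
    return PrevalenceReport(prevalence_unvaccinated=p0, prevalence_vaccinated=p1,
                            delta_hat=delta, n_strata=int(len(grouped)))
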