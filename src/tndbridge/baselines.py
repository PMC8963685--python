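"""Comparison estimators: oracle bridge, infeasible IPTW, and logistic
regression.

These serve as references in simulation studies.  The oracle variants use
information that is never available in a real TND analysis (the true
bridge function, or the latent confounder itself) and exist to separate
the error of *estimating* the bridge from the error of the weighting
identity it implements.  The logistic regression of test result on
vaccination (and covariates) among the tested is the conventional TND
analysis; it ignores the unmeasured confounder entirely.
"""

from __future__ import annotations

import numpy as np
import statsmodels.api as sm

from .bridge import BridgeModel, evaluate_bridge
from .inference import (EstimationResult, RR_NOTE, estimate_log_rr,
                        wald_ci_ve, _ve_terms)
from .sample import TNDSample
from .simulate import PopulationFrame, true_inverse_propensity

__all__ = ["nc_oracle_estimate", "iptw_oracle_estimate", "logistic_or_estimate"]


def _known_bridge_variance(sample: TNDSample, model: BridgeModel,
                           beta: float) -> float:
    """Sandwich variance of β̂ treating the bridge parameters as known:
    only the VE estimating function enters."""
    g1 = _ve_terms(sample, model, beta)
    q = evaluate_bridge(model, sample.a, sample.z, sample.x)
    jac = -np.mean(q * sample.a * sample.y * np.exp(-beta * sample.a))
    return float(np.var(g1) / (sample.n * jac ** 2))


def nc_oracle_estimate(sample: TNDSample, oracle_model: BridgeModel,
                       alpha: float = 0.05) -> EstimationResult:
    """Negative control estimator using the *true* bridge function.

    Identical to the closed-form log-RR estimator with q̂ replaced by the
    analytic oracle bridge; the sandwich variance treats τ as known.
    """
    beta = estimate_log_rr(sample, oracle_model)
    var = _known_bridge_variance(sample, oracle_model, beta)
    se = float(np.sqrt(var))
    return EstimationResult(
        beta_hat=beta, tau_hat=oracle_model.tau, cov=np.array([[var]]),
        se=se, ve=float(1 - np.exp(beta)), ve_ci=wald_ci_ve(beta, se, alpha),
        alpha=alpha, n=sample.n, scale_note=RR_NOTE, estimator="NC-Oracle")


def iptw_oracle_estimate(pop: PopulationFrame, config=None) -> float:
    """Infeasible IPTW log risk ratio over the selected sample.

    Uses the exact inverse treatment probabilities Q(A, U, X) computed
    from the latent confounder:
    β̂ = log[Σ Q A Y / Σ Q (1−A) Y] over S = 1 rows.  Invariant to
    positive rescaling of Q.
    """
    q_all = true_inverse_propensity(pop, config)
    sel = pop.data["s"].to_numpy() == 1
    a = pop.data["a"].to_numpy()[sel].astype(float)
    y = pop.data["y"].to_numpy()[sel].astype(float)
    q = q_all[sel]
    num = float(np.sum(q * a * y))
    den = float(np.sum(q * (1 - a) * y))
    if num <= 0:
        raise ValueError("no vaccinated cases in the selected sample")
    if den <= 0:
        raise ValueError("no unvaccinated cases in the selected sample")
    return float(np.log(num / den))


def logistic_or_estimate(sample: TNDSample, covariates=None,
                         alpha: float = 0.05) -> EstimationResult:
    """Conventional TND analysis: logistic regression of Y on A (and
    covariates) among the tested; the A coefficient is a log odds ratio.

    ``covariates`` selects columns of X (all by default).  VE is reported
    as 1 − OR for comparability — valid only absent unmeasured confounding
    and for a rare outcome.
    """
    x = sample.x if covariates is None else sample.x[:, list(covariates)]
    design = np.column_stack([np.ones(sample.n), sample.a, x])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("design matrix is singular (collinear covariates)")
    fit = sm.GLM(sample.y, design, family=sm.families.Binomial()).fit()
    if not np.all(np.isfinite(fit.bse)):
        raise ValueError("logistic fit failed (possible separation)")
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    return EstimationResult(
        beta_hat=beta, tau_hat=None, cov=np.array([[se ** 2]]), se=se,
        ve=float(1 - np.exp(beta)), ve_ci=wald_ci_ve(beta, se, alpha),
        alpha=alpha, n=sample.n,
        scale_note="OR (model-based logistic regression)",
        estimator="Logistic")
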