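"""Vaccine effectiveness estimation and sandwich inference.

Given a fitted treatment confounding bridge ``q̂``, the log causal risk
ratio has the closed form

    β̂ = log[ Σ_i q̂(A_i, Z_i, X_i) A_i Y_i / Σ_i q̂(A_i, Z_i, X_i) (1 − A_i) Y_i ],

and vaccine effectiveness is ``VE = 1 − exp(β̂)``.  Joint inference for
``(β̂, τ̂)`` stacks the VE estimating function on top of the bridge moment
functions and applies the standard M-estimation sandwich

    Σ̂_n = (Ω̂ᵀΩ̂)⁻¹ Ω̂ᵀ Var̂(G_i) Ω̂ (Ω̂ᵀΩ̂)⁻¹ / n,

with ``G_i`` the stacked per-subject estimating functions and ``Ω̂`` the
Jacobian of their empirical mean.  A Wald interval for VE is obtained by
transforming the endpoints of the β interval through ``1 − exp(·)``
(order-swapped, because the transform is decreasing).

The estimator targets the risk-ratio scale under a rare outcome and
treatment-independent sampling; under treatment-induced selection the same
computation is interpreted on the odds-ratio scale (the ``scale_note``
field records which reading is intended — the arithmetic is identical).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .bridge import (BridgeModel, MomentSpec, ConvergenceReport,
                     continuous_moment_basis, default_moment_basis,
                     estimate_bridge_params, evaluate_bridge,
                     _residual_terms, _numeric_jacobian)
from .sample import TNDSample

__all__ = [
    "EstimationResult",
    "InfluenceSet",
    "estimate_log_rr",
    "stacked_moments",
    "sandwich_covariance",
    "wald_ci_ve",
    "estimate_ve",
    "estimate_log_rr_modified",
]

RR_NOTE = "RR (rare outcome, treatment-independent sampling)"
OR_NOTE = "OR (treatment-induced selection reading)"


@dataclass
class EstimationResult:
    """Point estimate, joint covariance and VE interval."""

    beta_hat: float | np.ndarray
    tau_hat: np.ndarray | None
    cov: np.ndarray
    se: float
    ve: float
    ve_ci: tuple[float, float]
    alpha: float
    n: int
    scale_note: str = RR_NOTE
    estimator: str = "NC"
    convergence: ConvergenceReport | None = None

    @property
    def beta_ci(self) -> tuple[float, float]:
        zq = stats.norm.ppf(1 - self.alpha / 2)
        b = float(np.atleast_1d(self.beta_hat)[0])
        return (b - zq * self.se, b + zq * self.se)

    def to_dict(self) -> dict:
        beta = self.beta_hat
        d = {
            "schema_version": 1,
            "estimator": self.estimator,
            "beta_hat": beta if np.isscalar(beta) else np.asarray(beta).tolist(),
            "se": self.se,
            "beta_ci": list(self.beta_ci),
            "ve": self.ve,
            "ve_ci": list(self.ve_ci),
            "alpha": self.alpha,
            "n": self.n,
            "scale_note": self.scale_note,
            "tau_hat": None if self.tau_hat is None else np.asarray(self.tau_hat).tolist(),
            "cov": np.asarray(self.cov).tolist(),
        }
        if self.convergence is not None:
            d["convergence"] = asdict(self.convergence)
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


@dataclass
class InfluenceSet:
    """Per-subject stacked estimating-function values and their Jacobian."""

    g: np.ndarray       # (n, 1 + d_m)
    omega: np.ndarray   # (1 + d_m, 1 + dim tau)


def _ve_terms(sample: TNDSample, model: BridgeModel, beta: float) -> np.ndarray:
    """Per-subject VE estimating function (−1)^{1−A} q Y exp(−βA).

    Controls (Y = 0) contribute exactly zero."""
    q = evaluate_bridge(model, sample.a, sample.z, sample.x)
    sign = np.where(sample.a == 1, 1.0, -1.0)
    return sign * q * sample.y * np.exp(-beta * sample.a)


def estimate_log_rr(sample: TNDSample, model: BridgeModel) -> float:
    """Closed-form log risk-ratio estimate given a fitted bridge.

    Invariant to rescaling of q̂ by any positive constant (ratio form).
    Raises when either treatment arm has no bridge-weighted cases, naming
    the missing arm.
    """
    q = evaluate_bridge(model, sample.a, sample.z, sample.x)
    num = float(np.sum(q * sample.a * sample.y))
    den = float(np.sum(q * (1 - sample.a) * sample.y))
    if num <= 0 and den <= 0:
        raise ValueError("no cases in either treatment arm; log RR undefined")
    if num <= 0:
        raise ValueError("no vaccinated cases (A=1, Y=1); log RR undefined")
    if den <= 0:
        raise ValueError("no unvaccinated cases (A=0, Y=1); log RR undefined")
    return float(np.log(num / den))


def stacked_moments(sample: TNDSample, model: BridgeModel, m: MomentSpec,
                    beta: float, tau) -> InfluenceSet:
    """Stacked per-subject estimating functions G_i(β, τ) and Jacobian Ω.

    Row ``i`` of G is ``[(−1)^{1−A_i} q(·; τ) Y_i exp(−β A_i);
    (1 − Y_i)(m q − m(W,1,X) − m(W,0,X))]``.  Ω holds the derivatives of
    the mean of G with respect to ``(β, τ)``, by central differences.
    """
    tau = np.asarray(tau, dtype=float)

    def g_mat(theta):
        mdl = model.with_tau(theta[1:])
        return np.column_stack([
            _ve_terms(sample, mdl, theta[0]),
            _residual_terms(sample, mdl, m, theta[1:]),
        ])

    theta = np.concatenate([[beta], tau])
    g = g_mat(theta)
    omega = _numeric_jacobian(lambda th: g_mat(th).mean(axis=0), theta)
    return InfluenceSet(g=g, omega=omega)


def sandwich_covariance(infl: InfluenceSet) -> np.ndarray:
    """M-estimation sandwich Σ̂_n = (ΩᵀΩ)⁻¹ Ωᵀ Var̂(G) Ω (ΩᵀΩ)⁻¹ / n.

    Raises when Ω is column-rank deficient, naming the deficient direction.
    Output is symmetrised; diagonal entries are nonnegative up to numerics.
    """
    omega, g = infl.omega, infl.g
    n = g.shape[0]
    otg = omega.T @ omega
    rank = np.linalg.matrix_rank(otg)
    if rank < omega.shape[1]:
        # name the deficient direction via the null eigenvector
        eigval, eigvec = np.linalg.eigh(otg)
        direction = eigvec[:, 0]
        raise np.linalg.LinAlgError(
            "Jacobian is rank deficient (rank "
            f"{rank} < {omega.shape[1]}); unidentified parameter direction "
            f"{np.array2string(direction, precision=3)}")
    bread = np.linalg.solve(otg, omega.T)
    meat = np.cov(g, rowvar=False, bias=True)
    cov = bread @ np.atleast_2d(meat) @ bread.T / n
    return (cov + cov.T) / 2.0


def wald_ci_ve(beta_hat: float, se: float, alpha: float = 0.05
               ) -> tuple[float, float]:
    """Wald interval for VE = 1 − exp(β), by transforming the β-interval
    endpoints; the lower VE bound comes from the upper β bound."""
    if se < 0:
        raise ValueError("standard error must be nonnegative")
    zq = stats.norm.ppf(1 - alpha / 2)
    return (float(1 - np.exp(beta_hat + zq * se)),
            float(1 - np.exp(beta_hat - zq * se)))


def estimate_ve(sample: TNDSample, family: str = "saturated-binary",
                m: MomentSpec | None = None, *, alpha: float = 0.05,
                n_x_in_bridge: int | None = None,
                scale_note: str = RR_NOTE) -> EstimationResult:
    """End-to-end negative control VE estimation.

    1. fit the bridge parameters τ̂ on the test-negative controls;
    2. plug q̂ = q(·; τ̂) into the closed-form log-RR estimator;
    3. joint sandwich covariance for (β̂, τ̂), Wald interval for VE.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_x_in_bridge is None:
        n_x_in_bridge = sample.x.shape[1] if family == "logistic-form" else 0
    model = BridgeModel(family=family, n_x=n_x_in_bridge)
    if m is None:
        if family == "saturated-binary":
            m = default_moment_basis(sample.w.shape[1], 0)
        elif sample.w.shape[1] == 1:
            m = continuous_moment_basis(sample.x.shape[1])
        else:
            m = default_moment_basis(sample.w.shape[1], sample.x.shape[1])
    fitted, report = estimate_bridge_params(sample, model, m)
    beta = estimate_log_rr(sample, fitted)
    infl = stacked_moments(sample, fitted, m, beta, fitted.tau)
    cov = sandwich_covariance(infl)
    se = float(np.sqrt(cov[0, 0]))
    return EstimationResult(
        beta_hat=beta, tau_hat=fitted.tau, cov=cov, se=se,
        ve=float(1 - np.exp(beta)), ve_ci=wald_ci_ve(beta, se, alpha),
        alpha=alpha, n=sample.n, scale_note=scale_note,
        estimator="NC", convergence=report)


# ---------------------------------------------------------------------------
# effect modification by measured covariates: β0(X) = d(X)ᵀ b
# ---------------------------------------------------------------------------

def _design(sample: TNDSample, design) -> np.ndarray:
    if design is None:
        return np.column_stack([np.ones(sample.n), sample.x])
    d = np.asarray(design(sample.x), dtype=float)
    if d.ndim == 1:
        d = d[:, None]
    return d


def estimate_log_rr_modified(sample: TNDSample, model: BridgeModel,
                             design=None, m: MomentSpec | None = None, *,
                             alpha: float = 0.05, tol: float = 1e-10,
                             max_iter: int = 100) -> EstimationResult:
    """Log risk ratio varying with covariates: β0(x) = d(x)ᵀ b.

    Solves ``(1/n) Σ_i (−1)^{1−A_i} q̂_i d(X_i) Y_i exp(−d(X_i)ᵀ b A_i) = 0``
    by Newton iteration with analytic Jacobian (only vaccinated cases carry
    b-dependence).  ``design`` maps the covariate matrix to the basis
    ``d(X)``; the default is ``(1, Xᵀ)ᵀ``.  With ``d(X) = (1)`` this reduces
    exactly to :func:`estimate_log_rr`.

    Inference uses the same stacked sandwich with the β block widened to
    ``dim(d)``.
    """
    d = _design(sample, design)
    k = d.shape[1]
    q = evaluate_bridge(model, sample.a, sample.z, sample.x)
    sign = np.where(sample.a == 1, 1.0, -1.0)
    y, a = sample.y.astype(float), sample.a.astype(float)
    if not np.any((a == 1) & (y == 1)) or not np.any((a == 0) & (y == 1)):
        raise ValueError("cases are needed in both treatment arms")

    b = np.zeros(k)
    for it in range(max_iter):
        eta = d @ b
        wgt = sign * q * y * np.exp(-eta * a)
        g = d.T @ wgt / sample.n
        if np.max(np.abs(g)) <= tol:
            break
        vac = (a == 1) & (y == 1)
        jw = (q * y * np.exp(-eta))[vac]
        jac = -(d[vac].T * jw) @ d[vac] / sample.n
        try:
            step = np.linalg.solve(jac, -g)
        except np.linalg.LinAlgError as e:
            raise np.linalg.LinAlgError(
                "singular Jacobian in effect-modification Newton solve") from e
        b = b + step
    else:
        raise RuntimeError(
            f"effect-modification solver did not converge in {max_iter} "
            f"iterations (residual {np.max(np.abs(g)):.3e})")

    if m is None or model.tau is None:
        cov = np.full((k, k), np.nan)
        se = float("nan")
    else:
        cov = _modified_sandwich(sample, model, m, d, b)
        se = float(np.sqrt(cov[0, 0]))
    b0 = float(b[0])
    ve_ci = wald_ci_ve(b0, se, alpha) if np.isfinite(se) else (np.nan, np.nan)
    return EstimationResult(
        beta_hat=b, tau_hat=model.tau, cov=cov, se=se,
        ve=float(1 - np.exp(b0)), ve_ci=ve_ci, alpha=alpha, n=sample.n,
        estimator="NC (effect modification)")


def _modified_sandwich(sample, model, m, d, b) -> np.ndarray:
    """Stacked sandwich for (b, τ); returns the b block."""
    k = d.shape[1]
    tau = model.tau

    def g_mat(theta):
        bb, tt = theta[:k], theta[k:]
        mdl = model.with_tau(tt)
        q = evaluate_bridge(mdl, sample.a, sample.z, sample.x)
        sign = np.where(sample.a == 1, 1.0, -1.0)
        wgt = sign * q * sample.y * np.exp(-(d @ bb) * sample.a)
        return np.column_stack([d * wgt[:, None],
                                _residual_terms(sample, mdl, m, tt)])

    theta = np.concatenate([b, tau])
    g = g_mat(theta)
    omega = _numeric_jacobian(lambda th: g_mat(th).mean(axis=0), theta)
    cov = sandwich_covariance(InfluenceSet(g=g, omega=omega))
    return cov[:k, :k]
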