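"""Treatment confounding bridge functions and their estimation.

A treatment confounding bridge function ``q(A, Z, X)`` is a function of the
treatment, a negative control exposure (NCE) and measured covariates whose
conditional expectation given ``(A, U, X)`` equals the inverse treatment
probability ``1 / P(A | U, X)``, even though the confounder ``U`` is never
observed.  Under a rare-outcome condition the bridge can be estimated from
the test-negative controls alone, by solving moment equations built from a
negative control outcome (NCO) ``W``:

    (1/n) Σ_i (1 − Y_i) [ m(W_i, A_i, X_i) q(A_i, Z_i, X_i; τ)
                          − m(W_i, 1, X_i) − m(W_i, 0, X_i) ] = 0,

where ``m`` is a user-chosen vector function with ``dim(m) ≥ dim(τ)``.
Test-positive cases contribute exactly zero to these equations.

Two parametric families are provided:

* ``saturated-binary`` — ``q = τ0 + τ1 Z + τ2 A + τ3 Z A`` for binary
  scalar ``Z`` (a saturated model on the four treatment/NCE cells);
* ``logistic-form`` — ``q = 1 + exp[(−1)^A (τ0 + τ1 A + τ2 Z + τ3ᵀ X)]``,
  the closed-form family arising when ``A`` is logistic and ``Z`` Gaussian
  in a continuous confounder.

For binary ``Z`` and conditioning variable the bridge also has a closed
form as the solution of a 2×2 linear system in the cell probabilities
``P(Z = z, A = a | ·)``; see :func:`closed_form_binary_bridge`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

from .sample import TNDSample

__all__ = [
    "BridgeModel",
    "MomentSpec",
    "CellProbabilities",
    "ConvergenceReport",
    "IdentificationError",
    "BridgeEstimationError",
    "evaluate_bridge",
    "closed_form_binary_bridge",
    "moment_residuals",
    "estimate_bridge_params",
    "binary_moment_basis",
    "continuous_moment_basis",
    "default_moment_basis",
]

FAMILIES = ("saturated-binary", "logistic-form")

#: default condition-number threshold for the 2x2 closed form
COND_THRESHOLD = 1e8


class IdentificationError(ValueError):
    """The bridge function is not identified from the supplied information
    (e.g. the NCE carries no information about the conditioning variable)."""


class BridgeEstimationError(RuntimeError):
    """The moment-equation solver failed to converge."""

    def __init__(self, msg: str, residual_norm: float = np.nan):
        super().__init__(msg)
        self.residual_norm = residual_norm


@dataclass
class BridgeModel:
    """A parametric treatment confounding bridge family with parameters τ.

    ``n_x`` is the covariate dimension entering the bridge (0 for the
    saturated binary family).  For ``logistic-form`` the parameter vector is
    ``(τ0, τ1, τ2, τ3[0], …, τ3[n_x−1])``.
    """

    family: str
    tau: np.ndarray | None = None
    n_x: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown bridge family {self.family!r}")
        if self.tau is not None:
            self.tau = np.asarray(self.tau, dtype=float).ravel()
            if self.tau.shape[0] != self.n_params:
                raise ValueError(
                    f"{self.family} with n_x={self.n_x} needs "
                    f"{self.n_params} parameters, got {self.tau.shape[0]}")

    @property
    def n_params(self) -> int:
        return 4 if self.family == "saturated-binary" else 4 + max(self.n_x - 1, 0)

    def with_tau(self, tau) -> "BridgeModel":
        return replace(self, tau=np.asarray(tau, dtype=float))

    def __call__(self, a, z, x=None) -> np.ndarray:
        return evaluate_bridge(self, a, z, x)


def evaluate_bridge(model: BridgeModel, a, z, x=None) -> np.ndarray:
    """Evaluate ``q(a, z, x; τ)`` elementwise.

    ``a`` is binary; ``z`` is the (scalar) NCE value; ``x`` a covariate row
    or matrix (ignored by the saturated binary family).
    """
    if model.tau is None:
        raise ValueError("bridge parameters are not set")
    a = np.asarray(a, dtype=float)
    z = np.asarray(z, dtype=float)
    if z.ndim == 2:
        if z.shape[1] != 1:
            raise ValueError("parametric bridge families take a scalar NCE")
        z = z[:, 0]
    t = model.tau
    if model.family == "saturated-binary":
        return t[0] + t[1] * z + t[2] * a + t[3] * z * a
    # logistic-form
    lin = t[0] + t[1] * a + t[2] * z
    n_x = model.n_x
    if n_x:
        if x is None:
            raise ValueError("logistic-form bridge with covariates needs x")
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[:, None] if x.shape[0] == np.size(a) and n_x == 1 else x[None, :]
        if x.shape[1] != n_x:
            raise ValueError(f"x has width {x.shape[1]}, bridge expects {n_x}")
        lin = lin + x @ t[3:3 + n_x]
    # clip keeps intermediate solver iterates finite; exp(500) is already
    # far beyond any plausible inverse probability
    return 1.0 + np.exp(np.clip((-1.0) ** a * lin, -500.0, 500.0))


@dataclass(frozen=True)
class MomentSpec:
    """A user-specified moment function ``m(W, A, X)`` of dimension ``dim``.

    ``func(w, a, x) -> (n, dim)`` must be evaluable at both treatment
    levels ``a ∈ {0, 1}`` for every observed ``(w, x)``, because the
    estimating equations evaluate ``m`` at A=1 and A=0 counterfactually.
    """

    func: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]
    dim: int
    name: str = "custom"

    def __call__(self, w, a, x) -> np.ndarray:
        out = np.asarray(self.func(w, a, x), dtype=float)
        if out.ndim != 2 or out.shape[1] != self.dim:
            raise ValueError(
                f"moment function returned shape {out.shape}, expected (n, {self.dim})")
        return out


def binary_moment_basis() -> MomentSpec:
    """``m(W, A) = (1, W, A, WA)ᵀ`` — the canonical basis for a binary NCO
    paired with the saturated binary bridge (just-identified)."""

    def f(w, a, x):
        w0 = np.asarray(w, dtype=float)
        if w0.ndim == 2:
            w0 = w0[:, 0]
        a = np.broadcast_to(np.asarray(a, dtype=float), w0.shape)
        one = np.ones_like(w0)
        return np.column_stack([one, w0, a, w0 * a])

    return MomentSpec(f, 4, name="(1,W,A,WA)")


def continuous_moment_basis(n_x: int = 1) -> MomentSpec:
    """``m(W, A, X) = (1, W, A, Xᵀ)ᵀ`` — the canonical basis for a scalar
    continuous NCO with covariates (just-identified for logistic-form)."""

    def f(w, a, x):
        w0 = np.asarray(w, dtype=float)
        if w0.ndim == 2:
            w0 = w0[:, 0]
        a = np.broadcast_to(np.asarray(a, dtype=float), w0.shape)
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        if x.shape[1] != n_x:
            raise ValueError(f"x has width {x.shape[1]}, basis expects {n_x}")
        return np.column_stack([np.ones_like(w0), w0, a, x])

    return MomentSpec(f, 3 + n_x, name="(1,W,A,X)")


def default_moment_basis(n_w: int, n_x: int) -> MomentSpec:
    """General basis for vector W/X: all NCO components, treatment, their
    treatment interactions and covariates: ``(1, W, A, W·A, X)``."""
    if n_w == 1 and n_x == 0:
        return binary_moment_basis()

    def f(w, a, x):
        w = np.asarray(w, dtype=float)
        if w.ndim == 1:
            w = w[:, None]
        a = np.broadcast_to(np.asarray(a, dtype=float), w[:, 0].shape)
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        cols = [np.ones_like(a)] + [w[:, j] for j in range(n_w)] + [a]
        cols += [w[:, j] * a for j in range(n_w)]
        cols += [x[:, j] for j in range(n_x)]
        return np.column_stack(cols)

    return MomentSpec(f, 2 + 2 * n_w + n_x, name="(1,W,A,WA,X)")


@dataclass(frozen=True)
class CellProbabilities:
    """Conditional joint cell probabilities ``p[z, a | c]`` for binary
    ``Z``, ``A`` and a binary conditioning variable ``c`` (the confounder
    ``U`` in the oracle version, the NCO ``W`` in the observed-control
    version).

    ``p[z, a, c]`` is a (2, 2, 2) array; for each ``c`` the entries are
    nonnegative and sum to one over ``(z, a)``.
    """

    p: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        if p.shape != (2, 2, 2):
            raise ValueError("cell probabilities must have shape (2, 2, 2)")
        if np.any(p < -1e-12):
            raise ValueError("cell probabilities must be nonnegative")
        sums = p.sum(axis=(0, 1))
        if not np.allclose(sums, 1.0, atol=1e-8):
            raise ValueError("cell probabilities must sum to 1 over (z, a) "
                             f"for each conditioning level; got sums {sums}")
        object.__setattr__(self, "p", p)

    @classmethod
    def from_controls(cls, sample: TNDSample) -> "CellProbabilities":
        """Empirical ``p'[z, a | w] = P(Z=z, A=a | W=w, Y=0, S=1)`` from the
        test-negative controls of a binary-world sample."""
        ctl = sample.controls()
        z = ctl.z[:, 0].astype(int)
        w = ctl.w[:, 0].astype(int)
        a = ctl.a.astype(int)
        if not (np.isin(z, (0, 1)).all() and np.isin(w, (0, 1)).all()):
            raise ValueError("binary cell probabilities need binary Z and W")
        p = np.zeros((2, 2, 2))
        for c in (0, 1):
            mask = w == c
            n_c = int(mask.sum())
            if n_c == 0:
                raise IdentificationError(
                    f"no test-negative controls with W={c}; cell "
                    "probabilities cannot be estimated")
            for zz in (0, 1):
                for aa in (0, 1):
                    p[zz, aa, c] = np.sum(mask & (z == zz) & (a == aa)) / n_c
        return cls(p)


def closed_form_binary_bridge(p: CellProbabilities, a: int,
                              cond_threshold: float = COND_THRESHOLD
                              ) -> tuple[float, float]:
    """Closed-form bridge values ``(q(a, 0), q(a, 1))`` for binary Z.

    Solves, for the given treatment level ``a``, the linear system

        p[0,a|c] q(a,0) + p[1,a|c] q(a,1) = 1   for c = 0, 1.

    Raises :class:`IdentificationError` when the 2×2 matrix is singular or
    ill-conditioned — which happens exactly when Z carries no information
    about the conditioning variable.
    """
    a = int(a)
    if a not in (0, 1):
        raise ValueError("a must be 0 or 1")
    mat = np.array([[p.p[0, a, 0], p.p[1, a, 0]],
                    [p.p[0, a, 1], p.p[1, a, 1]]])
    cond = np.linalg.cond(mat)
    if not np.isfinite(cond) or cond > cond_threshold:
        raise IdentificationError(
            f"cell-probability matrix for treatment level a={a} is singular "
            f"or ill-conditioned (cond={cond:.3g}); the NCE is uninformative "
            "about the conditioning variable at this treatment level")
    q = np.linalg.solve(mat, np.ones(2))
    return float(q[0]), float(q[1])


def moment_residuals(sample: TNDSample, model: BridgeModel, m: MomentSpec,
                     tau) -> np.ndarray:
    """Mean estimating-function value ``g(τ)`` over the whole sample.

    Returns ``(1/n) Σ_i (1 − Y_i)[ m(W_i, A_i, X_i) q(A_i, Z_i, X_i; τ)
    − m(W_i, 1, X_i) − m(W_i, 0, X_i) ]``; rows with ``Y_i = 1`` contribute
    exactly zero (they are multiplied by ``1 − Y_i = 0`` and never touch
    the bridge evaluation).
    """
    if sample.n_controls == 0:
        raise ValueError("sample contains no test-negative controls (Y=0)")
    return _residual_terms(sample, model, m, tau).mean(axis=0)


def _residual_terms(sample: TNDSample, model: BridgeModel, m: MomentSpec,
                    tau) -> np.ndarray:
    """Per-subject (n, d_m) terms of the bridge estimating function."""
    model = model.with_tau(tau)
    ctl = sample.y == 0
    q = evaluate_bridge(model, sample.a[ctl], sample.z[ctl], sample.x[ctl])
    m_obs = m(sample.w[ctl], sample.a[ctl], sample.x[ctl])
    m1 = m(sample.w[ctl], np.ones(ctl.sum()), sample.x[ctl])
    m0 = m(sample.w[ctl], np.zeros(ctl.sum()), sample.x[ctl])
    terms = np.zeros((sample.n, m.dim))
    terms[ctl] = m_obs * q[:, None] - m1 - m0
    return terms


@dataclass
class ConvergenceReport:
    converged: bool
    iterations: int
    residual_norm: float
    method: str
    min_q: float = np.nan
    frac_q_below_1: float = np.nan
    #: inverse-probability validity: True when every fitted q̂ ≥ 1
    valid_inverse_probability: bool = True
    multistart_used: bool = False


def _numeric_jacobian(fun, tau: np.ndarray, rel_step: float = 1e-6) -> np.ndarray:
    """Central-difference Jacobian with step 1e-6·(1+|τ_j|) per coordinate."""
    tau = np.asarray(tau, dtype=float)
    d = tau.size
    f0 = np.asarray(fun(tau))
    jac = np.empty((f0.size, d))
    for j in range(d):
        h = rel_step * (1.0 + abs(tau[j]))
        tp, tm = tau.copy(), tau.copy()
        tp[j] += h
        tm[j] -= h
        jac[:, j] = (np.asarray(fun(tp)) - np.asarray(fun(tm))) / (2 * h)
    return jac


def _initial_tau(model: BridgeModel, sample: TNDSample | None = None
                 ) -> np.ndarray:
    if model.family == "saturated-binary":
        t = np.zeros(model.n_params)
        t[0] = 1.0  # q ≡ 1, the no-confounding bridge
        return t
    tau = np.zeros(model.n_params)  # q ≡ 2 everywhere
    if sample is None:
        return tau
    # observed-propensity start: a logistic fit of A on (Z, X) among the
    # controls gives 1/P(A=a|Z,X) = 1 + exp((-1)^a (c0 + cZ Z + cX X)),
    # i.e. the bridge that would be exact if Z were itself the confounder
    try:
        ctl = sample.controls()
        design = np.column_stack([np.ones(ctl.n), ctl.z[:, 0],
                                  ctl.x[:, :model.n_x]])
        import statsmodels.api as sm
        coef = sm.GLM(ctl.a, design,
                      family=sm.families.Binomial()).fit().params
        tau[0], tau[2] = coef[0], coef[1]
        tau[3:3 + model.n_x] = coef[2:2 + model.n_x]
    except Exception:  # fall back to the symmetric null start
        return np.zeros(model.n_params)
    return tau


def _newton_solve(fun, tau0: np.ndarray, tol: float, max_iter: int):
    """Damped Newton iteration on the moment residuals."""
    tau = tau0.astype(float).copy()
    g = np.asarray(fun(tau))
    norm = np.max(np.abs(g))
    for it in range(1, max_iter + 1):
        if norm <= tol:
            return tau, norm, it - 1, True
        jac = _numeric_jacobian(fun, tau)
        try:
            step = np.linalg.solve(jac, -g) if jac.shape[0] == jac.shape[1] \
                else np.linalg.lstsq(jac, -g, rcond=None)[0]
        except np.linalg.LinAlgError:
            return tau, norm, it, False
        lam = 1.0
        for _ in range(30):  # halving line search on the residual norm
            cand = tau + lam * step
            g_new = np.asarray(fun(cand))
            if np.all(np.isfinite(g_new)) and np.max(np.abs(g_new)) < norm:
                tau, g, norm = cand, g_new, np.max(np.abs(g_new))
                break
            lam *= 0.5
        else:
            return tau, norm, it, norm <= tol
    return tau, norm, max_iter, norm <= tol


def estimate_bridge_params(sample: TNDSample, model: BridgeModel,
                           m: MomentSpec | None = None, *,
                           tol: float = 1e-10, max_iter: int = 200,
                           n_multistart: int = 8,
                           ) -> tuple[BridgeModel, ConvergenceReport]:
    """Estimate the bridge parameters τ from the test-negative controls.

    When ``dim(m) == dim(τ)`` (just-identified) the moment equations are
    solved exactly by damped Newton iteration with a numerical Jacobian;
    when ``dim(m) > dim(τ)`` the squared Euclidean norm of the residual
    vector is minimised (identity-weighted GMM).  On failure the solver is
    restarted from 8 quasi-random perturbations of the initial point.

    Fitted bridge values below 1 are not errors — an inverse probability
    must be ≥ 1, so they are recorded on the convergence report as a
    validity warning.
    """
    if m is None:
        m = default_moment_basis(sample.w.shape[1], model.n_x)
    if m.dim < model.n_params:
        raise ValueError(
            f"moment dimension {m.dim} is smaller than the number of bridge "
            f"parameters {model.n_params}")
    if sample.n_controls == 0:
        raise ValueError("sample contains no test-negative controls (Y=0)")

    fun = lambda tau: moment_residuals(sample, model, m, tau)
    tau0 = _initial_tau(model, sample)
    just_identified = m.dim == model.n_params

    starts = [tau0]
    # deterministic quasi-random perturbations used only as fallbacks
    rng = np.random.default_rng(1234321)
    starts += [tau0 + rng.uniform(-1.0, 1.0, tau0.size) for _ in range(n_multistart)]

    best = None
    for k, start in enumerate(starts):
        if just_identified:
            tau, norm, its, ok = _newton_solve(fun, start, tol, max_iter)
        else:
            from scipy.optimize import least_squares
            res = least_squares(fun, start, xtol=1e-14, ftol=1e-14, gtol=1e-14,
                                max_nfev=200 * (tau0.size + 1))
            tau, its = res.x, res.nfev
            # polish: the GMM objective gradient must vanish, residual need not
            norm = np.max(np.abs(_numeric_jacobian(fun, tau).T @ fun(tau)))
            ok = norm <= max(tol, 1e-8)
        if best is None or norm < best[1]:
            best = (tau, norm, its, ok, k > 0)
        if ok:
            break
    tau, norm, its, ok, multistart = best
    if not ok:
        raise BridgeEstimationError(
            f"bridge moment equations did not converge after "
            f"{len(starts)} start(s); last residual max-norm {norm:.3e}",
            residual_norm=norm)

    fitted = model.with_tau(tau)
    ctl = sample.y == 0
    q = evaluate_bridge(fitted, sample.a[ctl], sample.z[ctl], sample.x[ctl])
    frac_below = float(np.mean(q < 1.0))
    report = ConvergenceReport(
        converged=True, iterations=its, residual_norm=float(norm),
        method="newton" if just_identified else "gmm-identity",
        min_q=float(q.min()), frac_q_below_1=frac_below,
        valid_inverse_probability=frac_below == 0.0,
        multistart_used=multistart)
    if frac_below > 0:
        import logging
        logging.getLogger(__name__).warning(
            "fitted bridge takes values < 1 (an inverse probability) for "
            "%.1f%% of controls (min %.4f)", 100 * frac_below, q.min())
    return fitted, report
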