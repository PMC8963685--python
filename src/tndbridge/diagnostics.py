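"""Negative-control bias detection and estimator comparison tests.

A valid NCE should be conditionally independent of the test result given
vaccination and covariates, and a valid NCO independent of the NCE; an
adjusted association between them signals residual (unmeasured)
confounding.  The Hausman test compares the negative-control estimate with
the conventional logistic estimate: a significant difference indicates
that the extra assumptions behind the logistic analysis (no unmeasured
confounding) are violated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .inference import EstimationResult
from .sample import TNDSample

__all__ = ["nce_bias_tests", "hausman_test", "HausmanResult"]


def _is_binary(v: np.ndarray) -> bool:
    return np.isin(v, (0.0, 1.0)).all()


def _fit_adjusted(outcome: np.ndarray, z: np.ndarray, adj: np.ndarray,
                  logistic: bool):
    design = np.column_stack([np.ones(len(outcome)), z, adj])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear design in negative-control regression")
    if logistic:
        fit = sm.GLM(outcome, design, family=sm.families.Binomial()).fit()
    else:
        fit = sm.OLS(outcome, design).fit()
    return fit


def nce_bias_tests(sample: TNDSample) -> pd.DataFrame:
    """Adjusted association tests between the NCE and (i) the test result,
    (ii) the NCO.

    Fits a logistic regression of Y on Z adjusting for (A, X), and a
    regression of each NCO component on Z adjusting for (A, X) — logistic
    when the NCO is binary, linear otherwise.  Returns one row per test and
    Z component with (estimate, se, p).  Small p-values flag residual
    confounding; under no unmeasured confounding the p-values are
    approximately uniform.
    """
    adj = np.column_stack([sample.a.astype(float), sample.x])
    rows = []
    nz = sample.z.shape[1]

    fit = _fit_adjusted(sample.y.astype(float), sample.z, adj, logistic=True)
    for j in range(nz):
        rows.append(("Y ~ Z | A, X", f"z{j + 1}" if nz > 1 else "z",
                     fit.params[1 + j], fit.bse[1 + j], fit.pvalues[1 + j]))

    for k in range(sample.w.shape[1]):
        w = sample.w[:, k]
        fit = _fit_adjusted(w, sample.z, adj, logistic=_is_binary(w))
        wname = f"w{k + 1}" if sample.w.shape[1] > 1 else "w"
        for j in range(nz):
            rows.append((f"{wname} ~ Z | A, X",
                         f"z{j + 1}" if nz > 1 else "z",
                         fit.params[1 + j], fit.bse[1 + j], fit.pvalues[1 + j]))

    return pd.DataFrame(rows, columns=["test", "term", "estimate", "se", "p"])


@dataclass(frozen=True)
class HausmanResult:
    statistic: float
    p_value: float
    df: int = 1

    @property
    def is_degenerate(self) -> bool:
        return not np.isfinite(self.statistic)


def hausman_test(result_nc: EstimationResult,
                 result_logit: EstimationResult) -> HausmanResult:
    """Hausman comparison of two estimators of the same log-scale contrast.

    ``T = (β̂₁ − β̂₂)² / (V₁ − V₂)`` referred to χ²(1), where estimator 1
    (negative control) is consistent under weaker assumptions and assumed
    less efficient.  When the variance difference is not positive the
    statistic is undefined and NaN is returned with a warning.
    """
    b1 = float(np.atleast_1d(result_nc.beta_hat)[0])
    b2 = float(np.atleast_1d(result_logit.beta_hat)[0])
    v1, v2 = result_nc.se ** 2, result_logit.se ** 2
    dv = v1 - v2
    if dv <= 0:
        warnings.warn("Hausman variance difference is not positive; "
                      "statistic undefined", stacklevel=2)
        return HausmanResult(float("nan"), float("nan"))
    t = (b1 - b2) ** 2 / dv
    return HausmanResult(float(t), float(stats.chi2.sf(t, df=1)))
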