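"""Functional-response shape classification from proportional consumption.

The shape of a functional response (type II vs type III) is read off a
polynomial logistic regression of the proportion of prey killed against
initial prey density, fitted to predator-present trials only: a negative,
significant first-order term indicates a type II (hyperbolic) response,
while a positive significant first-order term together with a negative
significant second-order term indicates a type III (sigmoidal) response.

The decision sequence fits the quadratic model first; if its first-order
term is positive and significant the type III condition on the quadratic
term is checked, otherwise the linear model decides the type II call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .trials import PredationTrial

__all__ = ["GLMCoefficients", "ResponseTypeFit", "fit_binomial_glm", "classify_response"]


@dataclass
class GLMCoefficients:
    """Coefficient table from a logit-link binomial polynomial regression."""

    names: list[str]
    estimates: np.ndarray
    std_errors: np.ndarray
    z_values: np.ndarray
    p_values: np.ndarray
    deviance: float
    converged: bool

    def term(self, name: str) -> tuple[float, float, float]:
        """(estimate, SE, p) for the named term."""
        i = self.names.index(name)
        return float(self.estimates[i]), float(self.std_errors[i]), float(self.p_values[i])


@dataclass
class ResponseTypeFit:
    classification: str  # "type_II", "type_III" or "inconclusive"
    coefficients: GLMCoefficients
    degree_used: int
    alpha: float
    n_trials: int
    converged: bool


def fit_binomial_glm(
    eaten: Sequence[int], initial: Sequence[int], degree: int = 2
) -> GLMCoefficients:
    """Binomial GLM of (eaten, alive) on density and optionally density^2.

    Logit link, fitted by iteratively reweighted least squares.  Requires
    at least ``degree + 2`` distinct density levels.  Non-convergence or
    non-finite standard errors (e.g. complete separation) are flagged on
    the result rather than raised.
    """
    eaten = np.asarray(eaten, dtype=float)
    initial = np.asarray(initial, dtype=float)
    if eaten.shape != initial.shape:
        raise ValueError("eaten and initial must have equal length")
    if np.any(eaten < 0) or np.any(eaten > initial):
        raise ValueError("need 0 <= eaten <= initial for every trial")
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    if np.unique(initial).size < degree + 2:
        raise ValueError(
            f"need at least {degree + 2} distinct density levels for degree {degree}"
        )
    names = ["intercept", "density"] + (["density2"] if degree == 2 else [])
    cols = [np.ones_like(initial), initial] + ([initial**2] if degree == 2 else [])
    exog = np.column_stack(cols)
    endog = np.column_stack([eaten, initial - eaten])
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.GLM(endog, exog, family=sm.families.Binomial())
            res = model.fit(maxiter=100, tol=1e-10)
            converged = bool(res.converged)
        except Exception:
            res = None
            converged = False
    if res is None:
        nan = np.full(len(names), np.nan)
        return GLMCoefficients(names, nan, nan, nan, nan, np.nan, False)
    se = np.asarray(res.bse)
    # a logit-scale coefficient beyond +-20 means fitted probabilities pinned
    # at 0/1 (separation or an empty response); flag rather than trust SEs
    if not np.all(np.isfinite(se)) or np.any(np.abs(res.params) > 20):
        converged = False
    return GLMCoefficients(
        names=names,
        estimates=np.asarray(res.params),
        std_errors=se,
        z_values=np.asarray(res.tvalues),
        p_values=np.asarray(res.pvalues),
        deviance=float(res.deviance),
        converged=converged,
    )


def classify_response(
    trials: Sequence[PredationTrial], alpha: float = 0.05
) -> ResponseTypeFit:
    """Classify one species x temperature group as type II or type III.

    Only predator-present, non-excluded trials enter the regression.
    ``type_II``: negative, significant first-order density term (from the
    linear fit when the quadratic fit does not already show a significant
    positive first-order term).  ``type_III``: positive significant
    first-order and negative significant second-order terms in the
    quadratic fit.  Anything else, including non-convergence, is
    ``inconclusive``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    use = [t for t in trials if t.predator_count >= 1 and not t.excluded]
    if not use:
        raise ValueError("no predator-present trials to classify")
    eaten = np.array([t.eaten for t in use], dtype=float)
    initial = np.array([t.initial_count for t in use], dtype=float)

    # the quadratic needs 4 distinct densities; otherwise only the linear
    # (type II) call is available
    if np.unique(initial).size >= 4:
        quad = fit_binomial_glm(eaten, initial, degree=2)
        if quad.converged:
            b1, _, p1 = quad.term("density")
            if b1 > 0 and p1 < alpha:
                b2, _, p2 = quad.term("density2")
                cls = "type_III" if (b2 < 0 and p2 < alpha) else "inconclusive"
                return ResponseTypeFit(cls, quad, 2, alpha, len(use), True)

    lin = fit_binomial_glm(eaten, initial, degree=1)
    if not lin.converged:
        return ResponseTypeFit("inconclusive", lin, 1, alpha, len(use), False)
    b1, _, p1 = lin.term("density")
    cls = "type_II" if (b1 < 0 and p1 < alpha) else "inconclusive"
    return ResponseTypeFit(cls, lin, 1, alpha, len(use), True)
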