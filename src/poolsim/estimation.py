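"""Maximum-likelihood logistic regression with offsets and stability rules.

The fitter is a plain Newton-Raphson / IRLS implementation written here so
that the iteration cap, the convergence criterion, and the behaviour under
separation are under explicit control: those details feed directly into the
study's accounting of "unstable" replicates.  A replicate model is *stable*
when it converged within the iteration cap and both exposure odds ratios lie
strictly between 0.1 and 10; separated fits are returned non-converged with
the last iterate's (possibly huge) coefficients retained, because extreme
odds ratios count toward the power and false-positive numerators.

The model is ``logit P(y=1) = c0 + c1*x1 + c2*x2 + c3*z + c4*ga + offset``
with the offset fixed (not estimated).  Standard errors are Wald, from the
inverse observed information at the optimum.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .errors import ParameterError, RankDeficiencyError

_MU_EPS = 1e-12


@dataclass
class FitResult:
    """One fitted logistic model (intercept + four covariate terms)."""

    coef: np.ndarray  # c0..c4
    se: np.ndarray    # se0..se4
    p1: float
    p2: float
    or1: float
    or2: float
    converged: bool
    n_iter: int
    stable: bool = field(default=False)
    loglik: float = np.nan

    @property
    def c1(self) -> float:
        return float(self.coef[1])

    @property
    def c2(self) -> float:
        return float(self.coef[2])


def classify_stability(fit: FitResult) -> bool:
    """Stable iff converged and both exposure ORs strictly inside (0.1, 10)."""
    return bool(
        fit.converged
        and np.isfinite(fit.or1) and np.isfinite(fit.or2)
        and 0.1 < fit.or1 < 10.0
        and 0.1 < fit.or2 < 10.0
    )


def _loglik(y, eta):
    mu = np.clip(expit(eta), _MU_EPS, 1.0 - _MU_EPS)
    return float(np.sum(y * np.log(mu) + (1.0 - y) * np.log(1.0 - mu)))


def fit_logistic(
    design: np.ndarray,
    outcome: np.ndarray,
    offset: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-8,
    criterion: str = "loglik",
) -> FitResult:
    """Fit the five-parameter logistic model by Newton-Raphson.

    Parameters
    ----------
    design:
        (n, 4) covariate matrix; an intercept column is prepended internally.
    outcome:
        Binary response vector of length n.
    offset:
        Fixed addition to the linear predictor (all-zero for individual-level
        fits without design offsets).
    max_iter, tol, criterion:
        Iteration cap and convergence rule.  ``"loglik"`` (default) declares
        convergence when the relative log-likelihood change drops below
        ``tol``; ``"gradient"`` when the score norm drops below ``tol``.
        After the criterion is met one extra Newton step is taken so the
        score equations are satisfied to near machine precision.

    Raises
    ------
    RankDeficiencyError
        If the design (with intercept) is not of full column rank.
    """
    X = np.asarray(design, dtype=float)
    if X.ndim != 2:
        raise ParameterError("design must be 2-dimensional")
    n, k = X.shape
    if n < k + 2:
        raise ParameterError(f"need at least {k + 2} rows, got {n}")
    y = np.asarray(outcome, dtype=float)
    if y.shape != (n,):
        raise ParameterError("outcome length does not match design rows")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ParameterError("outcome must be binary 0/1")
    off = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)
    if off.shape != (n,):
        raise ParameterError("offset length does not match design rows")
    if criterion not in ("loglik", "gradient"):
        raise ParameterError(f"unknown convergence criterion {criterion!r}")

    Xf = np.column_stack([np.ones(n), X])
    p = k + 1
    if np.linalg.matrix_rank(Xf) < p:
        raise RankDeficiencyError("design matrix is rank deficient")

    beta = np.zeros(p)
    ll_old = -np.inf
    converged = False
    n_iter = 0
    polish = False
    for it in range(1, max_iter + 1):
        n_iter = it
        eta = Xf @ beta + off
        mu = expit(eta)
        resid = y - mu
        grad = Xf.T @ resid
        ll = _loglik(y, eta)

        # perfect separation: every observation fitted (numerically) exactly,
        # which only happens when the classes are separable
        if np.all(np.abs(resid) < 1e-9):
            converged = False
            break

        if polish:
            converged = True
            break
        if criterion == "loglik":
            met = np.abs(ll - ll_old) <= tol * (np.abs(ll) + tol)
        else:
            met = np.linalg.norm(grad) <= tol
        ll_old = ll

        w = mu * (1.0 - mu)
        XtWX = Xf.T @ (Xf * w[:, None])
        try:
            delta = np.linalg.solve(XtWX, grad)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(XtWX, grad, rcond=None)[0]
        if not np.all(np.isfinite(delta)):
            converged = False
            break
        beta = beta + delta
        if met:
            # criterion met: take this one extra Newton step, then stop
            polish = True

    eta = Xf @ beta + off
    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), _MU_EPS, None)
    XtWX = Xf.T @ (Xf * w[:, None])
    try:
        cov = np.linalg.inv(XtWX)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.inf)

    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        zvals = beta / se
        pvals = 2.0 * norm.sf(np.abs(zvals))
        or1 = float(np.exp(beta[1]))
        or2 = float(np.exp(beta[2]))

    fit = FitResult(
        coef=beta,
        se=se,
        p1=float(pvals[1]),
        p2=float(pvals[2]),
        or1=or1,
        or2=or2,
        converged=converged,
        n_iter=n_iter,
        loglik=_loglik(y, eta),
    )
    fit.stable = classify_stability(fit)
    return fit


def fit_population_truth(
    viable_pop: pd.DataFrame,
    covariates: tuple[str, str, str, str] = ("x1", "x2", "z", "x_ga"),
    **kwargs,
) -> FitResult:
    """Individual-level logistic fit on the full viable population.

    Uses the *true* covariate values and no offset; its exposure odds ratios
    are the denominators of the replicate bias summaries.
    """
    X = np.column_stack([viable_pop[c].to_numpy(dtype=float) for c in covariates])
    y = viable_pop["y_case"].to_numpy(dtype=float)
    return fit_logistic(X, y, offset=None, **kwargs)
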