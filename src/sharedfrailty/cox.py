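"""Cox proportional hazards with delayed entry (left truncation).

Each at-risk interval ``(start, stop]`` contributes to the risk set of an
event at time ``t`` exactly when ``start < t <= stop``; with age as the
basic timescale this means a subject is at risk only from her age at surgery
(or at her previous failure) onward, never from birth.  The partial
likelihood, its analytic gradient and Hessian are computed for the Breslow
and Efron tie conventions, maximized by Newton-Raphson, and summarized as
relative risks with log-symmetric 95% Wald intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .event_history import Cohort, EventType

__all__ = [
    "CoxFit",
    "ConvergenceError",
    "SeparationError",
    "partial_loglik",
    "fit_cox",
    "wald_rr",
    "backward_eliminate",
]


class ConvergenceError(RuntimeError):
    """Newton-Raphson failed to reach the convergence tolerances."""


class SeparationError(ConvergenceError):
    """Monotone partial likelihood (complete separation): no finite maximizer."""


@dataclass(frozen=True)
class CoxFit:
    """A converged Cox partial-likelihood fit."""

    beta: np.ndarray
    covariance: np.ndarray
    loglik: float
    n_events: int
    ties_method: str
    names: tuple[str, ...]
    loglik_null: float
    n_iter: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, b, s in zip(self.names, self.beta, self.se):
            rr, lo, hi, p = wald_rr(b, s)
            rows.append(
                {"term": name, "coef": b, "se": s, "RR": rr, "lower": lo, "upper": hi, "p": p}
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# data preparation


def _prepare(
    cohort: Cohort,
    covariates: Sequence[str],
    event_filter: EventType | str | None,
    ranks: Sequence[int] | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[str]]:
    frame = cohort.intervals_frame()
    X, names = cohort.design_matrix(covariates)
    start = frame["entry"].to_numpy(float)
    stop = frame["exit"].to_numpy(float)
    event = frame["status"].to_numpy(int).copy()
    if event_filter is not None:
        target = EventType(event_filter).value
        event = ((frame["event_type"] == target) & (frame["status"] == 1)).to_numpy(int)
    if ranks is not None:
        keep = frame["rank"].isin(list(ranks)).to_numpy()
        start, stop, event, X = start[keep], stop[keep], event[keep], X[keep]
    return start, stop, event, X, names


def _loglik_grad_hess(
    start: np.ndarray,
    stop: np.ndarray,
    event: np.ndarray,
    X: np.ndarray,
    beta: np.ndarray,
    ties: str,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Partial log-likelihood with exact analytic gradient and Hessian."""
    if ties not in ("breslow", "efron"):
        raise ValueError(f"unknown ties method {ties!r}")
    if event.sum() == 0:
        raise ValueError("no events in cohort")
    p = X.shape[1]
    eta = X @ beta
    # guard against overflow in pathological (separated) iterations
    r = np.exp(np.clip(eta, -500, 500))
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for t in np.unique(stop[event == 1]):
        at_risk = (start < t) & (t <= stop)
        died = (stop == t) & (event == 1)
        d = int(died.sum())
        rR = r[at_risk]
        XR = X[at_risk]
        S0 = rR.sum()
        S1 = rR @ XR
        S2 = XR.T @ (rR[:, None] * XR)
        ll += float(eta[died].sum())
        grad += X[died].sum(axis=0)
        if ties == "breslow" or d == 1:
            ll -= d * np.log(S0)
            grad -= d * S1 / S0
            hess -= d * (S2 / S0 - np.outer(S1, S1) / S0**2)
        else:  # efron
            rD = r[died]
            XD = X[died]
            s0d = rD.sum()
            s1d = rD @ XD
            s2d = XD.T @ (rD[:, None] * XD)
            for l in range(d):
                f = l / d
                den = S0 - f * s0d
                num = S1 - f * s1d
                ll -= np.log(den)
                grad -= num / den
                hess -= (S2 - f * s2d) / den - np.outer(num, num) / den**2
    return ll, grad, hess


def partial_loglik(
    cohort: Cohort,
    beta: Sequence[float],
    covariates: Sequence[str],
    ties: str = "efron",
    event_filter: EventType | str | None = None,
    ranks: Sequence[int] | None = None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Cox partial log-likelihood, gradient and Hessian at ``beta``.

    The risk set at an event time ``t`` contains exactly the at-risk
    intervals with ``start < t <= stop`` (delayed entry).
    """
    start, stop, event, X, _ = _prepare(cohort, covariates, event_filter, ranks)
    return _loglik_grad_hess(start, stop, event, X, np.asarray(beta, float), ties)


def fit_cox(
    cohort: Cohort,
    covariates: Sequence[str],
    event_filter: EventType | str | None = None,
    ties: str = "efron",
    ranks: Sequence[int] | None = None,
    max_iter: int = 60,
    tol_loglik: float = 1e-9,
    tol_score: float = 1e-6,
) -> CoxFit:
    """Maximize the Cox partial likelihood by Newton-Raphson.

    ``event_filter`` restricts failures to one event type (all other
    outcomes censor the interval); ``ranks=(1,)`` restricts to first at-risk
    periods, the per-event analysis for the time to first failure.
    Convergence requires a relative log-likelihood change below
    ``tol_loglik`` and a score norm below ``tol_score``.
    """
    start, stop, event, X, names = _prepare(cohort, covariates, event_filter, ranks)
    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, hess = _loglik_grad_hess(start, stop, event, X, beta, ties)
    ll_null = ll
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if p == 0:
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as e:
            raise SeparationError(
                "singular information matrix (possible complete separation / "
                "collinear covariates)"
            ) from e
        # step-halving to guarantee ascent
        alpha = 1.0
        for _ in range(30):
            cand = beta + alpha * step
            ll_new, grad_new, hess_new = _loglik_grad_hess(start, stop, event, X, cand, ties)
            if ll_new >= ll - 1e-12 * (1.0 + abs(ll)):
                break
            alpha /= 2
        else:
            if np.linalg.norm(grad) < tol_score:
                break  # already at the optimum; the step is numerical noise
            raise ConvergenceError("step-halving failed to find an ascent step")
        beta, ll_prev, ll, grad, hess = cand, ll, ll_new, grad_new, hess_new
        if np.max(np.abs(beta)) > 25:
            raise SeparationError(
                "coefficient diverging (|beta| > 25): monotone partial likelihood, "
                "complete separation"
            )
        if abs(ll - ll_prev) < tol_loglik * (abs(ll_prev) + 1.0) and (
            np.linalg.norm(grad) < tol_score
        ):
            break
    else:
        raise ConvergenceError(
            f"no convergence after {max_iter} iterations (score norm "
            f"{np.linalg.norm(grad):.3g})"
        )
    if p > 0:
        if np.max(np.abs(beta)) > 10:
            raise SeparationError(
                "implausibly large coefficient at convergence: monotone partial "
                "likelihood (complete separation)"
            )
        cov = np.linalg.inv(-hess)
    else:
        cov = np.empty((0, 0))
    return CoxFit(
        beta=beta,
        covariance=cov,
        loglik=float(ll),
        n_events=int(event.sum()),
        ties_method=ties,
        names=tuple(names),
        loglik_null=float(ll_null),
        n_iter=n_iter,
    )


def wald_rr(beta_j: float, se_j: float) -> tuple[float, float, float, float]:
    """Relative risk with log-symmetric 95% Wald CI and two-sided p-value.

    RR = exp(beta), CI = exp(beta +/- 1.96 se); the printed bounds satisfy
    lower * upper = RR**2 up to rounding.
    """
    if se_j < 0:
        raise ValueError("standard error must be >= 0")
    rr = float(np.exp(beta_j))
    lo = float(np.exp(beta_j - 1.96 * se_j))
    hi = float(np.exp(beta_j + 1.96 * se_j))
    if se_j == 0:
        p = 1.0 if beta_j == 0 else 0.0
    else:
        p = float(2 * stats.norm.sf(abs(beta_j) / se_j))
    return rr, lo, hi, p


def _block_wald_p(fit: CoxFit, columns: Sequence[str]) -> float:
    """Wald chi-square p-value for a block of coefficients being jointly zero."""
    idx = [fit.names.index(c) for c in columns]
    b = fit.beta[idx]
    V = fit.covariance[np.ix_(idx, idx)]
    chi2 = float(b @ np.linalg.solve(V, b))
    return float(stats.chi2.sf(chi2, df=len(idx)))


def backward_eliminate(
    cohort: Cohort,
    start_covariates: Sequence[str],
    alpha: float = 0.05,
    **fit_kwargs,
) -> list[str]:
    """Descending stepwise selection on Wald tests.

    Repeatedly drops the covariate *block* (a categorical covariate's dummy
    columns are kept or dropped together) with the largest Wald p-value above
    ``alpha``, refitting after each drop, until every retained block has
    p <= alpha.
    """
    retained = list(start_covariates)
    while retained:
        fit = fit_cox(cohort, retained, **fit_kwargs)
        blocks = cohort.column_blocks(retained)
        pvals = {name: _block_wald_p(fit, cols) for name, cols in blocks.items()}
        worst = max(pvals, key=pvals.get)
        if pvals[worst] > alpha:
            retained.remove(worst)
        else:
            break
    return retained
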