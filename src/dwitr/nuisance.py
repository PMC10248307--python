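"""Nuisance models: treatment propensity and visit-intensity, with weights.

Two weights enter the doubly weighted estimating equation:

* the inverse probability of treatment (IPT) weight
  ``w(t) = 1 / P(A(t) = a_observed | K(t))`` from a logistic propensity
  model, which balances confounders across treatment arms; and
* the inverse intensity of visit (IIV) weight
  ``rho(t) = exp(-gamma' V(t))`` from an Andersen–Gill proportional rate
  model ``E[dN(t) | V(t)] = xi(t) exp(gamma' V(t)) dLambda0(t)``, which
  removes covariate-driven selection of the observation times.  With time
  measured since cohort entry the baseline rate ``dLambda0`` is common to
  all patients at each event time, cancels from the weight ratio, and is
  never estimated.

The proportional-rate coefficients maximise the Breslow partial likelihood

    l(gamma) = sum_t [ sum_{i: dN_i(t)=1} gamma' V_i(t)
                       - d_t * log( sum_{j in risk set at t} exp(gamma' V_j(t)) ) ]

which on grid data (ties at every event time) is evaluated by grouped sums
over the grid and maximised by Newton's method with step halving.  This
exploits the grid structure directly and scales linearly in person-time
rows, which matters for the n = 50,000 sensitivity-analysis cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import FitError, InvalidArgumentError, PositivityError
from .panel import LongitudinalPanel
from .specs import ModelSpec


def _as_frame(panel) -> pd.DataFrame:
    return panel.data if isinstance(panel, LongitudinalPanel) else panel


# --------------------------------------------------------------------------- #
# Propensity (treatment) model
# --------------------------------------------------------------------------- #
@dataclass
class PropensityFit:
    """Fitted logistic propensity model.

    ``kappa_hat`` is ordered as the spec's design columns (intercept first
    when present).  ``fitted_prob`` are the in-sample P(A=1 | K) values; all
    must lie strictly inside (0, 1).
    """

    spec: ModelSpec
    kappa_hat: np.ndarray
    fitted_prob: np.ndarray
    n_rows_used: int

    def predict_prob(self, df: pd.DataFrame) -> np.ndarray:
        X = self.spec.design_matrix(df)
        from scipy.special import expit

        return expit(X @ self.kappa_hat)


def fit_propensity(panel, spec: ModelSpec, rows: str = "all") -> PropensityFit:
    """Maximum-likelihood logistic regression of A(t) on the spec's terms.

    Parameters
    ----------
    panel : LongitudinalPanel or DataFrame
    spec : ModelSpec
        Confounder terms (response "A"); intercept handled by the spec.
    rows : {"all", "analysis"}
        Fit on all at-risk person-time (default — the treatment is observed
        continuously, and on the full process the estimate recovers the
        treatment-assignment coefficients) or on observation-time rows only
        (the rows the estimating equation touches).

    Raises
    ------
    FitError
        On a constant treatment column (separation), rank deficiency, or
        non-convergence.
    """
    df = _as_frame(panel)
    if rows == "analysis":
        df = df[df["obs"] >= 1]
    elif rows == "all":
        df = df[df["at_risk"] == 1]
    else:
        raise InvalidArgumentError("rows must be 'analysis' or 'all'")
    if len(df) == 0:
        raise FitError("no rows available to fit the propensity model")

    y = df["A"].to_numpy(dtype=float)
    X = spec.design_matrix(df)
    if y.min() == y.max():
        raise FitError("treatment A is constant in the fitting rows: separation")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise FitError(
            f"propensity design is rank deficient (rank {rank} < {X.shape[1]}): "
            f"terms {spec.column_names}"
        )
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=100)
    except Exception as exc:  # statsmodels raises several convergence errors
        raise FitError(
            f"propensity fit failed for terms {spec.column_names}: {exc}"
        ) from exc
    if not res.mle_retvals.get("converged", True):
        raise FitError(
            f"propensity fit did not converge for terms {spec.column_names}"
        )
    prob = np.asarray(res.predict(X))
    if np.any(prob <= 0.0) or np.any(prob >= 1.0):
        raise PositivityError(
            "fitted treatment probabilities reached 0 or 1 "
            f"(terms {spec.column_names})"
        )
    return PropensityFit(spec, np.asarray(res.params), prob, len(df))


def ipt_weights(fit: PropensityFit, panel) -> np.ndarray:
    """Inverse probability of treatment weights, one per row of ``panel``.

    ``w = 1 / P(A = 1 | K)`` for treated rows, ``1 / P(A = 0 | K)`` for
    untreated rows.
    """
    df = _as_frame(panel)
    p1 = fit.predict_prob(df)
    if np.any(p1 <= 0.0) or np.any(p1 >= 1.0):
        raise PositivityError("treatment probability at 0 or 1 in weight rows")
    a = df["A"].to_numpy()
    p_obs = np.where(a == 1, p1, 1.0 - p1)
    return 1.0 / p_obs


# --------------------------------------------------------------------------- #
# Proportional rate (observation) model
# --------------------------------------------------------------------------- #
@dataclass
class RateFit:
    """Fitted Andersen–Gill proportional-rate coefficients.

    No intercept / baseline rate is estimated: on the time-since-entry axis
    the baseline cancels from the partial likelihood and from the IIV weight.
    """

    spec: ModelSpec
    gamma_hat: np.ndarray
    n_iter: int
    grad_norm: float
    loglik: float


def _breslow_parts(df: pd.DataFrame, spec: ModelSpec):
    """Extract (X, dN, time codes) for at-risk person-time rows."""
    df = df[df["at_risk"] == 1]
    X = spec.design_matrix(df)
    dN = df["obs"].to_numpy(dtype=float)  # counts allowed (bootstrap multiplicity)
    codes, _ = pd.factorize(df["time"].to_numpy(), sort=True)
    return X, dN, codes


def breslow_loglik(gamma, X, dN, codes):
    """Breslow log partial likelihood, gradient and Hessian on grid data."""
    gamma = np.asarray(gamma, dtype=float)
    n_times = codes.max() + 1
    eta = X @ gamma
    w = np.exp(eta)
    p = X.shape[1]

    S0 = np.bincount(codes, weights=w, minlength=n_times)
    d = np.bincount(codes, weights=dN, minlength=n_times)
    event_mask = d > 0
    ll = float(dN @ eta - d[event_mask] @ np.log(S0[event_mask]))

    S1 = np.empty((n_times, p))
    for k in range(p):
        S1[:, k] = np.bincount(codes, weights=w * X[:, k], minlength=n_times)
    Ebar = np.zeros_like(S1)
    Ebar[event_mask] = S1[event_mask] / S0[event_mask, None]
    grad = X.T @ dN - Ebar.T @ d

    hess = np.zeros((p, p))
    for k in range(p):
        for l in range(k, p):
            S2kl = np.bincount(codes, weights=w * X[:, k] * X[:, l], minlength=n_times)
            v = np.zeros(n_times)
            v[event_mask] = S2kl[event_mask] / S0[event_mask]
            hkl = -float(d @ (v - Ebar[:, k] * Ebar[:, l]))
            hess[k, l] = hkl
            hess[l, k] = hkl
    return ll, grad, hess


def fit_proportional_rate(
    panel, spec: ModelSpec, tol: float = 1e-9, max_iter: int = 50
) -> RateFit:
    """Fit gamma by Newton's method on the Breslow partial likelihood.

    The panel must be in counting-process form (per-grid-interval rows with
    ``at_risk``, ``obs`` and the time-varying covariates); all at-risk
    person-time enters the risk sets, visit rows contribute the events.

    Raises
    ------
    FitError
        If there are no events, or Newton fails to drive the score to zero
        within ``max_iter`` iterations (the final gradient norm is reported).
    """
    if spec.intercept:
        raise InvalidArgumentError(
            "the proportional rate model has no intercept (baseline rate cancels)"
        )
    df = _as_frame(panel)
    X, dN, codes = _breslow_parts(df, spec)
    if dN.sum() == 0:
        raise FitError("no observation events: cannot fit the rate model")
    p = X.shape[1]
    gamma = np.zeros(p)
    scale = max(1.0, float(dN.sum()))
    ll, grad, hess = breslow_loglik(gamma, X, dN, codes)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        gnorm = float(np.linalg.norm(grad))
        if gnorm < tol * scale:
            break
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError as exc:
            raise FitError(f"singular information matrix in rate model: {exc}") from exc
        # step halving to guarantee ascent
        alpha = 1.0
        for _ in range(30):
            cand = gamma + alpha * step
            ll_new, grad_new, hess_new = breslow_loglik(cand, X, dN, codes)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12 * abs(ll):
                break
            alpha *= 0.5
        else:
            raise FitError("rate-model step halving failed to find ascent")
        gamma, ll, grad, hess = cand, ll_new, grad_new, hess_new
    gnorm = float(np.linalg.norm(grad))
    if gnorm >= tol * scale:
        raise FitError(
            f"rate model did not converge in {max_iter} iterations "
            f"(gradient norm {gnorm:.3e})"
        )
    return RateFit(spec, gamma, n_iter, gnorm, ll)


def iiv_weights(fit: RateFit, panel) -> np.ndarray:
    """Inverse intensity of visit weights ``rho = exp(-gamma' V)`` per row.

    Defined only on at-risk rows (``xi(t) = 1``); requesting a weight for a
    row outside the risk set is an error.
    """
    df = _as_frame(panel)
    if (df["at_risk"] == 0).any():
        raise InvalidArgumentError(
            "IIV weight undefined for rows with at_risk = 0"
        )
    V = fit.spec.design_matrix(df)
    return np.exp(-(V @ fit.gamma_hat))
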