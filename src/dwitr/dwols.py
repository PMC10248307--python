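"""Doubly weighted least squares core: design assembly, solve, rule, utility.

The outcome mean model is

    E[Y(t) | A(t), X(t)] = beta' X_beta(t) + A(t) * psi' X_psi(t)

with X_beta the treatment-free block (intercept, confounders, tailoring
variables) and psi' X_psi(t) the blip — the modelled gain from treatment 1
over treatment 0 given the tailoring variables.  For a linear treatment-free
model the doubly weighted estimating equation is exactly a weighted least
squares problem on the stacked design [X_beta | A * X_psi] over the rows
where the outcome was observed, with per-row weight
``w(t) * rho(t)`` (IPT times IIV).  The solve is the closed-form WLS
solution via a rank-revealing least-squares decomposition; no iteration.

The treatment rule is sign(blip): treat with A = 1 iff psi' X_psi >= 0,
boundary ties going to treatment 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import (
    FitError,
    InvalidArgumentError,
    UnderDeterminedError,
)
from .panel import LongitudinalPanel
from .specs import OutcomeSpec


@dataclass
class DesignMatrices:
    """Stacked dWOLS design over analysis rows (obs = 1, Y present)."""

    X_beta: np.ndarray
    X_psi: np.ndarray  # already gated by A: rows with A=0 are zero
    y: np.ndarray
    rows: pd.DataFrame
    spec: OutcomeSpec

    @property
    def X(self) -> np.ndarray:
        return np.hstack([self.X_beta, self.X_psi])


def assemble_design(panel, spec: OutcomeSpec) -> DesignMatrices:
    """Build [X_beta | A * X_psi] and y over observed-outcome rows.

    Columns shared between the treatment-free and blip parts appear once in
    each block (the stacked design may contain duplicated covariates —
    they are distinguished by the treatment gating).

    Raises
    ------
    FitError
        If the panel contains no analysis rows.
    UnderDeterminedError
        If there are fewer rows than free parameters.
    """
    if isinstance(panel, LongitudinalPanel):
        rows = panel.analysis_rows()
    else:
        rows = panel[(panel["obs"] >= 1) & panel["Y"].notna()]
    if len(rows) == 0:
        raise FitError("panel has no analysis rows (no observed outcomes)")
    p = spec.n_beta + spec.n_psi
    if len(rows) < p:
        raise UnderDeterminedError(
            f"{len(rows)} analysis rows < {p} parameters"
        )
    X_beta = spec.treatment_free.design_matrix(rows)
    X_psi_raw = spec.blip.design_matrix(rows)
    A = rows["A"].to_numpy(dtype=float)
    X_psi = X_psi_raw * A[:, None]
    y = rows["Y"].to_numpy(dtype=float)
    return DesignMatrices(X_beta, X_psi, y, rows, spec)


@dataclass
class ITRFit:
    """Solution of the doubly weighted estimating equation.

    ``estimating_eq_norm`` is || X' W (y - X theta) || at the solution — the
    residual of the estimating equation, which the closed-form WLS solve
    drives to numerical zero.
    """

    spec: OutcomeSpec
    beta_hat: np.ndarray
    psi_hat: np.ndarray
    weights: np.ndarray
    n_rows: int
    estimating_eq_norm: float

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([self.beta_hat, self.psi_hat])

    @property
    def param_names(self) -> list[str]:
        return self.spec.param_names


def fit_dwols(design: DesignMatrices, weights=None) -> ITRFit:
    """Solve the weighted normal equations for (beta, psi).

    Parameters
    ----------
    design : DesignMatrices
    weights : array-like or None
        Per-row combined weights (IPT x IIV); None means unit weights, in
        which case the result is exactly ordinary least squares.

    Raises
    ------
    FitError
        On rank deficiency (the collinear columns are named) or non-finite
        weights.
    """
    X = design.X
    y = design.y
    n, p = X.shape
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,):
            raise InvalidArgumentError(
                f"weights length {w.shape} does not match {n} analysis rows"
            )
        if not np.all(np.isfinite(w)) or np.any(w <= 0):
            raise InvalidArgumentError("weights must be finite and positive")
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    theta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    if rank < p:
        names = design.spec.param_names
        # name the columns involved in the deficiency via QR pivoting
        from scipy.linalg import qr

        _, R, piv = qr(Xw, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(Xw.shape) * np.finfo(float).eps if diag.size else 0.0
        dropped = [names[j] for j in piv[rank:]]
        raise FitError(
            f"design is rank deficient (rank {rank} < {p}); "
            f"collinear terms: {dropped}"
        )
    resid = y - X @ theta
    ee = X.T @ (w * resid)
    nb = design.spec.n_beta
    return ITRFit(
        spec=design.spec,
        beta_hat=theta[:nb],
        psi_hat=theta[nb:],
        weights=w,
        n_rows=n,
        estimating_eq_norm=float(np.linalg.norm(ee)),
    )


# --------------------------------------------------------------------------- #
def blip_value(psi_hat, tailoring_row) -> float:
    """psi' (1, tailoring covariates) for a single row.

    ``tailoring_row`` excludes the leading 1 — it holds only the tailoring
    covariates, in the blip spec's order.
    """
    psi = np.asarray(psi_hat, dtype=float)
    row = np.atleast_1d(np.asarray(tailoring_row, dtype=float))
    x = np.concatenate([[1.0], row])
    if x.shape != psi.shape:
        raise InvalidArgumentError(
            f"tailoring row length {row.shape[0]} does not match "
            f"{psi.shape[0] - 1} blip covariates"
        )
    return float(psi @ x)


def blip_values(psi_hat, spec: OutcomeSpec, df: pd.DataFrame) -> np.ndarray:
    """Vectorised blip over a covariate frame using the blip spec."""
    X = spec.blip.design_matrix(df)
    return X @ np.asarray(psi_hat, dtype=float)


def decide_treatment(blip) -> np.ndarray:
    """The estimated rule: treat with A = 1 iff the blip is >= 0.

    The boundary blip = 0 is assigned to treatment 1.  Accepts scalars or
    arrays; non-finite blips are an error.
    """
    b = np.asarray(blip, dtype=float)
    if not np.all(np.isfinite(b)):
        raise InvalidArgumentError("blip values must be finite")
    out = (b >= 0).astype(np.int64)
    return out if out.ndim else int(out)


def bmi_utility(bmi_t, bmi_0):
    """BMI-change utility, percent scale.

    U(t) = 100 - (|BMI(t) - 22| - |BMI(0) - 22|) / BMI(0) * 100.

    Peaks when BMI(t) is at 22 (mid normal range); 100 means no net change
    in distance from 22 relative to baseline.  Under percent BMI changes of
    at most 50% the utility lies in [50, 150].
    """
    bmi_t = np.asarray(bmi_t, dtype=float)
    bmi_0 = np.asarray(bmi_0, dtype=float)
    if np.any(bmi_0 <= 0):
        raise InvalidArgumentError("baseline BMI must be positive")
    u = 100.0 - (np.abs(bmi_t - 22.0) - np.abs(bmi_0 - 22.0)) / bmi_0 * 100.0
    return u if u.ndim else float(u)


def mask_implausible_bmi(series, low: float = 15.0, high: float = 50.0):
    """Set BMI values outside the plausibility window to missing."""
    s = pd.Series(np.asarray(series, dtype=float))
    return s.where((s >= low) & (s <= high))
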