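"""Symbolic model specifications and the six estimator presets.

A :class:`ModelSpec` is an ordered list of terms, each a panel column with an
optional transform (identity or square, written ``"K1"`` / ``"K1^2"``).  The
square transform exists to express the misspecified-treatment-model scenario
in the simulation study; richer formulas are deliberately out of scope.

The presets encode the six estimators compared in the simulation study:

========  =========================  ======================  ==================
name      observation model (IIV)    treatment model (IPT)   treatment-free
========  =========================  ======================  ==================
DW1       A, Z, K2, K3 (correct)     K1, K2, K3 (correct)    K1, K2, K3, Q
DW2       A, Z (partial)             K1, K2, K3              K1, K3, Q (no K2)
DW3       A, Z (partial)             K1^2, K2, K3^2          K1, K2, K3, Q
DW4       A, K2 (misspecified)       K1, K2, K3              K1, K2, K3, Q
OLS       none                       none                    K1, K2, K3, Q
IPT       none                       K1, K2, K3              K1, K2, K3, Q
IIV       A, Z, K2, K3               none                    K1, K2, K3, Q
========  =========================  ======================  ==================

The blip part is (1, Q, K1) in every preset (the blip model is always
correctly specified).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError, PanelSchemaError

_TRANSFORMS = ("identity", "square")


@dataclass(frozen=True)
class Term:
    column: str
    transform: str = "identity"

    def __post_init__(self) -> None:
        if self.transform not in _TRANSFORMS:
            raise InvalidArgumentError(
                f"transform must be one of {_TRANSFORMS}, got {self.transform!r}"
            )

    @property
    def name(self) -> str:
        return self.column if self.transform == "identity" else f"{self.column}^2"

    def evaluate(self, df: pd.DataFrame) -> np.ndarray:
        if self.column not in df.columns:
            raise PanelSchemaError(f"column {self.column!r} missing from panel")
        x = df[self.column].to_numpy(dtype=float)
        return x * x if self.transform == "square" else x


def parse_term(s: str) -> Term:
    """Parse "K1" or "K1^2" into a Term."""
    s = s.strip()
    if s.endswith("^2"):
        return Term(s[:-2], "square")
    return Term(s)


@dataclass(frozen=True)
class ModelSpec:
    """Ordered term list for one nuisance or outcome-model component.

    Parameters
    ----------
    terms : tuple of Term
        Covariate terms in design-matrix order.
    intercept : bool
        Whether a leading column of ones is included.
    response : str or None
        Response column, where the component has one (propensity: "A";
        observation model: "obs"; outcome: "Y").
    """

    terms: tuple = ()
    intercept: bool = False
    response: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "terms",
            tuple(parse_term(t) if isinstance(t, str) else t for t in self.terms),
        )

    @property
    def column_names(self) -> list[str]:
        names = ["1"] if self.intercept else []
        return names + [t.name for t in self.terms]

    @property
    def n_params(self) -> int:
        return len(self.terms) + (1 if self.intercept else 0)

    def design_matrix(self, df: pd.DataFrame) -> np.ndarray:
        cols = [t.evaluate(df) for t in self.terms]
        if self.intercept:
            cols = [np.ones(len(df))] + cols
        if not cols:
            return np.empty((len(df), 0))
        return np.column_stack(cols)


@dataclass(frozen=True)
class OutcomeSpec:
    """Treatment-free and blip components of the outcome mean model.

    The design is [X_beta | A * X_psi]; columns shared between the two parts
    appear once in each block (they are deliberately not deduplicated).  The
    blip part always carries an intercept.  The mediator Z must not appear in
    either part.
    """

    treatment_free: ModelSpec
    blip: ModelSpec

    def __post_init__(self) -> None:
        if not self.blip.intercept:
            raise InvalidArgumentError("blip model must include an intercept")
        for part, spec in (("treatment_free", self.treatment_free), ("blip", self.blip)):
            for t in spec.terms:
                if t.column == "Z":
                    raise InvalidArgumentError(
                        f"mediator Z may not enter the {part} model"
                    )

    @property
    def param_names(self) -> list[str]:
        beta = [f"tf:{n}" for n in self.treatment_free.column_names]
        psi = [f"blip:{n}" for n in self.blip.column_names]
        return beta + psi

    @property
    def n_beta(self) -> int:
        return self.treatment_free.n_params

    @property
    def n_psi(self) -> int:
        return self.blip.n_params


@dataclass(frozen=True)
class EstimatorConfig:
    """One estimator: outcome model plus which weights it carries."""

    name: str
    outcome: OutcomeSpec
    propensity: ModelSpec | None = None
    observation: ModelSpec | None = None


def _outcome(treatment_free_terms, blip_terms=("Q", "K1")) -> OutcomeSpec:
    return OutcomeSpec(
        treatment_free=ModelSpec(tuple(treatment_free_terms), intercept=True, response="Y"),
        blip=ModelSpec(tuple(blip_terms), intercept=True),
    )


_CORRECT_OUTCOME = _outcome(("K1", "K2", "K3", "Q"))
_NO_K2_OUTCOME = _outcome(("K1", "K3", "Q"))
_CORRECT_PS = ModelSpec(("K1", "K2", "K3"), intercept=True, response="A")
_SQUARED_PS = ModelSpec(("K1^2", "K2", "K3^2"), intercept=True, response="A")
_OBS_FULL = ModelSpec(("A", "Z", "K2", "K3"), intercept=False, response="obs")
_OBS_PARTIAL = ModelSpec(("A", "Z"), intercept=False, response="obs")
_OBS_WRONG = ModelSpec(("A", "K2"), intercept=False, response="obs")

ESTIMATOR_PRESETS = {
    "DW1": EstimatorConfig("DW1", _CORRECT_OUTCOME, _CORRECT_PS, _OBS_FULL),
    "DW2": EstimatorConfig("DW2", _NO_K2_OUTCOME, _CORRECT_PS, _OBS_PARTIAL),
    "DW3": EstimatorConfig("DW3", _CORRECT_OUTCOME, _SQUARED_PS, _OBS_PARTIAL),
    "DW4": EstimatorConfig("DW4", _CORRECT_OUTCOME, _CORRECT_PS, _OBS_WRONG),
    "OLS": EstimatorConfig("OLS", _CORRECT_OUTCOME, None, None),
    "IPT": EstimatorConfig("IPT", _CORRECT_OUTCOME, _CORRECT_PS, None),
    "IIV": EstimatorConfig("IIV", _CORRECT_OUTCOME, None, _OBS_FULL),
}


def get_estimator(name: str) -> EstimatorConfig:
    try:
        return ESTIMATOR_PRESETS[name]
    except KeyError:
        raise InvalidArgumentError(
            f"unknown estimator {name!r}; choose from {sorted(ESTIMATOR_PRESETS)}"
        ) from None
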