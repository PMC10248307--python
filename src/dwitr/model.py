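"""Model/Results interface for the doubly weighted ITR estimator.

:class:`DoublyWeightedITR` is constructed from a long-format panel plus an
outcome specification and optional nuisance-model specifications; ``fit()``
runs the full pipeline — Andersen–Gill visit model on all at-risk
person-time, logistic propensity model, inverse weights, then the closed-form
doubly weighted least squares on the observed-outcome rows — and returns an
:class:`ITRResults` carrying the coefficient estimates, the weights used, a
``summary()`` table, the fitted treatment rule, and cluster-bootstrap
confidence intervals.

Example
-------
>>> from dwitr import ScenarioConfig, simulate_cohort, DoublyWeightedITR
>>> panel = simulate_cohort(ScenarioConfig.preset("scenario1", 250, seed=3))
>>> res = DoublyWeightedITR.from_preset(panel, "DW1").fit()
>>> res.psi  # blip coefficients on (1, Q, K1)        # doctest: +SKIP
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dwols, nuisance
from .exceptions import InvalidArgumentError
from .panel import LongitudinalPanel
from .specs import (
    ESTIMATOR_PRESETS,
    EstimatorConfig,
    ModelSpec,
    OutcomeSpec,
    get_estimator,
)


class DoublyWeightedITR:
    """Doubly weighted ordinary least squares for a one-stage treatment rule.

    Parameters
    ----------
    panel : LongitudinalPanel or DataFrame
        Long-format person-time data (counting-process form).  The outcome
        model uses only the observed-outcome rows; the visit model uses all
        at-risk person-time.
    outcome : OutcomeSpec
        Treatment-free and blip term lists.
    propensity : ModelSpec or None
        Confounder terms of the treatment logit; None drops the IPT weight.
    observation : ModelSpec or None
        Terms of the proportional-rate visit model; None drops the IIV
        weight.  With both None the fit is plain OLS.
    propensity_rows : {"all", "analysis"}
        Person-time used to fit the propensity model (default: all at-risk
        person-time; "analysis" restricts to the observed-outcome rows).
    weight_truncation : float or None
        Optional upper percentile (e.g. 99) at which combined weights are
        truncated.  Off by default; raw weights match the methodology.
    """

    def __init__(
        self,
        panel,
        outcome: OutcomeSpec,
        propensity: ModelSpec | None = None,
        observation: ModelSpec | None = None,
        propensity_rows: str = "all",
        weight_truncation: float | None = None,
        name: str = "DW",
    ):
        self.panel = panel
        self.data = panel.data if isinstance(panel, LongitudinalPanel) else panel
        self.outcome = outcome
        self.propensity = propensity
        self.observation = observation
        self.propensity_rows = propensity_rows
        self.weight_truncation = weight_truncation
        self.name = name

    # ------------------------------------------------------------------ #
    @classmethod
    def from_preset(cls, panel, name: str, **kwargs) -> "DoublyWeightedITR":
        """Build from one of the named estimator presets (DW1..DW4, OLS, IPT, IIV)."""
        cfg = get_estimator(name)
        return cls.from_config(panel, cfg, **kwargs)

    @classmethod
    def from_config(cls, panel, cfg: EstimatorConfig, **kwargs) -> "DoublyWeightedITR":
        return cls(
            panel,
            outcome=cfg.outcome,
            propensity=cfg.propensity,
            observation=cfg.observation,
            name=cfg.name,
            **kwargs,
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        treatment_free,
        blip,
        propensity=None,
        observation=None,
        **kwargs,
    ) -> "DoublyWeightedITR":
        """Construct from a raw frame and plain term lists (strings, "^2" ok)."""
        outcome = OutcomeSpec(
            treatment_free=ModelSpec(tuple(treatment_free), intercept=True, response="Y"),
            blip=ModelSpec(tuple(blip), intercept=True),
        )
        ps = ModelSpec(tuple(propensity), intercept=True, response="A") if propensity else None
        obs = ModelSpec(tuple(observation), intercept=False, response="obs") if observation else None
        return cls(df, outcome, ps, obs, **kwargs)

    # ------------------------------------------------------------------ #
    def fit(self) -> "ITRResults":
        """Run nuisance fits, form weights, and solve the estimating equation."""
        design = dwols.assemble_design(self.data, self.outcome)
        rows = design.rows

        rate_fit = None
        rho = np.ones(len(rows))
        if self.observation is not None:
            rate_fit = nuisance.fit_proportional_rate(self.data, self.observation)
            rho = nuisance.iiv_weights(rate_fit, rows)

        ps_fit = None
        w_ipt = np.ones(len(rows))
        if self.propensity is not None:
            ps_fit = nuisance.fit_propensity(
                self.data, self.propensity, rows=self.propensity_rows
            )
            w_ipt = nuisance.ipt_weights(ps_fit, rows)

        w = w_ipt * rho
        if self.weight_truncation is not None:
            cap = np.percentile(w, self.weight_truncation)
            w = np.minimum(w, cap)

        fit = dwols.fit_dwols(design, w)
        return ITRResults(
            model=self,
            fit=fit,
            rate_fit=rate_fit,
            propensity_fit=ps_fit,
            ipt_w=w_ipt,
            iiv_rho=rho,
        )


@dataclass
class ITRResults:
    """Fitted doubly weighted ITR.

    Attributes
    ----------
    fit : dwols.ITRFit
        Coefficients and estimating-equation diagnostics.
    rate_fit, propensity_fit
        The nuisance fits actually used (None where the estimator carries no
        such weight).
    """

    model: DoublyWeightedITR
    fit: dwols.ITRFit
    rate_fit: nuisance.RateFit | None
    propensity_fit: nuisance.PropensityFit | None
    ipt_w: np.ndarray
    iiv_rho: np.ndarray

    # -- coefficient access --------------------------------------------- #
    @property
    def params(self) -> pd.Series:
        return pd.Series(self.fit.params, index=self.fit.param_names)

    @property
    def beta(self) -> pd.Series:
        names = [f"tf:{n}" for n in self.model.outcome.treatment_free.column_names]
        return pd.Series(self.fit.beta_hat, index=names)

    @property
    def psi(self) -> pd.Series:
        names = [f"blip:{n}" for n in self.model.outcome.blip.column_names]
        return pd.Series(self.fit.psi_hat, index=names)

    @property
    def gamma(self) -> pd.Series | None:
        if self.rate_fit is None:
            return None
        return pd.Series(self.rate_fit.gamma_hat, index=self.rate_fit.spec.column_names)

    @property
    def kappa(self) -> pd.Series | None:
        if self.propensity_fit is None:
            return None
        return pd.Series(
            self.propensity_fit.kappa_hat, index=self.propensity_fit.spec.column_names
        )

    # -- rule ------------------------------------------------------------ #
    def blip(self, df: pd.DataFrame) -> np.ndarray:
        """Estimated blip values at the rows of ``df``."""
        return dwols.blip_values(self.fit.psi_hat, self.model.outcome, df)

    def decide(self, df: pd.DataFrame) -> np.ndarray:
        """Estimated optimal treatment (1 iff estimated blip >= 0)."""
        return dwols.decide_treatment(self.blip(df))

    # -- inference -------------------------------------------------------- #
    def bootstrap(self, B: int = 500, seed: int = 0, **kwargs):
        """Two-stage cluster bootstrap CIs; see :mod:`dwitr.inference`."""
        from .inference import two_stage_bootstrap

        cfg = EstimatorConfig(
            self.model.name, self.model.outcome, self.model.propensity, self.model.observation
        )
        return two_stage_bootstrap(self.model.panel, cfg, B=B, seed=seed, **kwargs)

    # -- reporting -------------------------------------------------------- #
    def weight_summary(self) -> dict:
        w = self.fit.weights
        return {
            "n_rows": int(self.fit.n_rows),
            "min": float(w.min()),
            "mean": float(w.mean()),
            "max": float(w.max()),
        }

    def summary(self) -> str:
        """Human-readable fit report."""
        lines = [
            f"Doubly weighted ITR fit [{self.model.name}]",
            "=" * 46,
            f"analysis rows: {self.fit.n_rows}",
            f"estimating-equation norm: {self.fit.estimating_eq_norm:.3e}",
            "",
            "treatment-free coefficients (beta):",
        ]
        for k, v in self.beta.items():
            lines.append(f"  {k:<16} {v: .6f}")
        lines.append("blip coefficients (psi):")
        for k, v in self.psi.items():
            lines.append(f"  {k:<16} {v: .6f}")
        if self.gamma is not None:
            lines.append("observation model log rate ratios (gamma):")
            for k, v in self.gamma.items():
                lines.append(f"  {k:<16} {v: .6f}")
        if self.kappa is not None:
            lines.append("propensity coefficients (kappa):")
            for k, v in self.kappa.items():
                lines.append(f"  {k:<16} {v: .6f}")
        ws = self.weight_summary()
        lines.append(
            f"weights: min {ws['min']:.4f} / mean {ws['mean']:.4f} / max {ws['max']:.4f}"
        )
        rule_terms = self.model.outcome.blip.column_names
        rule = " + ".join(
            f"{c:+.4f}*{n}" if n != "1" else f"{c:+.4f}"
            for c, n in zip(self.fit.psi_hat, rule_terms)
        )
        lines.append(f"rule: treat with A=1 iff {rule} >= 0")
        return "\n".join(lines)

    def to_report(self) -> dict:
        """Machine-readable structured report."""
        rep = {
            "estimator": self.model.name,
            "n_rows": int(self.fit.n_rows),
            "estimating_eq_norm": self.fit.estimating_eq_norm,
            "beta": {k: float(v) for k, v in self.beta.items()},
            "psi": {k: float(v) for k, v in self.psi.items()},
            "weights": self.weight_summary(),
        }
        if self.gamma is not None:
            rep["gamma"] = {k: float(v) for k, v in self.gamma.items()}
        if self.kappa is not None:
            rep["kappa"] = {k: float(v) for k, v in self.kappa.items()}
        return rep

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_report(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s
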