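"""Performance metrics and the Monte Carlo scenario harness.

Three criteria quantify how well an estimated rule recovers the true one:

* **MSE of blip values** — mean over analysis rows of the squared gap
  between the true blip ``-2 + 0.5 Q - K1`` and the estimated blip,
  averaged over replicates.  Across replicates it decomposes as squared
  empirical bias of the blip values plus their empirical variance.
* **Decision error rate** — the fraction of rows where the estimated rule
  (treat iff estimated blip >= 0) disagrees with the true rule.
* **Value function** — the mean outcome in a fresh population treated
  according to a given rule, with the mediator drawn conditional on the
  assigned treatment.

``run_scenario`` simulates replicate cohorts under one scenario
configuration, fits every requested estimator on each replicate (sharing
nuisance fits between estimators that use the same specification), and
aggregates the metrics into a :class:`ScenarioReport`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dwols, nuisance
from .exceptions import DwitrError, FitError, InvalidArgumentError
from .simulate import (
    PSI_TRUE,
    ScenarioConfig,
    replicate_seed,
    simulate_baseline,
    simulate_cohort,
    true_blip,
)
from .specs import EstimatorConfig, get_estimator

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------- #
# Metrics
# --------------------------------------------------------------------------- #
def mse_blip(psi_hat, rows: pd.DataFrame, psi_true=PSI_TRUE) -> float:
    """Mean squared gap between true and estimated blip values over rows."""
    if len(rows) == 0:
        raise InvalidArgumentError("mse_blip needs at least one covariate row")
    psi_true = np.asarray(psi_true, dtype=float)
    Q = rows["Q"].to_numpy(dtype=float)
    K1 = rows["K1"].to_numpy(dtype=float)
    b_true = psi_true[0] + psi_true[1] * Q + psi_true[2] * K1
    psi_hat = np.asarray(psi_hat, dtype=float)
    b_hat = psi_hat[0] + psi_hat[1] * Q + psi_hat[2] * K1
    return float(np.mean((b_true - b_hat) ** 2))


def mean_blip_error(psi_hat, rows: pd.DataFrame, psi_true=PSI_TRUE) -> float:
    """Mean (estimated - true) blip value over rows; the per-replicate bias."""
    if len(rows) == 0:
        raise InvalidArgumentError("needs at least one covariate row")
    psi_true = np.asarray(psi_true, dtype=float)
    psi_hat = np.asarray(psi_hat, dtype=float)
    Q = rows["Q"].to_numpy(dtype=float)
    K1 = rows["K1"].to_numpy(dtype=float)
    d = psi_hat - psi_true
    return float(np.mean(d[0] + d[1] * Q + d[2] * K1))


def decision_error_rate(psi_hat, rows: pd.DataFrame, psi_true=PSI_TRUE) -> float:
    """Proportion of rows whose estimated decision differs from the true one."""
    if len(rows) == 0:
        raise InvalidArgumentError("decision_error_rate needs at least one row")
    psi_true = np.asarray(psi_true, dtype=float)
    psi_hat = np.asarray(psi_hat, dtype=float)
    Q = rows["Q"].to_numpy(dtype=float)
    K1 = rows["K1"].to_numpy(dtype=float)
    b_true = psi_true[0] + psi_true[1] * Q + psi_true[2] * K1
    b_hat = psi_hat[0] + psi_hat[1] * Q + psi_hat[2] * K1
    d_true = dwols.decide_treatment(b_true)
    d_hat = dwols.decide_treatment(b_hat)
    return float(np.mean(d_true != d_hat))


# --------------------------------------------------------------------------- #
# Value function
# --------------------------------------------------------------------------- #
def true_rule(df: pd.DataFrame) -> np.ndarray:
    """The gold-standard rule: treat iff the true blip is nonnegative."""
    return dwols.decide_treatment(true_blip(df["Q"], df["K1"]))


def constant_rule(a: int):
    def rule(df: pd.DataFrame) -> np.ndarray:
        return np.full(len(df), int(a), dtype=np.int64)

    return rule


def estimate_value(rule, config: ScenarioConfig, n_eval: int, seed: int) -> float:
    """Mean outcome in a fresh population treated according to ``rule``.

    A new cohort of ``n_eval`` patients is simulated from ``config``; at each
    grid time the treatment is assigned by the rule (a callable mapping a
    covariate frame with columns K1, K2, K3, Q, time to 0/1), the mediator is
    drawn conditional on the assigned treatment, and the mean of Y over all
    person-time is returned.
    """
    if n_eval < 1:
        raise InvalidArgumentError("n_eval must be >= 1")
    rng = np.random.default_rng(seed)
    baseline = simulate_baseline(n_eval, rng)
    m = config.n_grid
    grid = config.grid
    K1 = np.repeat(baseline["K1"].to_numpy(float), m)
    K2 = np.repeat(baseline["K2"].to_numpy(), m)
    K3 = np.repeat(baseline["K3"].to_numpy(float), m)
    t = np.tile(grid, n_eval)
    Q = rng.normal(0.5, np.sqrt(0.5), n_eval * m)
    cov = pd.DataFrame({"time": t, "K1": K1, "K2": K2, "K3": K3, "Q": Q})
    A = np.asarray(rule(cov), dtype=np.int64)
    if A.shape != (n_eval * m,) or not np.isin(A, [0, 1]).all():
        raise InvalidArgumentError("rule must return one 0/1 value per row")
    z_mean = np.where(A == 1, 2.0, 4.0)
    z_sd = np.sqrt(np.where(A == 1, 1.0, 2.0))
    Z = rng.normal(z_mean, z_sd)
    phi = np.repeat(rng.normal(0.0, np.sqrt(config.phi_var), n_eval), m)
    eps = rng.normal(phi, np.sqrt(config.eps_var))
    from .simulate import OUTCOME_COEFS as oc

    Y = (
        oc["alpha_slope"] * t
        + oc["A"] * A
        + oc["Z_centered"] * (Z - z_mean)
        + oc["K1"] * K1
        + oc["K2"] * K2
        + oc["K3"] * K3
        + oc["A_Q"] * A * Q
        + oc["A_K1"] * A * K1
        + eps
    )
    return float(Y.mean())


# --------------------------------------------------------------------------- #
# Monte Carlo harness
# --------------------------------------------------------------------------- #
@dataclass
class EstimatorSummary:
    name: str
    n_replicates: int
    mse_blip: float
    mse_mc_se: float
    bias_blip: float
    var_blip: float
    error_rate: float
    psi_bias: np.ndarray
    psi_mean: np.ndarray
    value: float | None = None

    def as_dict(self) -> dict:
        d = {
            "estimator": self.name,
            "n_replicates": self.n_replicates,
            "mse_blip": self.mse_blip,
            "mse_mc_se": self.mse_mc_se,
            "bias_blip": self.bias_blip,
            "var_blip": self.var_blip,
            "error_rate": self.error_rate,
        }
        for i, b in enumerate(self.psi_bias):
            d[f"psi{i}_bias"] = float(b)
        if self.value is not None:
            d["value"] = self.value
        return d


@dataclass
class ScenarioReport:
    """Monte Carlo summary for one (scenario, sample size) cell."""

    config: ScenarioConfig
    estimators: dict  # name -> EstimatorSummary
    visit_mean: float
    visit_iqr: tuple
    n_replicates: int
    n_failures: dict
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([s.as_dict() for s in self.estimators.values()]).set_index(
            "estimator"
        )

    def to_text(self) -> str:
        """One row per estimator x metric, mirroring the results-table layout."""
        lines = [
            f"scenario gamma={np.array2string(self.config.gamma_obs)}  "
            f"n={self.config.n_patients}  replicates={self.n_replicates}",
            f"visits per patient: mean {self.visit_mean:.1f} "
            f"(IQR {self.visit_iqr[0]:.0f}-{self.visit_iqr[1]:.0f})",
            f"{'estimator':<10}{'mse_blip':>10}{'mc_se':>9}{'err_rate':>10}"
            f"{'bias':>9}{'failures':>10}",
        ]
        for name, s in self.estimators.items():
            lines.append(
                f"{name:<10}{s.mse_blip:>10.3f}{s.mse_mc_se:>9.3f}"
                f"{s.error_rate:>10.3f}{s.bias_blip:>9.3f}"
                f"{self.n_failures.get(name, 0):>10d}"
            )
        return "\n".join(lines)


def _shared_fit(panel, cfg: EstimatorConfig, caches: dict):
    """Fit one estimator, reusing nuisance fits cached per replicate."""
    design_cache, rate_cache, ps_cache = caches["design"], caches["rate"], caches["ps"]
    if cfg.outcome not in design_cache:
        design_cache[cfg.outcome] = dwols.assemble_design(panel.data, cfg.outcome)
    design = design_cache[cfg.outcome]
    rows = design.rows

    rho = np.ones(len(rows))
    if cfg.observation is not None:
        if cfg.observation not in rate_cache:
            rate_cache[cfg.observation] = nuisance.fit_proportional_rate(
                panel.data, cfg.observation
            )
        rho = nuisance.iiv_weights(rate_cache[cfg.observation], rows)

    w_ipt = np.ones(len(rows))
    if cfg.propensity is not None:
        if cfg.propensity not in ps_cache:
            ps_cache[cfg.propensity] = nuisance.fit_propensity(
                panel.data, cfg.propensity, rows="all"
            )
        w_ipt = nuisance.ipt_weights(ps_cache[cfg.propensity], rows)

    return dwols.fit_dwols(design, w_ipt * rho), rows


def run_scenario(
    config: ScenarioConfig,
    estimators=("DW1", "DW2", "DW3", "DW4", "OLS", "IPT"),
    n_replicates: int = 1000,
    psi_true=PSI_TRUE,
    compute_value: bool = False,
    value_n_eval: int = 25000,
    max_failure_frac: float = 0.05,
) -> ScenarioReport:
    """Simulate replicate cohorts and summarise every estimator's metrics.

    Replicate r uses the deterministic RNG substream ``(config.seed, r)``, so
    reports are reproducible and replicates could be farmed out in parallel.
    A replicate on which an estimator fails to fit is excluded from that
    estimator's summary (with a logged count); more than
    ``max_failure_frac`` failures for any estimator is a hard error.
    """
    if n_replicates < 1:
        raise InvalidArgumentError("n_replicates must be >= 1")
    configs = [get_estimator(e) if isinstance(e, str) else e for e in estimators]
    names = [c.name for c in configs]
    per_rep: dict[str, list] = {n: [] for n in names}
    failures = {n: 0 for n in names}
    visit_means = np.empty(n_replicates)
    visit_q1 = np.empty(n_replicates)
    visit_q3 = np.empty(n_replicates)

    for r in range(n_replicates):
        rng = replicate_seed(config.seed, r)
        panel = simulate_cohort(config, rng)
        counts = panel.visit_counts()
        visit_means[r] = counts.mean()
        visit_q1[r], visit_q3[r] = np.percentile(counts, [25, 75])
        caches = {"design": {}, "rate": {}, "ps": {}}
        for cfg in configs:
            try:
                fit, rows = _shared_fit(panel, cfg, caches)
            except DwitrError as exc:
                failures[cfg.name] += 1
                logger.warning("replicate %d: %s failed: %s", r, cfg.name, exc)
                continue
            rec = {
                "mse": mse_blip(fit.psi_hat, rows, psi_true),
                "err": decision_error_rate(fit.psi_hat, rows, psi_true),
                "bias": mean_blip_error(fit.psi_hat, rows, psi_true),
                "psi": fit.psi_hat,
            }
            if compute_value:
                blip_spec = cfg.outcome.blip
                psi_hat = fit.psi_hat

                def est_rule(df, _spec=blip_spec, _psi=psi_hat):
                    return dwols.decide_treatment(_spec.design_matrix(df) @ _psi)

                rec["value"] = estimate_value(
                    est_rule, config, value_n_eval, seed=int(rng.integers(2**31))
                )
            per_rep[cfg.name].append(rec)

    summaries = {}
    for name in names:
        recs = per_rep[name]
        if failures[name] > max_failure_frac * n_replicates:
            raise FitError(
                f"{name}: {failures[name]} of {n_replicates} replicates failed"
            )
        if not recs:
            raise FitError(f"{name}: no successful replicates")
        mses = np.array([rec["mse"] for rec in recs])
        biases = np.array([rec["bias"] for rec in recs])
        errs = np.array([rec["err"] for rec in recs])
        psis = np.vstack([rec["psi"] for rec in recs])
        mse = float(mses.mean())
        bias = float(biases.mean())
        summaries[name] = EstimatorSummary(
            name=name,
            n_replicates=len(recs),
            mse_blip=mse,
            mse_mc_se=float(mses.std(ddof=1) / np.sqrt(len(mses))) if len(mses) > 1 else 0.0,
            bias_blip=bias,
            var_blip=mse - bias**2,
            error_rate=float(errs.mean()),
            psi_bias=psis.mean(axis=0) - np.asarray(psi_true, dtype=float),
            psi_mean=psis.mean(axis=0),
            value=float(np.mean([rec["value"] for rec in recs]))
            if compute_value
            else None,
        )
    return ScenarioReport(
        config=config,
        estimators=summaries,
        visit_mean=float(visit_means.mean()),
        visit_iqr=(float(visit_q1.mean()), float(visit_q3.mean())),
        n_replicates=n_replicates,
        n_failures=failures,
        seed=config.seed,
    )
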