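"""Two-stage cluster bootstrap for blip coefficients and rate ratios.

Each bootstrap replicate resamples patients with replacement (first stage)
and, within every sampled patient, resamples that patient's observed-outcome
rows with replacement keeping the original within-patient count (second
stage).  A patient drawn twice enters as two distinct clusters with fresh
identifiers, and the whole estimator — visit-intensity model, propensity
model, and the doubly weighted least squares — is refit on every replicate
so the sampling variability of the estimated weights propagates into the
intervals.  Percentile 95% intervals are reported.

The scheme preserves within-patient correlation but not within-patient time
trends; no correction for serial dependence is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import dwols, nuisance
from .exceptions import DwitrError, FitError, InvalidArgumentError
from .panel import LongitudinalPanel
from .specs import EstimatorConfig

logger = logging.getLogger(__name__)


@dataclass
class BootstrapResult:
    """Bootstrap draws and percentile intervals for one estimator fit."""

    param_names: list
    point: np.ndarray
    draws: np.ndarray  # (B_successful, p)
    B: int
    n_failures: int
    seed: int
    ci_level: float = 0.95

    @property
    def lower(self) -> np.ndarray:
        a = 100 * (1 - self.ci_level) / 2
        return np.percentile(self.draws, a, axis=0)

    @property
    def upper(self) -> np.ndarray:
        a = 100 * (1 - (1 - self.ci_level) / 2)
        return np.percentile(self.draws, a, axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.point,
                "ci_lower": self.lower,
                "ci_upper": self.upper,
            },
            index=self.param_names,
        )

    def summary(self) -> str:
        df = self.to_frame()
        lines = [
            f"two-stage cluster bootstrap: B={self.B}, "
            f"failures={self.n_failures}, seed={self.seed}",
            f"{'parameter':<18}{'estimate':>10}{'2.5%':>10}{'97.5%':>10}",
        ]
        for name, row in df.iterrows():
            lines.append(
                f"{name:<18}{row['estimate']:>10.4f}"
                f"{row['ci_lower']:>10.4f}{row['ci_upper']:>10.4f}"
            )
        return "\n".join(lines)


def _fit_resampled(proc: pd.DataFrame, ana: pd.DataFrame, cfg: EstimatorConfig):
    """Full estimator on one resampled dataset; returns (psi, gamma or None)."""
    design = dwols.assemble_design(ana, cfg.outcome)
    rows = design.rows
    rho = np.ones(len(rows))
    gamma = None
    if cfg.observation is not None:
        rate = nuisance.fit_proportional_rate(proc, cfg.observation)
        rho = nuisance.iiv_weights(rate, rows)
        gamma = rate.gamma_hat
    w = np.ones(len(rows))
    if cfg.propensity is not None:
        ps = nuisance.fit_propensity(proc, cfg.propensity, rows="all")
        w = nuisance.ipt_weights(ps, rows)
    fit = dwols.fit_dwols(design, w * rho)
    return fit.psi_hat, gamma


def two_stage_bootstrap(
    panel,
    cfg: EstimatorConfig,
    B: int = 500,
    seed: int = 0,
    ci_level: float = 0.95,
    max_failure_frac: float = 0.2,
) -> BootstrapResult:
    """Percentile bootstrap CIs for the blip coefficients (and rate ratios).

    Parameters
    ----------
    panel : LongitudinalPanel
        The original counting-process panel.
    cfg : EstimatorConfig
        Which estimator to refit on each replicate.
    B : int
        Number of bootstrap replicates (>= 1).
    seed : int
        RNG seed; identical (panel, cfg, B, seed) give identical intervals.

    Raises
    ------
    InvalidArgumentError
        On B < 1 or a single-patient panel (no between-cluster variability
        to resample).
    """
    if B < 1:
        raise InvalidArgumentError("B must be >= 1")
    df = panel.data if isinstance(panel, LongitudinalPanel) else panel
    df = df.reset_index(drop=True)
    id_codes, uniq = pd.factorize(df["id"])
    n_pat = len(uniq)
    if n_pat < 2:
        raise InvalidArgumentError("bootstrap needs at least 2 patients")

    obs_vals = df["obs"].to_numpy()
    blocks = [np.flatnonzero(id_codes == k) for k in range(n_pat)]
    visit_blocks = [idx[obs_vals[idx] == 1] for idx in blocks]
    block_lens = np.array([len(b) for b in blocks])

    # point estimate on the original data
    psi0, gamma0 = _fit_resampled(df, df, cfg)
    names = [f"blip:{n}" for n in cfg.outcome.blip.column_names]
    point = list(psi0)
    if gamma0 is not None:
        names += [f"gamma:{n}" for n in cfg.observation.column_names]
        point += list(gamma0)
    point = np.asarray(point)

    rng = np.random.default_rng(seed)
    draws = []
    n_failures = 0
    for b in range(B):
        chosen = rng.integers(0, n_pat, n_pat)
        proc_idx = np.concatenate([blocks[k] for k in chosen])
        proc = df.iloc[proc_idx].copy()
        proc["id"] = np.repeat(np.arange(n_pat), block_lens[chosen])
        obs_counts = np.zeros(len(proc_idx), dtype=np.int64)
        ana_idx_parts, ana_id_parts = [], []
        pos = 0
        for j, k in enumerate(chosen):
            blk, vis = blocks[k], visit_blocks[k]
            if len(vis):
                samp = rng.choice(vis, size=len(vis), replace=True)
                np.add.at(obs_counts, pos + np.searchsorted(blk, samp), 1)
                ana_idx_parts.append(samp)
                ana_id_parts.append(np.full(len(samp), j))
            pos += len(blk)
        proc["obs"] = obs_counts
        if not ana_idx_parts:
            n_failures += 1
            continue
        ana = df.iloc[np.concatenate(ana_idx_parts)].copy()
        ana["id"] = np.concatenate(ana_id_parts)
        try:
            psi_b, gamma_b = _fit_resampled(proc, ana, cfg)
        except DwitrError as exc:
            n_failures += 1
            logger.warning("bootstrap replicate %d dropped: %s", b, exc)
            continue
        row = list(psi_b) + (list(gamma_b) if gamma_b is not None else [])
        draws.append(row)

    if not draws or n_failures > max_failure_frac * B:
        raise FitError(f"bootstrap failed on {n_failures} of {B} replicates")
    return BootstrapResult(
        param_names=names,
        point=point,
        draws=np.asarray(draws),
        B=B,
        n_failures=n_failures,
        seed=seed,
        ci_level=ci_level,
    )
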