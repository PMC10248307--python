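"""Synthetic cohort generator with a covariate-driven visit process.

The generative mechanism is a longitudinal cohort observed on a fixed time
grid.  Per patient: three baseline confounders K1 ~ N(1, 1), K2 ~
Bernoulli(0.55), K3 ~ N(0, 1) and a random intercept phi ~ N(0, 0.04).  At
each grid time t the binary treatment is drawn as

    A(t) ~ Bernoulli(expit(0.5 + 0.55 K1 - 0.2 K2 - 1 K3)),

a mediator Z(t) | A(t)=1 ~ N(2, 1), Z(t) | A(t)=0 ~ N(4, 2), a tailoring
variable Q(t) ~ N(0.5, 0.5), and the latent outcome

    Y(t) = t/100 - 2 A(t) + 2.5 {Z(t) - E[Z(t)|A(t)]} + 0.4 K1 + 0.05 K2
           - 0.6 K3 + 0.5 A(t) Q(t) - 1 A(t) K1 + eps(t),

with eps(t) ~ N(phi, 0.01).  All N(a, b) above are (mean, variance).  The
true blip is therefore -2 + 0.5 Q(t) - 1 K1 with coefficients
``PSI_TRUE = (-2, 0.5, -1)`` on (1, Q, K1).

Visits follow a nonhomogeneous Poisson process discretised on the grid: the
outcome is observed at t with probability

    p(t) = min(base_rate * exp{g1 A(t) + g2 Z(t) + g3 K2 + g4 K3}, 1),

the per-grid-point Bernoulli version of the intensity
0.1 exp{gamma' V(t)} with V(t) = (A(t), Z(t), K2, K3).  Four preset gamma
vectors ("scenario1" .. "scenario4") range from strong covariate-driven
observation to uninformative observation (gamma = 0, ~10 visits per patient
on the default 100-point grid).

Covariates are redrawn independently at each grid time (no serial
correlation), no patient is censored before tau, and the outcome is missing
exactly where no visit occurred.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .exceptions import InvalidArgumentError, PanelSchemaError
from .panel import PANEL_COLUMNS, LongitudinalPanel

logger = logging.getLogger(__name__)

#: True blip coefficients on (1, Q, K1).
PSI_TRUE = np.array([-2.0, 0.5, -1.0])

#: True treatment-logit coefficients on (1, K1, K2, K3).
TREATMENT_COEFS = np.array([0.5, 0.55, -0.2, -1.0])

#: Preset visit-intensity log-rate-ratio vectors on (A, Z, K2, K3).
SCENARIO_GAMMAS = {
    "scenario1": np.array([-2.0, -0.3, 0.2, -1.2]),
    "scenario2": np.array([0.3, -0.6, -0.4, -0.3]),
    "scenario3": np.array([0.4, -0.8, 1.0, 0.6]),
    "scenario4": np.array([0.0, 0.0, 0.0, 0.0]),
}

#: Outcome-equation coefficients (latent mean model).
OUTCOME_COEFS = {
    "alpha_slope": 0.01,  # alpha(t) = t / 100
    "A": -2.0,
    "Z_centered": 2.5,
    "K1": 0.4,
    "K2": 0.05,
    "K3": -0.6,
    "A_Q": 0.5,
    "A_K1": -1.0,
}

_Z_MEAN = {1: 2.0, 0: 4.0}
_Z_VAR = {1: 1.0, 0: 2.0}


@dataclass(frozen=True)
class ScenarioConfig:
    """Full parameterisation of one simulated study condition.

    Parameters
    ----------
    n_patients : int
        Cohort size.
    gamma_obs : array-like of length 4
        Log rate ratios of the visit intensity on (A(t), Z(t), K2, K3).
    grid_step : float
        Grid resolution in time units (default 0.01).
    tau : float
        Maximum follow-up; the grid is {grid_step, 2*grid_step, ..., tau}.
    base_rate : float
        Baseline per-grid-point visit probability scale (default 0.1).
    seed : int
        Master RNG seed.
    """

    n_patients: int
    gamma_obs: np.ndarray = field(
        default_factory=lambda: SCENARIO_GAMMAS["scenario4"].copy()
    )
    grid_step: float = 0.01
    tau: float = 1.0
    base_rate: float = 0.1
    treatment_coefs: np.ndarray = field(
        default_factory=lambda: TREATMENT_COEFS.copy()
    )
    phi_var: float = 0.04
    eps_var: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise InvalidArgumentError("n_patients must be >= 1")
        if self.grid_step <= 0 or self.tau <= 0:
            raise InvalidArgumentError("grid_step and tau must be positive")
        if self.base_rate < 0:
            raise InvalidArgumentError("base_rate must be >= 0")
        object.__setattr__(
            self, "gamma_obs", np.asarray(self.gamma_obs, dtype=float)
        )
        object.__setattr__(
            self, "treatment_coefs", np.asarray(self.treatment_coefs, dtype=float)
        )
        if self.gamma_obs.shape != (4,):
            raise InvalidArgumentError("gamma_obs must have length 4")
        if self.treatment_coefs.shape != (4,):
            raise InvalidArgumentError("treatment_coefs must have length 4")

    @property
    def n_grid(self) -> int:
        return int(round(self.tau / self.grid_step))

    @property
    def grid(self) -> np.ndarray:
        # round to the canonical decimal floats so times print compactly and
        # round-trip text serialization exactly
        return np.round((np.arange(self.n_grid) + 1) * self.grid_step, 12)

    @classmethod
    def preset(cls, name: str, n_patients: int, seed: int = 0, **kwargs) -> "ScenarioConfig":
        """Build a config from a scenario preset name ("scenario1".."scenario4")."""
        key = name if name.startswith("scenario") else f"scenario{name}"
        if key not in SCENARIO_GAMMAS:
            raise InvalidArgumentError(
                f"unknown scenario {name!r}; choose from {sorted(SCENARIO_GAMMAS)}"
            )
        return cls(
            n_patients=n_patients,
            gamma_obs=SCENARIO_GAMMAS[key].copy(),
            seed=seed,
            **kwargs,
        )

    def with_seed(self, seed: int) -> "ScenarioConfig":
        return replace(self, seed=int(seed))


def replicate_seed(master_seed: int, replicate: int) -> np.random.Generator:
    """Deterministic per-replicate RNG substream from one master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(replicate),))
    )


# --------------------------------------------------------------------------- #
def simulate_baseline(n_patients: int, rng) -> pd.DataFrame:
    """Draw the baseline confounder table (one row per patient).

    K1 ~ N(1, 1), K2 ~ Bernoulli(0.55), K3 ~ N(0, 1).

    Parameters
    ----------
    rng : numpy.random.Generator or int
        Generator, or a seed to build one.
    """
    if n_patients < 1:
        raise InvalidArgumentError("n_patients must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return pd.DataFrame(
        {
            "id": np.arange(n_patients),
            "K1": rng.normal(1.0, 1.0, n_patients),
            "K2": rng.binomial(1, 0.55, n_patients),
            "K3": rng.normal(0.0, 1.0, n_patients),
        }
    )


def simulate_panel(
    baseline: pd.DataFrame, config: ScenarioConfig, rng=None
) -> LongitudinalPanel:
    """Simulate the latent panel: every grid time, outcome present everywhere.

    Treatment, mediator, tailoring variable and noise are redrawn
    independently at each grid point; the patient-level random intercept phi
    is drawn once.  Returns a latent :class:`LongitudinalPanel` (``obs`` all
    zero, ``Y`` fully observed).
    """
    for col in ("id", "K1", "K2", "K3"):
        if col not in baseline.columns:
            raise PanelSchemaError(f"baseline table lacks column {col!r}")
    rng = np.random.default_rng(config.seed if rng is None else rng) \
        if not isinstance(rng, np.random.Generator) else rng

    n = len(baseline)
    m = config.n_grid
    grid = config.grid

    ids = np.repeat(baseline["id"].to_numpy(), m)
    K1 = np.repeat(baseline["K1"].to_numpy(float), m)
    K2 = np.repeat(baseline["K2"].to_numpy(), m)
    K3 = np.repeat(baseline["K3"].to_numpy(float), m)
    t = np.tile(grid, n)

    c0, c1, c2, c3 = config.treatment_coefs
    pA = expit(c0 + c1 * K1 + c2 * K2 + c3 * K3)
    A = rng.binomial(1, pA)

    z_mean = np.where(A == 1, _Z_MEAN[1], _Z_MEAN[0])
    z_sd = np.sqrt(np.where(A == 1, _Z_VAR[1], _Z_VAR[0]))
    Z = rng.normal(z_mean, z_sd)
    Q = rng.normal(0.5, np.sqrt(0.5), n * m)

    phi = np.repeat(rng.normal(0.0, np.sqrt(config.phi_var), n), m)
    eps = rng.normal(phi, np.sqrt(config.eps_var))

    oc = OUTCOME_COEFS
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

    df = pd.DataFrame(
        {
            "id": ids,
            "time": t,
            "at_risk": np.ones(n * m, dtype=np.int64),
            "obs": np.zeros(n * m, dtype=np.int64),
            "A": A.astype(np.int64),
            "Y": Y,
            "K1": K1,
            "K2": np.asarray(K2, dtype=np.int64),
            "K3": K3,
            "Z": Z,
            "Q": Q,
        },
        columns=PANEL_COLUMNS,
    )
    return LongitudinalPanel(df, latent=True)


def simulate_observation_times(
    latent: LongitudinalPanel, config: ScenarioConfig, rng=None
) -> LongitudinalPanel:
    """Assign visit indicators and mask the outcome between visits.

    Visits are Bernoulli draws per grid point with probability
    ``min(base_rate * exp(gamma' V(t)), 1)``; a warning is logged when the
    probability is clipped at 1.  Patients with zero visits remain in the
    panel (they still contribute to the at-risk sets of the visit model).
    """
    rng = np.random.default_rng(config.seed if rng is None else rng) \
        if not isinstance(rng, np.random.Generator) else rng
    df = latent.data.copy()
    g = config.gamma_obs
    lin = (
        g[0] * df["A"].to_numpy()
        + g[1] * df["Z"].to_numpy(float)
        + g[2] * df["K2"].to_numpy()
        + g[3] * df["K3"].to_numpy(float)
    )
    p = config.base_rate * np.exp(lin)
    n_clip = int((p > 1.0).sum())
    if n_clip:
        logger.warning(
            "visit probability clipped at 1 for %d of %d person-times", n_clip, len(p)
        )
    p = np.minimum(p, 1.0)
    dN = rng.binomial(1, p) * df["at_risk"].to_numpy()
    df["obs"] = dN.astype(np.int64)
    df.loc[df["obs"] == 0, "Y"] = np.nan
    return LongitudinalPanel(df, latent=False)


def simulate_cohort(config: ScenarioConfig, rng=None) -> LongitudinalPanel:
    """Baseline -> latent panel -> visit masking, with one RNG stream."""
    rng = np.random.default_rng(config.seed if rng is None else rng) \
        if not isinstance(rng, np.random.Generator) else rng
    baseline = simulate_baseline(config.n_patients, rng)
    latent = simulate_panel(baseline, config, rng)
    return simulate_observation_times(latent, config, rng)


def true_blip(Q, K1) -> np.ndarray:
    """True blip values -2 + 0.5 Q - 1 K1 at the given covariates."""
    return PSI_TRUE[0] + PSI_TRUE[1] * np.asarray(Q, float) + PSI_TRUE[2] * np.asarray(K1, float)
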