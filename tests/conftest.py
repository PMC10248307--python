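import numpy as np
import pandas as pd
import pytest

from dwitr import LongitudinalPanel, ScenarioConfig, simulate_cohort
from dwitr.panel import PANEL_COLUMNS


def build_panel(rows: list[dict]) -> LongitudinalPanel:
    """Hand-build a panel from row dicts; unspecified columns get defaults."""
    defaults = {
        "at_risk": 1,
        "obs": 1,
        "A": 0,
        "Y": 0.0,
        "K1": 0.0,
        "K2": 0,
        "K3": 0.0,
        "Z": 0.0,
        "Q": 0.0,
    }
    full = [{**defaults, **r} for r in rows]
    return LongitudinalPanel(pd.DataFrame(full, columns=PANEL_COLUMNS))


@pytest.fixture(scope="session")
def make_panel():
    return build_panel


@pytest.fixture(scope="session")
def sc1_cohort_250() -> LongitudinalPanel:
    """One observed cohort under strong covariate-driven observation."""
    return simulate_cohort(ScenarioConfig.preset("scenario1", 250, seed=7))


@pytest.fixture(scope="session")
def sc4_cohort_400() -> LongitudinalPanel:
    """One observed cohort under uninformative observation (gamma = 0)."""
    return simulate_cohort(ScenarioConfig.preset("scenario4", 400, seed=9))


@pytest.fixture(scope="session")
def sc1_cohort_2000() -> LongitudinalPanel:
    """A larger cohort for moment/recovery checks."""
    return simulate_cohort(ScenarioConfig.preset("scenario1", 2000, seed=21))
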