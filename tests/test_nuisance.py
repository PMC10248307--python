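"""Propensity and visit-intensity model checks, including independent oracles."""

import numpy as np
import pandas as pd
import pytest
import scipy.optimize
import statsmodels.api as sm

from dwitr import (
    FitError,
    InvalidArgumentError,
    ScenarioConfig,
    fit_propensity,
    fit_proportional_rate,
    iiv_weights,
    ipt_weights,
    simulate_baseline,
    simulate_cohort,
    simulate_observation_times,
    simulate_panel,
)
from dwitr.nuisance import PropensityFit, RateFit, breslow_loglik, _breslow_parts
from dwitr.specs import ModelSpec

PS_SPEC = ModelSpec(("K1", "K2", "K3"), intercept=True, response="A")
OBS_SPEC = ModelSpec(("A", "Z", "K2", "K3"), intercept=False, response="obs")


# --------------------------------------------------------------------------- #
# Propensity
# --------------------------------------------------------------------------- #
class TestPropensity:
    def test_recovers_treatment_assignment_coefficients(self, sc1_cohort_2000):
        fit = fit_propensity(sc1_cohort_2000, PS_SPEC, rows="all")
        np.testing.assert_allclose(
            fit.kappa_hat, [0.5, 0.55, -0.2, -1.0], atol=0.06
        )
        assert np.all((fit.fitted_prob > 0) & (fit.fitted_prob < 1))

    def test_constant_treatment_is_separation_error(self, make_panel):
        panel = make_panel(
            [{"id": 0, "time": 0.01 * (x + 1), "A": 1, "K1": float(x)} for x in range(5)]
        )
        with pytest.raises(FitError, match="separation|constant"):
            fit_propensity(panel, ModelSpec(("K1",), intercept=True))

    def test_matches_grid_search_likelihood_maximizer(self, make_panel):
        """On a 6-row dataset the ML estimate agrees with a brute-force grid
        maximizer of the Bernoulli log-likelihood to 3 decimals."""
        K1 = np.array([-1.0, -0.5, 0.0, 0.5, 1.0, 1.5])
        A = np.array([0, 0, 1, 0, 1, 1])
        panel = make_panel(
            [
                {"id": i, "time": 0.01 * (i + 1), "A": int(a), "K1": k}
                for i, (a, k) in enumerate(zip(A, K1))
            ]
        )
        fit = fit_propensity(panel, ModelSpec(("K1",), intercept=True), rows="all")

        def loglik(b0, b1):
            eta = b0 + np.multiply.outer(b1, K1)
            return (A * eta - np.log1p(np.exp(eta))).sum(axis=-1)

        grid = np.arange(-4, 4, 0.05)
        ll = np.array([loglik(b0, grid) for b0 in grid])
        i0, i1 = np.unravel_index(ll.argmax(), ll.shape)
        fine0 = np.arange(grid[i0] - 0.06, grid[i0] + 0.06, 0.001)
        fine1 = np.arange(grid[i1] - 0.06, grid[i1] + 0.06, 0.001)
        llf = np.array([loglik(b0, fine1) for b0 in fine0])
        j0, j1 = np.unravel_index(llf.argmax(), llf.shape)
        np.testing.assert_allclose(
            fit.kappa_hat, [fine0[j0], fine1[j1]], atol=2e-3
        )

    def test_concave_likelihood_start_invariance(self, sc4_cohort_400):
        df = sc4_cohort_400.data
        X = PS_SPEC.design_matrix(df)
        y = df["A"].to_numpy(float)
        r1 = sm.Logit(y, X).fit(disp=0, start_params=np.zeros(4))
        r2 = sm.Logit(y, X).fit(disp=0, start_params=np.array([1.0, -1.0, 0.5, 0.5]))
        np.testing.assert_allclose(r1.params, r2.params, atol=1e-6)


class TestIPTWeights:
    def test_known_probabilities(self, make_panel):
        spec = ModelSpec((), intercept=True, response="A")
        rows_a1 = make_panel([{"id": 0, "time": 0.01, "A": 1}]).data
        fit = PropensityFit(spec, np.array([0.0]), np.array([0.5]), 1)
        assert ipt_weights(fit, rows_a1)[0] == pytest.approx(2.0)
        rows_a0 = make_panel([{"id": 0, "time": 0.01, "A": 0}]).data
        fit75 = PropensityFit(spec, np.array([np.log(3.0)]), np.array([0.75]), 1)
        assert ipt_weights(fit75, rows_a0)[0] == pytest.approx(4.0)

    def test_weighted_confounder_balance(self, sc1_cohort_2000):
        """IPT weighting equalises confounder means across treatment arms."""
        df = sc1_cohort_2000.data
        fit = fit_propensity(df, PS_SPEC, rows="all")
        w = ipt_weights(fit, df)
        a = df["A"].to_numpy()
        k1 = df["K1"].to_numpy()
        raw_gap = k1[a == 1].mean() - k1[a == 0].mean()
        w_gap = np.average(k1[a == 1], weights=w[a == 1]) - np.average(
            k1[a == 0], weights=w[a == 0]
        )
        assert abs(raw_gap) > 0.2  # confounding is real before weighting
        assert abs(w_gap) < 0.03


# --------------------------------------------------------------------------- #
# Proportional rate model
# --------------------------------------------------------------------------- #
def _toy_rate_panel(make_panel):
    """3 patients x 5 grid times, one event per event time (tie-free)."""
    rows = []
    events = {(0, 0.02), (0, 0.04), (1, 0.03), (2, 0.05)}
    rng = np.random.default_rng(5)
    for pid in range(3):
        for j, t in enumerate([0.01, 0.02, 0.03, 0.04, 0.05]):
            rows.append(
                {
                    "id": pid,
                    "time": t,
                    "obs": int((pid, t) in events),
                    "A": int(rng.integers(0, 2)),
                    "Z": float(rng.normal(3, 1)),
                    "Y": 0.0,
                }
            )
    return make_panel(rows)


class TestProportionalRate:
    def test_null_scenario_recovery(self, sc4_cohort_400):
        fit = fit_proportional_rate(sc4_cohort_400, OBS_SPEC)
        assert np.linalg.norm(fit.gamma_hat) < 0.12

    def test_scenario1_recovery(self, sc1_cohort_2000):
        fit = fit_proportional_rate(sc1_cohort_2000, OBS_SPEC)
        np.testing.assert_allclose(
            fit.gamma_hat, [-2.0, -0.3, 0.2, -1.2], atol=0.15
        )

    def test_score_is_zero_at_optimum(self, sc1_cohort_250):
        fit = fit_proportional_rate(sc1_cohort_250, OBS_SPEC)
        X, dN, codes = _breslow_parts(sc1_cohort_250.data, OBS_SPEC)
        _, grad, _ = breslow_loglik(fit.gamma_hat, X, dN, codes)
        assert np.linalg.norm(grad) < 1e-6 * max(1.0, dN.sum())

    def test_matches_direct_partial_likelihood_maximizer(self, make_panel):
        """Newton solution equals a Nelder-Mead maximizer of the written-out
        Breslow partial likelihood to 4 decimals on a toy panel."""
        panel = _toy_rate_panel(make_panel)
        spec = ModelSpec(("A", "Z"), intercept=False, response="obs")
        fit = fit_proportional_rate(panel, spec)

        df = panel.data

        def neg_breslow(gamma):
            ll = 0.0
            for _, grp in df[df["at_risk"] == 1].groupby("time"):
                d = grp["obs"].sum()
                if d == 0:
                    continue
                V = grp[["A", "Z"]].to_numpy(float)
                ev = grp["obs"].to_numpy(float)
                ll += float(ev @ (V @ gamma))
                ll -= d * np.log(np.exp(V @ gamma).sum())
            return -ll

        res = scipy.optimize.minimize(
            neg_breslow,
            np.zeros(2),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 4000},
        )
        np.testing.assert_allclose(fit.gamma_hat, res.x, atol=1e-4)

    def test_matches_r_survival_coxph(self, make_panel, tmp_path):
        """Cross-check against R survival::coxph (Breslow ties) in
        counting-process form — the reference Andersen–Gill implementation."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        panel = _toy_rate_panel(make_panel)
        spec = ModelSpec(("A", "Z"), intercept=False, response="obs")
        fit = fit_proportional_rate(panel, spec)
        df = panel.data.copy()
        df["start"] = np.round(df["time"] - 0.01, 10)
        csv = tmp_path / "toy.csv"
        df[["id", "start", "time", "obs", "A", "Z"]].to_csv(csv, index=False)
        script = (
            "suppressMessages(library(survival));"
            f"d <- read.csv('{csv}');"
            "f <- coxph(Surv(start, time, obs) ~ A + Z, data=d, ties='breslow');"
            "cat(sprintf('%.10f %.10f', coef(f)[1], coef(f)[2]))"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        ref = np.array([float(x) for x in out.stdout.split()])
        np.testing.assert_allclose(fit.gamma_hat, ref, atol=1e-4)

    def test_no_events_is_fit_error(self, make_panel):
        panel = make_panel(
            [{"id": 0, "time": 0.01, "obs": 0}, {"id": 1, "time": 0.01, "obs": 0}]
        )
        with pytest.raises(FitError, match="event"):
            fit_proportional_rate(panel, ModelSpec(("Z",), intercept=False))

    def test_invariant_to_baseline_rate_scale(self):
        """Doubling base_rate moves gamma-hat only within MC error (the
        baseline rate is not part of the estimand)."""
        cfg = ScenarioConfig.preset("scenario1", 800, seed=31)
        latent = simulate_panel(simulate_baseline(800, rng=31), cfg, rng=31)
        fits = []
        for rate, rs in [(0.1, 32), (0.2, 33)]:
            cfg_r = ScenarioConfig.preset("scenario1", 800, base_rate=rate, seed=31)
            obs = simulate_observation_times(latent, cfg_r, rng=rs)
            fits.append(fit_proportional_rate(obs, OBS_SPEC).gamma_hat)
        np.testing.assert_allclose(fits[0], fits[1], atol=0.3)


class TestIIVWeights:
    def test_formula_values(self, make_panel):
        spec = ModelSpec(("A", "Z"), intercept=False)
        fit = RateFit(spec, np.array([0.0, 0.0]), 1, 0.0, 0.0)
        rows = make_panel([{"id": 0, "time": 0.01, "A": 1, "Z": 3.0}]).data
        assert iiv_weights(fit, rows)[0] == pytest.approx(1.0)
        fit2 = RateFit(spec, np.array([np.log(2.0), 0.0]), 1, 0.0, 0.0)
        assert iiv_weights(fit2, rows)[0] == pytest.approx(0.5)

    def test_not_at_risk_is_error(self, make_panel):
        spec = ModelSpec(("Z",), intercept=False)
        fit = RateFit(spec, np.array([0.1]), 1, 0.0, 0.0)
        rows = make_panel([{"id": 0, "time": 0.01, "at_risk": 0, "obs": 0}]).data
        with pytest.raises(InvalidArgumentError, match="at_risk"):
            iiv_weights(fit, rows)

    def test_null_observation_makes_dw_close_to_ipt(self, sc4_cohort_400):
        """Under uninformative observation the IIV weights are ~1 and the
        doubly weighted and IPT-only blip estimates nearly coincide."""
        from dwitr import DoublyWeightedITR

        rate = fit_proportional_rate(sc4_cohort_400, OBS_SPEC)
        rho = iiv_weights(rate, sc4_cohort_400.analysis_rows())
        assert np.allclose(rho, 1.0, atol=0.25)
        psi_dw = DoublyWeightedITR.from_preset(sc4_cohort_400, "DW1").fit().psi
        psi_ipt = DoublyWeightedITR.from_preset(sc4_cohort_400, "IPT").fit().psi
        np.testing.assert_allclose(psi_dw, psi_ipt, atol=0.1)

    def test_weighted_visit_covariate_balance(self):
        """In the rho-weighted person-time the association between the
        mediator and the visit indicator shrinks essentially to zero."""
        cfg = ScenarioConfig.preset("scenario1", 3000, seed=41)
        panel = simulate_cohort(cfg)
        df = panel.data
        rate = fit_proportional_rate(df, OBS_SPEC)
        rho = iiv_weights(rate, df)
        z = df["Z"].to_numpy(float)
        d = df["obs"].to_numpy(float)

        def slope(w):
            zb = np.average(z, weights=w)
            db = np.average(d, weights=w)
            return np.average((z - zb) * (d - db), weights=w) / np.average(
                (z - zb) ** 2, weights=w
            )

        raw = slope(np.ones_like(z))
        weighted = slope(rho)
        assert abs(raw) > 0.002
        assert abs(weighted) < 0.35 * abs(raw)
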