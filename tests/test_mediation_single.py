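"""Single-mediator closed-form mediation and delta-method inference."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mixmediate.mediation import (
    MediationFit,
    binary_mediator_transform,
    fit_total_effect,
    mediate,
)
from mixmediate.scenarios import generate_cohort, scenario_truth


def _manual_fit(th1, th2, th3, b0, b1, sigma2=1.0, link="identity"):
    """A MediationFit with hand-set coefficients and zero covariance."""
    theta_names = ["const", "black", "m", "black:m"]
    beta_names = ["const", "black"]
    params = np.array([0.0, th1, th2, th3, b0, b1])
    return MediationFit(
        effects=None,
        link=link,
        reference="white",
        sigma2=sigma2,
        theta_names=theta_names,
        beta_names=beta_names,
        params=params,
        cov=np.zeros((6, 6)),
        cbar={},
        contrast_groups=["black"],
    )


class TestClosedForms:
    def test_product_of_coefficients_identity(self):
        fit = _manual_fit(th1=-0.5, th2=-0.2, th3=0.0, b0=0.0, b1=0.5)
        z = fit.params
        assert fit._effect_fn("black", "nie")(z) == pytest.approx(-0.1)
        assert fit._effect_fn("black", "nde")(z) == pytest.approx(-0.5)
        assert fit._effect_fn("black", "te")(z) == pytest.approx(-0.6)
        assert fit._effect_fn("black", "pm")(z) == pytest.approx(100 / 6)

    def test_cde_with_interaction(self):
        fit = _manual_fit(th1=-0.5, th2=-0.2, th3=0.1, b0=0.0, b1=0.5)
        assert fit._effect_fn("black", "cde", 2.0)(fit.params) == pytest.approx(-0.3)

    def test_logit_nie_is_exp_of_product(self):
        fit = _manual_fit(th1=0.0, th2=0.2, th3=0.0, b0=0.0, b1=0.5, link="logit")
        log_nie = fit._effect_fn("black", "nie")(fit.params)
        assert math.exp(log_nie) == pytest.approx(math.exp(0.1))

    def test_logit_nde_uses_residual_variance(self):
        # with an interaction, log NDE picks up th3*(b0 + th2*s2) + 0.5*th3^2*s2
        th1, th2, th3, b0, s2 = -0.4, 0.2, 0.1, 0.3, 2.0
        fit = _manual_fit(th1, th2, th3, b0, 0.5, sigma2=s2, link="logit")
        expected = th1 + th3 * (b0 + th2 * s2) + 0.5 * th3**2 * s2
        assert fit._effect_fn("black", "nde")(fit.params) == pytest.approx(expected)

    def test_cde_linearity_in_level(self):
        fit = _manual_fit(th1=-0.23, th2=-0.07, th3=-0.07413, b0=0.0, b1=0.0)
        f = lambda m: fit._effect_fn("black", "cde", m)(fit.params)
        assert f(-0.6745) == pytest.approx(-0.18, abs=0.001)
        assert f(2.0) - f(1.0) == pytest.approx(-0.07413, abs=1e-12)

    @given(
        st.floats(-1, 1), st.floats(-1, 1), st.floats(-1, 1), st.floats(-1, 1)
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_additivity_invariant(self, th1, th2, th3, b1):
        fit = _manual_fit(th1, th2, th3, b0=0.2, b1=b1)
        z = fit.params
        te = fit._effect_fn("black", "te")(z)
        nde = fit._effect_fn("black", "nde")(z)
        nie = fit._effect_fn("black", "nie")(z)
        assert te == pytest.approx(nde + nie, abs=1e-10)


class TestTotalEffect:
    def test_exact_coefficient_two_groups(self):
        df = pd.DataFrame({"group": ["white"] * 5 + ["black"] * 5})
        df["y"] = (df["group"] == "black").astype(float)
        te = fit_total_effect(df, "y", link="identity")
        assert te.loc["black", "est"] == pytest.approx(1.0, abs=1e-10)

    def test_constant_outcome_rejected(self):
        df = pd.DataFrame({"group": ["white", "black"] * 4, "y": 1.0})
        with pytest.raises(ValueError, match="constant"):
            fit_total_effect(df, "y")

    def test_missing_reference_rejected(self):
        df = pd.DataFrame({"group": ["black"] * 6, "y": np.arange(6.0)})
        with pytest.raises(ValueError, match="reference"):
            fit_total_effect(df, "y")

    def test_complete_case_filtering(self, catalog):
        df = generate_cohort(catalog["S1"], 4000, seed=31)
        df.loc[:99, "cov_confounder"] = np.nan
        full = fit_total_effect(df, "ga_weeks", ["cov_confounder"])
        manual = fit_total_effect(df.dropna(), "ga_weeks", ["cov_confounder"])
        assert full.loc["black", "est"] == manual.loc["black", "est"]


class TestMediateOnCohorts:
    def test_s1_recovery(self, catalog, s1_cohort):
        fit = mediate(s1_cohort, "m", "ga_weeks", ["cov_confounder"])
        truth = scenario_truth(catalog["S1"])["black"]
        eff = fit.effects["black"]
        assert eff.te.est == pytest.approx(truth.te.est, abs=0.02)
        assert eff.nie.est == pytest.approx(truth.nie.est, abs=0.01)
        assert eff.pm.est == pytest.approx(truth.pm.est, abs=1.5)

    def test_s1b_interaction_cdes(self, catalog, s1b_cohort):
        fit = mediate(s1b_cohort, "m", "ga_weeks", ["cov_confounder"], interaction=True)
        eff = fit.effects["black"]
        assert eff.cdes["p50"].est == pytest.approx(-0.23, abs=0.02)
        assert eff.cdes["p25"].est == pytest.approx(-0.18, abs=0.02)
        med = float(np.median(s1b_cohort["m"]))
        assert fit.cde_at(med, "black").est == pytest.approx(eff.cdes["p50"].est, abs=1e-6)

    def test_cde_constant_without_interaction(self, s1_cohort):
        fit = mediate(s1_cohort, "m", "ga_weeks", ["cov_confounder"])
        eff = fit.effects["black"]
        vals = {v.est for v in eff.cdes.values()}
        assert max(vals) - min(vals) < 1e-10

    def test_nonfinite_cde_level_rejected(self, s1_cohort):
        fit = mediate(s1_cohort, "m", "ga_weeks", ["cov_confounder"])
        with pytest.raises(ValueError, match="finite"):
            fit.cde_at(float("nan"), "black")

    def test_logit_or_scale(self, catalog):
        df = generate_cohort(catalog["S1"], 60_000, seed=32)
        fit = mediate(df, "m", "ptb", ["cov_confounder"])
        assert fit.effects.scale == "OR"
        eff = fit.effects["black"]
        # odds-ratio multiplicativity
        assert math.log(eff.te.est) == pytest.approx(
            math.log(eff.nde.est) + math.log(eff.nie.est), abs=1e-10
        )

    def test_delta_ci_close_to_bootstrap(self, catalog):
        """Delta CI endpoints within 10% relative width of a percentile bootstrap."""
        df = generate_cohort(catalog["S1"], 5000, seed=33)
        fit = mediate(df, "m", "ga_weeks", ["cov_confounder"])
        nie = fit.effects["black"].nie
        rg = np.random.default_rng(34)
        reps = []
        for _ in range(1000):
            idx = rg.integers(0, len(df), len(df))
            bfit = mediate(df.iloc[idx], "m", "ga_weeks", ["cov_confounder"])
            reps.append(bfit.effects["black"].nie.est)
        blo, bhi = np.percentile(reps, [2.5, 97.5])
        width_d = nie.ci[1] - nie.ci[0]
        width_b = bhi - blo
        assert width_d == pytest.approx(width_b, rel=0.10)


class TestBinaryMediator:
    def test_median_split(self):
        np.testing.assert_array_equal(
            binary_mediator_transform([1, 2, 3, 4]), [0, 0, 1, 1]
        )

    def test_ties_go_high(self):
        got = binary_mediator_transform([1, 2, 2, 3])
        np.testing.assert_array_equal(got, [0, 1, 1, 1])

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            binary_mediator_transform([2, 2, 2])
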