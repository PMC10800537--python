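"""Multiple-mediator counterfactual imputation and the g-formula variant."""

import numpy as np
import pandas as pd
import pytest

from mixmediate.mediation import fit_total_effect, mediate
from mixmediate.multimediation import gformula_effects, mediate_joint
from mixmediate.scenarios import generate_cohort, scenario_truth

PBDE6 = ["pbde_28", "pbde_47", "pbde_99", "pbde_100", "pbde_153", "pbde_154"]


class TestMediateJoint:
    def test_vanishing_residual_variance_is_exact(self):
        """As mediator residual noise vanishes the imputation draws become
        degenerate and the joint NIE equals sum(t2j * b1j) from the fits."""
        rg = np.random.default_rng(41)
        n = 4000
        grp = np.where(rg.random(n) < 0.5, "black", "white")
        x = (grp == "black").astype(float)
        eps = 1e-3  # keeps the outcome design identifiable
        m1 = 0.5 * x + eps * rg.normal(size=n)
        m2 = -0.3 * x + eps * rg.normal(size=n)
        y = 1.0 + -0.4 * x + 0.2 * m1 + 0.5 * m2 + rg.normal(size=n)
        df = pd.DataFrame({"group": grp, "m1": m1, "m2": m2, "y": y})
        eff = mediate_joint(df, ["m1", "m2"], "y", mc_draws=5, n_boot=0, seed=42)
        import statsmodels.api as sm

        Xo = np.column_stack([np.ones(n), x, m1, m2])
        t2 = sm.OLS(y, Xo).fit().params[2:4]
        Xm = np.column_stack([np.ones(n), x])
        b1 = np.array([sm.OLS(m, Xm).fit().params[1] for m in (m1, m2)])
        assert eff["black"].nie.est == pytest.approx(float(t2 @ b1), abs=1e-4)

    def test_j1_reduces_to_closed_form(self, catalog):
        df = generate_cohort(catalog["S1"], 30_000, seed=43)
        joint = mediate_joint(
            df, ["m"], "ga_weeks", ["cov_confounder"], mc_draws=400, n_boot=0, seed=44
        )
        closed = mediate(df, "m", "ga_weeks", ["cov_confounder"])
        ce = closed.effects["black"]
        je = joint["black"]
        for a, b in ((je.nie, ce.nie), (je.nde, ce.nde), (je.te, ce.te)):
            assert a.est == pytest.approx(b.est, abs=3 * max(b.se, 1e-3))

    def test_s4_joint_pm_recovery(self, s4_cohort_small, catalog):
        eff = mediate_joint(
            s4_cohort_small, PBDE6, "ga_weeks", ["cov_confounder"],
            mc_draws=500, n_boot=0, seed=45, only_groups=["black"],
        )
        truth = scenario_truth(catalog["S4"])["black"]
        # n = 20k: looser MC band than the full-size recovery criterion
        assert eff["black"].pm.est == pytest.approx(truth.pm.est, abs=5.0)

    def test_mediator_order_invariance(self, s4_cohort_small):
        e1 = mediate_joint(
            s4_cohort_small, PBDE6, "ga_weeks", ["cov_confounder"],
            mc_draws=200, n_boot=0, seed=46, only_groups=["black"],
        )
        e2 = mediate_joint(
            s4_cohort_small, PBDE6[::-1], "ga_weeks", ["cov_confounder"],
            mc_draws=200, n_boot=0, seed=46, only_groups=["black"],
        )
        assert e1["black"].nie.est == pytest.approx(e2["black"].nie.est, abs=2e-3)
        assert e1["black"].nde.est == pytest.approx(e2["black"].nde.est, abs=2e-3)

    def test_te_agrees_with_regression_total_effect(self, s4_cohort_small):
        eff = mediate_joint(
            s4_cohort_small, PBDE6, "ga_weeks", ["cov_confounder"],
            mc_draws=500, n_boot=0, seed=47, only_groups=["black"],
        )
        te = fit_total_effect(s4_cohort_small, "ga_weeks", ["cov_confounder"])
        assert eff["black"].te.est == pytest.approx(
            te.loc["black", "est"], abs=3 * te.loc["black", "se"]
        )

    def test_bootstrap_ci_contains_point(self, catalog):
        df = generate_cohort(catalog["S4"], 3000, seed=48)
        eff = mediate_joint(
            df, PBDE6, "ga_weeks", ["cov_confounder"],
            mc_draws=100, n_boot=120, boot_mc_draws=40, seed=49, only_groups=["black"],
        )
        nie = eff["black"].nie
        assert nie.ci[0] < nie.est < nie.ci[1]

    def test_seed_and_draw_validation(self, s4_cohort_small):
        with pytest.raises(ValueError, match="seed"):
            mediate_joint(s4_cohort_small, PBDE6, "ga_weeks", mc_draws=10, n_boot=0)
        with pytest.raises(ValueError, match="mc_draws"):
            mediate_joint(s4_cohort_small, PBDE6, "ga_weeks", mc_draws=0, n_boot=0, seed=1)


class TestGFormula:
    def test_empty_l_matches_joint(self, catalog):
        df = generate_cohort(catalog["S1"], 30_000, seed=50)
        g = gformula_effects(
            df, ["m"], "ga_weeks", ["cov_confounder"], mc_draws=400, seed=51
        )
        closed = mediate(df, "m", "ga_weeks", ["cov_confounder"]).effects["black"]
        assert g["black"].nie.est == pytest.approx(closed.nie.est, abs=3 * closed.nie.se)

    def test_exposure_induced_confounder_shifts_te(self, catalog):
        # treating the group-shifted covariate as exposure-induced L moves the
        # total disparity toward the crude (unadjusted) contrast
        df = generate_cohort(catalog["S1"], 40_000, seed=52)
        g = gformula_effects(
            df, ["m"], "ga_weeks", post_exposure_confounders=["cov_confounder"],
            mc_draws=300, seed=53,
        )
        crude = fit_total_effect(df, "ga_weeks")
        assert g["black"].te.est == pytest.approx(
            crude.loc["black", "est"], abs=3 * crude.loc["black", "se"]
        )

    def test_rd_scale_with_planted_risks(self, catalog):
        df = generate_cohort(catalog["S2"], 150_000, seed=54)
        df["null_m"] = np.random.default_rng(55).normal(size=len(df))
        g = gformula_effects(
            df, ["null_m"], "ptb", scale="RD", mc_draws=100, seed=56
        )
        eff = g["black"]
        assert eff.te.est == pytest.approx(0.0891 - 0.051, abs=0.004)
        assert abs(eff.nie.est) < 0.003

    def test_zero_draws_rejected(self, catalog):
        df = generate_cohort(catalog["S1"], 1000, seed=57)
        with pytest.raises(ValueError, match="mc_draws"):
            gformula_effects(
                df, ["m"], "ga_weeks", post_exposure_confounders=["cov_confounder"],
                mc_draws=0, seed=58,
            )
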