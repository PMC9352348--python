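"""Trial-level mixed models: REML recovery, diagnostics, robustness, WT slopes."""

import numpy as np
import pandas as pd
import pytest

from astroca import mixed, synthetic
from astroca.config import CohortCoefficients, SimulationConfig


def cohort(seed=0, n_episodes=None, per_geno=5, trials=6, **coef_overrides):
    coeffs = CohortCoefficients(**coef_overrides)
    cfg = SimulationConfig(
        seed=seed, n_mice_per_genotype=per_geno, trials_per_mouse=trials, coeffs=coeffs
    )
    return synthetic.generate_cohort(cfg, n_episodes=n_episodes)


class TestZeroNoiseIdentifiability:
    def test_fixed_effects_recovered_exactly(self):
        table, truth = cohort(seed=1, sigma_mouse=0.0, sigma_resid_tg=0.0, sigma_resid_wt=0.0)
        fit = mixed.fit_pupil_model(table)
        c = truth.true_coeffs
        expected = {
            "intercept_tg": c.intercept_tg,
            "genotype_wt": c.beta_genotype_wt,
            "pupil_tg": c.beta_pupil_tg,
            "pupil_x_genotype_wt": c.beta_interaction_wt,
            "um_per_pixel": c.beta_umpp,
            "depth_um": c.beta_depth,
            "max_speed": c.beta_maxspeed,
        }
        for term, want in expected.items():
            assert fit.estimate(term) == pytest.approx(want, rel=1e-8, abs=1e-10)

    def test_zero_mouse_variance_estimated_near_zero(self):
        table, _ = cohort(seed=2, per_geno=6, trials=10, sigma_mouse=0.0,
                          sigma_resid_tg=0.1, sigma_resid_wt=0.1,
                          beta_pupil_tg=0.0, beta_interaction_wt=0.0)
        fit = mixed.fit_response_model(table)
        assert fit.sigma_mouse < 0.05


class TestAgainstStatsmodels:
    def test_homoscedastic_fit_matches_mixedlm(self):
        import statsmodels.formula.api as smf

        table, _ = cohort(seed=3, per_geno=6, trials=10, sigma_mouse=0.15)
        fit = mixed.fit_pupil_model(table)
        df = table.assign(
            wt=(table["genotype"] == "WT").astype(float),
            umpp_hi=(table["um_per_pixel"] == table["um_per_pixel"].max()).astype(float),
        )
        sm_fit = smf.mixedlm(
            "response ~ wt + pupil_dilation + pupil_dilation:wt + umpp_hi + depth_um + max_speed",
            data=df,
            groups=df["mouse"],
        ).fit(reml=True)
        pairs = {
            "intercept_tg": "Intercept",
            "genotype_wt": "wt",
            "pupil_tg": "pupil_dilation",
            "pupil_x_genotype_wt": "pupil_dilation:wt",
            "um_per_pixel": "umpp_hi",
            "depth_um": "depth_um",
            "max_speed": "max_speed",
        }
        row = fit.coefficients.set_index("term")
        for ours, theirs in pairs.items():
            assert row.loc[ours, "estimate"] == pytest.approx(sm_fit.params[theirs], rel=1e-4, abs=1e-8)
            # statsmodels derives fixed-effect SEs from the joint Hessian,
            # not the GLS formula, so ~1% differences are expected
            assert row.loc[ours, "se"] == pytest.approx(sm_fit.bse_fe[theirs], rel=2e-2, abs=1e-8)
        assert fit.sigma_mouse**2 == pytest.approx(
            float(sm_fit.cov_re.iloc[0, 0]), rel=5e-3, abs=1e-6
        )
        assert fit.sigma_resid["TG"] ** 2 == pytest.approx(sm_fit.scale, rel=5e-3)


class TestCoding:
    def test_genotype_label_swap_negates_genotype_coefficient(self):
        table, _ = cohort(seed=4, beta_pupil_tg=0.0, beta_interaction_wt=0.0)
        fit = mixed.fit_response_model(table)
        swapped = table.assign(genotype=table["genotype"].map({"WT": "TG", "TG": "WT"}))
        fit2 = mixed.fit_response_model(swapped)
        assert fit2.estimate("genotype_wt") == pytest.approx(-fit.estimate("genotype_wt"), rel=1e-4)

    def test_rank_deficiency_names_offending_terms(self):
        table, _ = cohort(seed=5)
        broken = table.assign(max_speed=0.0)
        with pytest.raises(ValueError, match="max_speed"):
            mixed.fit_response_model(broken)

    def test_missing_pupil_rows_dropped_with_warning(self):
        table, _ = cohort(seed=6)
        table.loc[table.index[:5], "pupil_dilation"] = np.nan
        with pytest.warns(UserWarning, match="missing pupil"):
            fit = mixed.fit_pupil_model(table)
        assert fit.n_obs == len(table) - 5

    def test_too_few_mice_rejected(self):
        table, _ = cohort(seed=7)
        sub = table[table["mouse"].isin(["TG0", "WT0", "WT1"])]
        with pytest.raises(ValueError, match="2 mice"):
            mixed.fit_response_model(sub)

    def test_no_multiplicity_adjustment_fields(self):
        table, _ = cohort(seed=8)
        fit = mixed.fit_response_model(table)
        adjusted = [c for c in fit.coefficients.columns if "adj" in c.lower() or "fdr" in c.lower()]
        assert adjusted == []
        assert not hasattr(fit, "p_adjusted")


class TestClusteredSE:
    def test_duplicating_rows_does_not_halve_clustered_se(self):
        # duplicating every observation doubles n but adds no new mice; with
        # random intercepts the genotype SE must shrink far less than sqrt(2)
        table, _ = cohort(seed=9, per_geno=4, trials=6, sigma_mouse=0.15,
                          sigma_resid_tg=0.05, sigma_resid_wt=0.05)
        fit = mixed.fit_response_model(table)
        doubled = pd.concat([table, table.assign(trial=table["trial"] + "b")], ignore_index=True)
        fit2 = mixed.fit_response_model(doubled)
        se1 = float(fit.coefficients.set_index("term").loc["genotype_wt", "se"])
        se2 = float(fit2.coefficients.set_index("term").loc["genotype_wt", "se"])
        assert se2 > se1 / np.sqrt(2) * 1.1


class TestWtSlope:
    @pytest.mark.parametrize(
        "tg_slope, interaction, printed",
        [
            (-0.3537, 1.1562, 0.80),
            (-0.0129, 0.9235, 0.91),
            (0.0030, 0.043, 0.046),
            (0.0078, 0.037, 0.045),
        ],
    )
    def test_printed_sums(self, tg_slope, interaction, printed):
        assert mixed.wt_slope_from_components(tg_slope, interaction) == pytest.approx(printed)

    def test_from_fit_and_missing_term(self):
        table, _ = cohort(seed=10, sigma_mouse=0.0, sigma_resid_tg=0.0, sigma_resid_wt=0.0)
        fit = mixed.fit_pupil_model(table)
        c = CohortCoefficients()
        assert mixed.wt_slope(fit) == mixed.wt_slope_from_components(
            c.beta_pupil_tg, c.beta_interaction_wt
        )
        plain = mixed.fit_response_model(table)
        with pytest.raises(ValueError, match="interaction"):
            mixed.wt_slope(plain)


class TestDiagnosticsAndHeteroscedasticity:
    def test_homoscedastic_data_does_not_trigger_refit(self):
        table, _ = cohort(seed=11, per_geno=6, trials=10,
                          sigma_resid_tg=0.1, sigma_resid_wt=0.1,
                          beta_pupil_tg=0.0, beta_interaction_wt=0.0)
        diag = mixed.residual_diagnostics(mixed.fit_response_model(table))
        assert diag.sd_ratio < 1.5
        assert not diag.refit_heteroscedastic

    def test_two_to_one_noise_triggers_and_het_fit_recovers(self):
        table, _ = cohort(seed=12, per_geno=6, trials=12,
                          sigma_resid_tg=0.05, sigma_resid_wt=0.10,
                          beta_pupil_tg=0.0, beta_interaction_wt=0.0)
        fit = mixed.fit_response_model(table)
        diag = mixed.residual_diagnostics(fit)
        assert diag.refit_heteroscedastic
        het = mixed.fit_response_model(
            table, mixed.ModelSpec(residual_variance_by_genotype=True)
        )
        assert het.sigma_resid["WT"] / het.sigma_resid["TG"] > 1.4
        assert het.sigma_resid["TG"] == pytest.approx(0.05, rel=0.4)
        assert het.sigma_resid["WT"] == pytest.approx(0.10, rel=0.4)

    def test_residuals_center_near_zero(self):
        table, _ = cohort(seed=13, beta_pupil_tg=0.0, beta_interaction_wt=0.0)
        fit = mixed.fit_response_model(table)
        assert abs(fit.residuals.mean()) < 0.02


class TestRobustness:
    def test_homogeneous_cohort_is_stable(self):
        table, _ = cohort(seed=14, per_geno=5, trials=8)
        spec = mixed.ModelSpec(include_pupil=True)
        full = mixed.fit_pupil_model(table, spec)
        est = full.estimate("pupil_x_genotype_wt")
        se = float(full.coefficients.set_index("term").loc["pupil_x_genotype_wt", "se"])
        out = mixed.robustness_check(table, spec, "leave_one_mouse_out")
        focal = out[out["term"] == "pupil_x_genotype_wt"]
        assert len(focal) == table["mouse"].nunique()
        assert np.all(np.abs(focal["estimate"] - est) < 2 * se)

    def test_outlier_mouse_dominates_deletion_shift(self):
        table, _ = cohort(seed=15, per_geno=5, trials=8,
                          beta_pupil_tg=0.0, beta_interaction_wt=0.0)
        table = table.copy()
        outlier = table["mouse"] == "WT0"
        table.loc[outlier, "response"] += 5.0
        spec = mixed.ModelSpec()
        full = mixed.fit_response_model(table, spec)
        out = mixed.robustness_check(table, spec, "leave_one_mouse_out")
        focal = out[out["term"] == "genotype_wt"].set_index("left_out")
        shifts = (focal["estimate"] - full.estimate("genotype_wt")).abs()
        assert shifts.idxmax() == "WT0"

    def test_deletions_that_break_identifiability_are_skipped(self):
        table, _ = cohort(seed=16, per_geno=2, trials=8)
        with pytest.warns(UserWarning, match="skip"):
            out = mixed.robustness_check(table, mixed.ModelSpec(), "leave_one_mouse_out")
        assert out.empty  # every deletion leaves one genotype with 1 mouse

    def test_leave_one_trial_out_bookkeeping(self):
        table, _ = cohort(seed=17, per_geno=3, trials=4)
        out = mixed.robustness_check(table, mixed.ModelSpec(), "leave_one_trial_out")
        n_terms = 5  # intercept, genotype, umpp, depth, speed
        assert len(out) == len(table) * n_terms


def test_round_sig_reporting_convention():
    assert mixed.round_sig(0.8025) == 0.80
    assert mixed.round_sig(0.9106) == 0.91
    assert mixed.round_sig(0.0448) == 0.045
    assert mixed.round_sig(-123.4) == -120.0
    assert mixed.round_sig(0.0) == 0.0
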