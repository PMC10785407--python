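"""QC, genetic-model encodings, 2x2 estimation and logistic regression."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nihlkit.association import (
    DEFAULT_MODELS,
    GeneticModel,
    adjust_pvalues,
    call_rate,
    chi_square_2x2,
    contingency_2x2,
    encode_genetic_model,
    fit_logistic,
    hwe_test,
    odds_ratio_woolf,
    qc_filter,
    snp_association,
    two_stage_screen,
)
from nihlkit.cohort import ContingencyTable2x2
from nihlkit.simulate import (
    EffectSpec,
    SimulationConfig,
    default_panel,
    simulate_case_control,
    simulate_genotypes,
)

from conftest import make_cohort


class TestHwe:
    @pytest.mark.parametrize("counts,chi2,p", [
        ((25, 50, 25), 0.0, 1.0),                 # exact HWE proportions
        ((30, 40, 30), 4.0, 0.0455),              # expected (25,50,25)
        ((50, 0, 50), 100.0, 0.0),                # complete heterozygote deficit
    ])
    def test_known_tables(self, counts, chi2, p):
        res = hwe_test(*counts)
        assert res.chi2 == pytest.approx(chi2, abs=1e-9)
        if p > 0:
            assert res.p == pytest.approx(p, abs=2e-4)
        else:
            assert res.p < 1e-20

    def test_monomorphic_flagged(self):
        res = hwe_test(100, 0, 0)
        assert res.monomorphic and res.chi2 == 0.0 and res.p == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hwe_test(0, 0, 0)

    def test_type_one_error_calibrated(self, rng):
        """At alpha=0.01, ~1% of HWE-true SNPs (n=252 controls) are rejected."""
        n_reps, n = 5000, 252
        rejections = 0
        for _ in range(n_reps):
            calls = simulate_genotypes(0.3, 0.0, n, rng)
            nAA = int((calls == "AA").sum())
            nAB = int((calls == "AB").sum())
            rejections += hwe_test(nAA, nAB, n - nAA - nAB).p < 0.01
        assert rejections / n_reps == pytest.approx(0.01, abs=0.005)


class TestEncoding:
    @pytest.mark.parametrize("call,model,expect", [
        ("BB", GeneticModel.RECESSIVE, "exposed"),
        ("AB", GeneticModel.RECESSIVE, "unexposed"),
        ("AB", GeneticModel.DOMINANT, "exposed"),
        ("AA", GeneticModel.DOMINANT, "unexposed"),
        ("AB", GeneticModel.SUPER_DOMINANT, "exposed"),
        ("BB", GeneticModel.SUPER_DOMINANT, "unexposed"),
        ("AB", GeneticModel.HOMOZYGOTE, "excluded"),
        ("BB", GeneticModel.HOMOZYGOTE, "exposed"),
        ("AB", GeneticModel.ADDITIVE, 1),
        ("BB", GeneticModel.ADDITIVE, 2),
    ])
    def test_model_rules(self, call, model, expect):
        assert encode_genetic_model(call, model) == expect

    def test_missing_is_error(self):
        with pytest.raises(ValueError):
            encode_genetic_model("MISSING", GeneticModel.RECESSIVE)


class TestContingency:
    def test_recessive_extreme(self):
        cohort = make_cohort([["BB"]] * 10 + [["AA"]] * 10,
                             ["case"] * 10 + ["control"] * 10)
        t = contingency_2x2(cohort, "rs1", GeneticModel.RECESSIVE)
        assert (t.a, t.b, t.c, t.d) == (10, 0, 0, 10)

    def test_allele_model_counts_two_alleles_per_subject(self):
        cohort = make_cohort([["AB"], ["AA"]], ["case", "control"])
        t = contingency_2x2(cohort, "rs1", GeneticModel.ALLELE)
        assert (t.a, t.b, t.c, t.d) == (1, 0, 1, 2)

    def test_homozygote_drops_heterozygotes(self):
        cohort = make_cohort([["AA"], ["AB"], ["BB"], ["AB"]],
                             ["case", "case", "control", "control"])
        t = contingency_2x2(cohort, "rs1", GeneticModel.HOMOZYGOTE)
        assert t.n == 2

    def test_allele_total_is_twice_genotype_total(self, balanced_cohort):
        t_geno = contingency_2x2(balanced_cohort, "rs1", GeneticModel.RECESSIVE)
        t_alle = contingency_2x2(balanced_cohort, "rs1", GeneticModel.ALLELE)
        assert t_alle.n == 2 * t_geno.n


class TestOddsRatio:
    @pytest.mark.parametrize("cells,expect", [
        ((105, 112, 48, 140), 2.734),   # high vs low genetic risk score
        ((9, 3, 26, 87), 10.038),       # highest-risk tree node vs reference
        ((1, 1, 1, 1), 1.0),
    ])
    def test_cross_product_values(self, cells, expect):
        assert odds_ratio_woolf(ContingencyTable2x2(*cells)).value == pytest.approx(
            expect, abs=1e-3)

    def test_ci_symmetric_on_log_scale_at_null(self):
        r = odds_ratio_woolf(ContingencyTable2x2(5, 5, 5, 5))
        assert math.log(r.ci_low) == pytest.approx(-math.log(r.ci_high))

    def test_zero_cell_continuity_correction_flagged(self):
        r = odds_ratio_woolf(ContingencyTable2x2(10, 0, 0, 10))
        assert r.continuity_corrected and r.value > 1

    def test_no_cases_is_error(self):
        with pytest.raises(ValueError):
            odds_ratio_woolf(ContingencyTable2x2(0, 5, 0, 5))

    @given(a=st.integers(1, 50), b=st.integers(1, 50),
           c=st.integers(1, 50), d=st.integers(1, 50))
    def test_reciprocal_symmetry(self, a, b, c, d):
        t = ContingencyTable2x2(a, b, c, d)
        r = odds_ratio_woolf(t)
        s = odds_ratio_woolf(t.swapped())
        assert s.value == pytest.approx(1 / r.value)
        assert s.ci_low == pytest.approx(1 / r.ci_high)
        assert s.ci_high == pytest.approx(1 / r.ci_low)
        assert s.p == pytest.approx(r.p)


class TestChiSquare2x2:
    def test_values(self):
        chi2, p = chi_square_2x2(ContingencyTable2x2(10, 10, 10, 10))
        assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)
        chi2, _ = chi_square_2x2(ContingencyTable2x2(20, 10, 10, 20))
        assert chi2 == pytest.approx(6.667, abs=1e-3)


class TestQcFilter:
    def _cohort(self, case_calls, control_calls, snp="rs1"):
        calls = case_calls + control_calls
        return make_cohort([[c] for c in calls],
                           ["case"] * len(case_calls) + ["control"] * len(control_calls),
                           snp_ids=(snp,))

    def test_low_call_rate_excluded(self):
        control_calls = ["AA"] * 5 + ["AB"] * 10 + ["BB"] * 5
        case_calls = [np.nan] * 3 + ["AA"] * 2  # overall call rate 22/25 = 0.88
        cohort = self._cohort(case_calls, control_calls)
        report = qc_filter(cohort)
        assert report.excluded == ["rs1"]
        assert "call_rate" in report.reason("rs1")

    def test_hwe_consistent_controls_kept(self):
        cohort = self._cohort(["AA"] * 4, ["AA"] * 25 + ["AB"] * 50 + ["BB"] * 25)
        report = qc_filter(cohort)
        assert report.kept == ["rs1"]

    def test_hwe_violation_in_controls_excluded(self):
        # no heterozygotes at all: gross HWE departure
        cohort = self._cohort(["AA"] * 4, ["AA"] * 50 + ["BB"] * 50)
        report = qc_filter(cohort)
        assert report.excluded == ["rs1"]
        assert "hwe" in report.reason("rs1")

    def test_hwe_power_against_strong_inbreeding(self, rng):
        """f=0.5 departures in 500 controls are excluded essentially always."""
        excluded = 0
        reps = 200
        for _ in range(reps):
            calls = simulate_genotypes(0.3, 0.5, 500, rng)
            cohort = make_cohort([[c] for c in calls], ["control"] * 500)
            excluded += qc_filter(cohort).excluded == ["rs1"]
        assert excluded / reps >= 0.99

    def test_no_controls_is_error(self):
        cohort = make_cohort([["AA"], ["AB"]], ["case", "case"])
        with pytest.raises(ValueError):
            qc_filter(cohort)


class TestLogistic:
    def test_unadjusted_fit_equals_cross_product_or(self, balanced_cohort):
        t = contingency_2x2(balanced_cohort, "rs1", GeneticModel.DOMINANT)
        crude = odds_ratio_woolf(t)
        exposure = np.r_[np.ones(t.a), np.zeros(t.c), np.ones(t.b), np.zeros(t.d)]
        y = np.r_[np.ones(t.a + t.c), np.zeros(t.b + t.d)]
        fit = fit_logistic(y, pd.DataFrame({"x": exposure}))
        assert math.exp(fit.params["x"]) == pytest.approx(crude.value, abs=1e-6)

    def test_matches_statsmodels_oracle(self, rng):
        import statsmodels.api as sm

        n = 500
        x1 = rng.standard_normal(n)
        x2 = rng.random(n) < 0.4
        eta = -0.5 + 0.8 * x1 + 0.6 * x2
        y = rng.random(n) < 1 / (1 + np.exp(-eta))
        X = pd.DataFrame({"x1": x1, "x2": x2.astype(float)})
        fit = fit_logistic(y.astype(float), X)
        sm_fit = sm.Logit(y.astype(float), sm.add_constant(X)).fit(disp=0)
        assert np.allclose(fit.params.to_numpy(), sm_fit.params.to_numpy(), atol=1e-6)
        assert np.allclose(fit.bse.to_numpy(), sm_fit.bse.to_numpy(), atol=1e-5)

    def test_rank_deficient_design_rejected(self):
        y = np.array([0, 1, 0, 1, 0, 1], dtype=float)
        X = pd.DataFrame({"z": np.zeros(6)})
        with pytest.raises(ValueError, match="rank"):
            fit_logistic(y, X)

    def test_perfect_separation_flagged_not_raised(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        y = x.copy()
        fit = fit_logistic(y, pd.DataFrame({"x": x}))
        assert fit.separated and not fit.converged

    def test_parameter_recovery_on_synthetic_cohort(self):
        panel = default_panel(1, seed=3)
        panel["maf"] = 0.35
        true = 0.9
        cfg = SimulationConfig(
            n_cases=2000, n_controls=2000, panel=panel, intercept=-1.0,
            effects=(EffectSpec(panel.index[0], GeneticModel.DOMINANT, true),),
            seed=77)
        cohort = simulate_case_control(cfg)
        r = snp_association(cohort, panel.index[0], GeneticModel.DOMINANT,
                            adjust_for=("age", "smoking"))
        ln_or = math.log(r.or_adjusted.value)
        se = (math.log(r.or_adjusted.ci_high) - math.log(r.or_adjusted.value)) / 1.96
        assert abs(ln_or - true) < 3 * se


class TestAdjustPvalues:
    def test_bonferroni_and_bh(self):
        p = [0.01, 0.02, 0.04]
        assert np.allclose(adjust_pvalues(p, "bonferroni"), [0.03, 0.06, 0.12])
        assert np.allclose(adjust_pvalues(p, "bh"), [0.03, 0.03, 0.04])
        assert np.allclose(adjust_pvalues(p, "none"), p)


class TestSnpAssociation:
    def test_no_covariates_matches_crude(self, balanced_cohort):
        r = snp_association(balanced_cohort, "rs1", GeneticModel.DOMINANT, adjust_for=())
        assert r.or_adjusted.value == pytest.approx(r.or_crude.value, abs=1e-6)

    def test_tier_assignment(self, balanced_cohort):
        r = snp_association(balanced_cohort, "rs1", GeneticModel.DOMINANT, adjust_for=())
        assert r.tier in ("significant", "marginal", "null")
        assert (r.tier == "significant") == (r.p_crude < 0.05)

    def test_report_row_reproduces_own_or(self, balanced_cohort):
        for model in (GeneticModel.RECESSIVE, GeneticModel.DOMINANT, GeneticModel.ALLELE):
            r = snp_association(balanced_cohort, "rs1", model, adjust_for=())
            recomputed = odds_ratio_woolf(r.table)
            assert recomputed.value == pytest.approx(r.or_crude.value)


class TestTwoStageScreen:
    def _pair(self, seed=5, n=60):
        from nihlkit.simulate import generate_two_stage_study, two_stage_configs
        cfg_s, cfg_r = two_stage_configs(seed, n_screen=(60, 60), n_replicate=(100, 150))
        return generate_two_stage_study(cfg_s, cfg_r)

    def test_alpha_one_passes_everything(self):
        s, r = self._pair()
        res = two_stage_screen(s, r, alpha=1.0, alpha_marginal=1.0,
                               snp_ids=s.snp_ids[:8])
        assert res.candidates == s.snp_ids[:8]
        assert res.validated == s.snp_ids[:8]

    def test_idempotent_on_identical_cohorts(self):
        s, _ = self._pair()
        res1 = two_stage_screen(s, s, snp_ids=s.snp_ids[:10])
        res2 = two_stage_screen(s, s, snp_ids=s.snp_ids[:10])
        assert res1.validated == res2.validated
        # stage-2 keeps a subset of stage-1 candidates by construction
        assert set(res1.validated) <= set(res1.candidates)

    def test_mismatched_panels_rejected(self):
        s, r = self._pair()
        r2 = r.subset(r.subjects.index)
        r2.panel = r2.panel.iloc[::-1]
        with pytest.raises(ValueError, match="panel"):
            two_stage_screen(s, r2)
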