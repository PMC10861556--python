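import numpy as np
import pandas as pd
import pytest
from scipy import integrate, special, stats

from wfmr import (
    DiseaseScenario,
    ValidationError,
    assign_birthweight,
    assign_disease,
    calibrate_intercept,
    compute_scores,
    fit_logistic,
    sample_pgs_pairs,
    simulate_families,
    simulate_panel,
)
from wfmr.family_sim import simulate_covariates


class TestSimulatePanel:
    def test_class_constraints_and_mix(self):
        panel = simulate_panel(213, seed=1)
        counts = panel.class_counts()
        assert counts == {"M_ONLY": 32, "F_ONLY": 68, "SHARED_CONC": 27, "SHARED_OPP": 15, "UNCLASSIFIED": 71}
        t = panel.table
        assert (t.loc[t.effect_class == "M_ONLY", "w_fetal"] == 0).all()
        assert (t.loc[t.effect_class == "F_ONLY", "w_maternal"] == 0).all()
        assert (t.loc[t.effect_class == "SHARED_OPP", "w_fetal"] < 0).all()

    def test_all_maternal_mix(self):
        panel = simulate_panel(29, class_mix={"M_ONLY": 1.0}, seed=2)
        assert (panel.table["w_fetal"] == 0).all()
        assert (panel.table["effect_class"] == "M_ONLY").all()

    def test_effect_scale_zero_gives_zero_weights(self):
        panel = simulate_panel(10, effect_scale=0.0, seed=3)
        assert (panel.table[["w_maternal", "w_fetal"]] == 0).all().all()

    def test_variance_normalisation(self):
        panel = simulate_panel(50, effect_scale=2.0, seed=4)
        t = panel.table
        het = 2 * t.eaf * (1 - t.eaf)
        assert np.sum(het * t.w_maternal**2) == pytest.approx(2.0)
        assert np.sum(het * t.w_fetal**2) == pytest.approx(2.0)

    def test_seed_determinism(self):
        a = simulate_panel(20, seed=7).table
        b = simulate_panel(20, seed=7).table
        pd.testing.assert_frame_equal(a, b)

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValidationError):
            simulate_panel(0)
        with pytest.raises(ValidationError):
            simulate_panel(10, maf_low=0.3, maf_high=0.2)
        with pytest.raises(ValidationError):
            simulate_panel(10, class_mix={"M_ONLY": -0.5, "F_ONLY": 1.5})


class TestTransmission:
    def test_forced_transmission_cases(self, demo_panel, trio_cohort):
        """Homozygous parents fully determine the transmitted allele."""
        mat = trio_cohort.dosages.matrix
        kids = trio_cohort.of_role("CHILD")
        m = mat.loc[kids["mother_id"]].to_numpy()
        f = mat.loc[kids["father_id"]].to_numpy()
        c = mat.loc[kids["individual_id"]].to_numpy()
        assert (c[(m == 2) & (f == 2)] == 2).all()
        assert (c[(m == 0) & (f == 0)] == 0).all()
        assert (c[(m == 2) & (f == 0)] == 1).all()
        # Mendelian attainability everywhere: child within reach of parents
        low = (m == 2).astype(int) + (f == 2).astype(int)
        high = 2 - (m == 0).astype(int) - (f == 0).astype(int)
        assert ((c >= low) & (c <= high)).all()

    def test_heterozygous_parent_transmits_half_the_time(self, trio_cohort):
        mat = trio_cohort.dosages.matrix
        kids = trio_cohort.of_role("CHILD")
        m = mat.loc[kids["mother_id"]].to_numpy()
        f = mat.loc[kids["father_id"]].to_numpy()
        c = mat.loc[kids["individual_id"]].to_numpy()
        # with father homozygous ref, child dosage == maternal transmitted allele
        sel = (m == 1) & (f == 0)
        rate = c[sel].mean()
        n = sel.sum()
        assert abs(rate - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_parent_offspring_score_correlation_half(self):
        panel = simulate_panel(100, seed=21)
        cohort = simulate_families(panel, 4000, seed=22)
        raw = cohort.dosages.matrix.sum(axis=1)  # unweighted allele count over all SNPs
        kids = cohort.of_role("CHILD")
        r_mc = np.corrcoef(raw.loc[kids["mother_id"]], raw.loc[kids["individual_id"]])[0, 1]
        r_fc = np.corrcoef(raw.loc[kids["father_id"]], raw.loc[kids["individual_id"]])[0, 1]
        r_mf = np.corrcoef(raw.loc[kids["mother_id"]], raw.loc[kids["father_id"]])[0, 1]
        assert abs(r_mc - 0.5) < 0.03
        assert abs(r_fc - 0.5) < 0.03
        assert abs(r_mf) < 0.05  # random mating

    def test_sibling_score_correlation_half(self, trio_cohort):
        raw = trio_cohort.dosages.matrix.sum(axis=1)
        duos = trio_cohort.sibling_duos()
        r = np.corrcoef(raw.loc[duos["sib1"]], raw.loc[duos["sib2"]])[0, 1]
        assert abs(r - 0.5) < 0.06

    def test_assortative_mating_knob(self):
        panel = simulate_panel(80, seed=30)
        cohort = simulate_families(panel, 3000, seed=31, parent_pgs_corr=0.4)
        w = panel.table["w_maternal"].to_numpy() + panel.table["w_fetal"].to_numpy()
        mat = cohort.dosages.matrix
        kids = cohort.of_role("CHILD")
        s_m = mat.loc[kids["mother_id"]].to_numpy() @ w
        s_f = mat.loc[kids["father_id"]].to_numpy() @ w
        assert np.corrcoef(s_m, s_f)[0, 1] == pytest.approx(0.4, abs=0.08)

    def test_cohort_structure_and_determinism(self, demo_panel):
        a = simulate_families(demo_panel, 50, seed=5, n_children=2)
        b = simulate_families(demo_panel, 50, seed=5, n_children=2)
        pd.testing.assert_frame_equal(a.individuals, b.individuals)
        pd.testing.assert_frame_equal(a.dosages.matrix, b.dosages.matrix)
        assert (a.of_role("CHILD")["age"] >= 18).all()
        with pytest.raises(ValidationError):
            simulate_families(demo_panel, 0)


class TestBirthweight:
    def test_zero_heritability_gives_pure_noise(self, m_only_panel):
        cohort = simulate_families(m_only_panel, 3000, seed=40)
        pheno = assign_birthweight(cohort, m_only_panel, h2_maternal=0.0, h2_fetal=0.0, seed=41)
        kids = cohort.of_role("CHILD")
        bw = pheno.table.loc[kids["individual_id"], "birth_weight"].to_numpy()
        g_m = cohort.dosages.matrix.loc[kids["mother_id"]].to_numpy() @ m_only_panel.table["w_maternal"].to_numpy()
        slope = np.polyfit((g_m - g_m.mean()) / g_m.std(), bw, 1)[0]
        assert abs(slope) < 3 * 500 / np.sqrt(len(bw))

    def test_maternal_slope_matches_variance_target(self, m_only_panel):
        """With h2_maternal = 0.05, the regression of birth weight on the
        standardized maternal genetic value has slope sd_g * sqrt(0.05)."""
        cohort = simulate_families(m_only_panel, 20000, seed=42)
        pheno = assign_birthweight(cohort, m_only_panel, h2_maternal=0.05, h2_fetal=0.0, seed=43)
        kids = cohort.of_role("CHILD")
        bw = pheno.table.loc[kids["individual_id"], "birth_weight"].to_numpy()
        g_m = cohort.dosages.matrix.loc[kids["mother_id"]].to_numpy() @ m_only_panel.table["w_maternal"].to_numpy()
        z = (g_m - g_m.mean()) / g_m.std()
        slope = np.polyfit(z, bw, 1)[0]
        expected = 500.0 * np.sqrt(0.05)  # 111.8 g per SD of maternal genetic value
        se = 500.0 * np.sqrt(0.95) / np.sqrt(len(bw))
        assert abs(slope - expected) < 3 * se
        assert np.nanstd(pheno.table["birth_weight"]) == pytest.approx(500.0, rel=0.03)

    def test_reproducible_and_validated(self, m_only_panel, trio_cohort):
        cohort = simulate_families(m_only_panel, 100, seed=44)
        a = assign_birthweight(cohort, m_only_panel, h2_fetal=0.0, seed=45).table
        b = assign_birthweight(cohort, m_only_panel, h2_fetal=0.0, seed=45).table
        pd.testing.assert_frame_equal(a, b)
        with pytest.raises(ValidationError):
            assign_birthweight(cohort, m_only_panel, h2_maternal=-0.1)
        with pytest.raises(ValidationError):
            assign_birthweight(cohort, m_only_panel, h2_maternal=0.6, h2_fetal=0.5)


class TestDisease:
    def test_null_intercept_is_logit_prevalence(self):
        assert calibrate_intercept(0.167) == pytest.approx(special.logit(0.167), abs=1e-12)

    def test_calibration_matches_numerical_integration(self):
        """alpha from Gauss-Hermite calibration reproduces the target mean risk
        under independent numerical integration of the logistic over the normal."""
        alpha = calibrate_intercept(0.0275, beta_mother=0.0, beta_child=0.3, rho=0.5)
        mean_risk, _ = integrate.quad(
            lambda z: special.expit(alpha + 0.3 * z) * stats.norm.pdf(z), -10, 10
        )
        assert mean_risk == pytest.approx(0.0275, abs=1e-3)

    def test_logor_definition(self):
        # one SD higher child PGS multiplies the odds by exp(beta)
        alpha = calibrate_intercept(0.1, beta_child=np.log(2.0))
        odds = lambda p: p / (1 - p)
        r1 = special.expit(alpha + np.log(2.0))
        r0 = special.expit(alpha)
        assert odds(r1) / odds(r0) == pytest.approx(2.0, abs=1e-12)

    def test_realized_prevalence_null_scenario(self, demo_panel):
        cohort = simulate_families(demo_panel, 6000, seed=50)
        pheno = assign_birthweight(cohort, demo_panel, seed=51)
        scores = compute_scores(cohort.dosages, demo_panel).values
        scen = DiseaseScenario(0.0, 0.0, 0.167)
        pheno = assign_disease(cohort, pheno, scen, scores, "M-SPECIFIC", seed=52)
        prev = pheno.table["disease"].mean()
        assert abs(prev - 0.167) < 3 * np.sqrt(0.167 * 0.833 / 6000)

    def test_prevalence_calibration_across_seeds(self, demo_panel):
        cohort = simulate_families(demo_panel, 5000, seed=53)
        pheno = assign_birthweight(cohort, demo_panel, seed=54)
        scores = compute_scores(cohort.dosages, demo_panel).values
        scen = DiseaseScenario(0.2, 0.1, 0.1)
        tol = 3 * np.sqrt(0.1 * 0.9 / 5000)
        misses = 0
        for s in range(30):
            p = assign_disease(cohort, pheno, scen, scores, "M-SPECIFIC", seed=s).table["disease"].mean()
            misses += abs(p - 0.1) > tol
        assert misses <= 4  # ~95% of seeds inside the 3-SE band

    def test_via_birthweight_routes_maternal_effect_through_bw(self, m_only_panel):
        """Under the intrauterine mediation mode, disease depends on birth weight,
        so a cohort whose birth weight is pure noise shows no maternal-PGS effect."""
        cohort = simulate_families(m_only_panel, 8000, seed=55)
        pheno = assign_birthweight(cohort, m_only_panel, h2_maternal=0.0, h2_fetal=0.0, seed=56)
        scores = compute_scores(cohort.dosages, m_only_panel).values
        scen = DiseaseScenario(0.5, 0.0, 0.2, mediation="via_birthweight")
        pheno = assign_disease(cohort, pheno, scen, scores, "M-SPECIFIC", seed=57)
        kids = cohort.of_role("CHILD")
        y = pheno.table.loc[kids["individual_id"], "disease"].to_numpy()
        x = scores.loc[kids["mother_id"], "M-SPECIFIC"].to_numpy()
        fit = fit_logistic(y, x[:, None])
        assert abs(fit.params.iloc[1]) < 3 * fit.se.iloc[1]
        # but birth weight itself drives risk
        bw = pheno.table.loc[kids["individual_id"], "birth_weight"].to_numpy()
        fit_bw = fit_logistic(y, ((bw - bw.mean()) / bw.std())[:, None])
        assert fit_bw.params.iloc[1] == pytest.approx(0.5, abs=3 * fit_bw.se.iloc[1])

    def test_invalid_scenarios_rejected(self):
        with pytest.raises(ValidationError):
            DiseaseScenario(0, 0, 0.0)
        with pytest.raises(ValidationError):
            DiseaseScenario(0, 0, 1.0)
        with pytest.raises(ValidationError):
            DiseaseScenario(0, 0, 0.5, mediation="telepathy")


class TestPGSPairs:
    def test_stated_moments(self):
        pairs = sample_pgs_pairs(36211, rho=0.5, seed=60)
        assert np.corrcoef(pairs.mother, pairs.child)[0, 1] == pytest.approx(0.5, abs=0.01)
        for v in (pairs.mother, pairs.child):
            assert abs(v.mean()) < 0.02
            assert abs(v.std() - 1.0) < 0.02

    def test_independent_margins_at_rho_zero(self):
        pairs = sample_pgs_pairs(50000, rho=0.0, seed=61)
        assert abs(np.corrcoef(pairs.mother, pairs.child)[0, 1]) < 0.015

    def test_near_collinear_pair_inflates_joint_se(self):
        """At rho = 0.99 the joint fit still converges; the SE of each term is
        inflated by ~1/sqrt(1 - rho^2) relative to the single-score model."""
        rho = 0.99
        pairs = sample_pgs_pairs(100_000, rho=rho, seed=62)
        rng = np.random.default_rng(63)
        alpha = calibrate_intercept(0.2, beta_child=0.2, rho=rho)
        y = (rng.random(pairs.n) < special.expit(alpha + 0.2 * pairs.child)).astype(float)
        joint = fit_logistic(y, np.column_stack([pairs.mother, pairs.child]))
        single = fit_logistic(y, pairs.mother[:, None])
        inflation = joint.se.iloc[1] / single.se.iloc[1]
        assert inflation == pytest.approx(1 / np.sqrt(1 - rho**2), rel=0.15)

    def test_parameter_validation(self):
        with pytest.raises(ValidationError):
            sample_pgs_pairs(0)
        with pytest.raises(ValidationError):
            sample_pgs_pairs(10, rho=1.0)


def test_simulated_covariates_shape():
    cov = simulate_covariates(["a", "b", "c"], seed=1, n_pcs=10, n_batches=4)
    assert cov.shape == (3, 13)
    assert {f"PC{i}" for i in range(1, 11)} <= set(cov.columns)
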