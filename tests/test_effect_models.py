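"""Regression battery: d/t conversion, batteries, global adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dtimega import (
    METRICS,
    ROI_OUTCOMES,
    cohens_d_from_t,
    derive_periphery,
    generate_cohort,
    run_case_control_battery,
    run_clinical_associations,
    run_global_adjusted_battery,
    run_interaction_models,
    run_stratified_battery,
    run_subgroup_battery,
    t_from_cohens_d,
)
from dtimega.effect_models import DesignSpec, ModelError, fit_roi_model
from dtimega.rois import V_CORE, V_PERIPHERY, V_TOTAL
from dtimega.synthetic_cohort import with_injected_effect, _default_effect_matrix

from conftest import make_config


class TestCohensD:
    def test_matches_classical_two_sample_d(self):
        """Covariate-free two-group fit reproduces (m1-m2)/pooled SD."""
        rng = np.random.default_rng(8)
        n = 200
        ctr = rng.normal(0.5, 1.0, n)
        case = rng.normal(0.0, 1.0, n)
        pooled = np.sqrt(((n - 1) * ctr.var(ddof=1) + (n - 1) * case.var(ddof=1))
                         / (2 * n - 2))
        d_classical = (ctr.mean() - case.mean()) / pooled
        data = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(2 * n)],
            "diagnosis": ["CTR"] * n + ["EOP"] * n,
            "subgroup": ["CTR"] * n + ["EOS"] * n,
            "sex": ["F"] * (2 * n), "age": 15.0,
            "value": np.concatenate([ctr, case]),
        })
        res = fit_roi_model(data, "SLF", "FA", DesignSpec(covariates=()))
        assert res["d"] == pytest.approx(d_classical, rel=0.01)

    def test_zero_t_gives_zero_d(self):
        d, se = cohens_d_from_t(0.0, 100, 100, 198)
        assert d == 0.0
        assert se == pytest.approx(np.sqrt(2 / 100))

    @given(st.floats(-5, 5), st.integers(10, 400), st.integers(10, 400))
    @settings(max_examples=50, deadline=None)
    def test_t_d_inverse_consistency(self, t, n1, n2):
        df = n1 + n2 - 7
        d, _ = cohens_d_from_t(t, n1, n2, df)
        assert t_from_cohens_d(d, n1, n2, df) == pytest.approx(t, abs=1e-10)


class TestCaseControlBattery:
    def test_one_row_per_roi_and_metric(self, study_cohort_harmonized):
        _, p, adj, _ = study_cohort_harmonized
        cc = run_case_control_battery(adj, p)
        assert len(cc) == 25 * 4
        for metric in METRICS:
            assert set(cc.loc[cc["metric"] == metric, "roi"]) == set(ROI_OUTCOMES)

    def test_bonferroni_flag_consistency(self, study_cohort_harmonized):
        _, p, adj, _ = study_cohort_harmonized
        cc = run_case_control_battery(adj, p, alpha=0.05)
        np.testing.assert_array_equal(
            cc["significant"].to_numpy(), (cc["p"] <= 0.05 / 25).to_numpy()
        )

    def test_bonferroni_monotonicity(self, study_cohort_harmonized):
        """Lowering alpha never makes a non-significant cell significant."""
        _, p, adj, _ = study_cohort_harmonized
        loose = run_case_control_battery(adj, p, alpha=0.05)
        strict = run_case_control_battery(adj, p, alpha=0.01)
        assert not (strict["significant"] & ~loose["significant"]).any()

    def test_sign_convention_fa_deficit_positive(self, study_cohort_harmonized):
        """Cases generated with lower FA yield positive d (control minus
        case orientation) and sign(d) == sign(t)."""
        _, p, adj, _ = study_cohort_harmonized
        cc = run_case_control_battery(adj, p)
        fa = cc[cc["metric"] == "FA"].set_index("roi")
        assert fa.loc["SLF", "d"] > 0
        assert (np.sign(cc["d"]) == np.sign(cc["t"])).all()

    def test_centering_invariance(self, small_cohort):
        _, p, m = small_cohort
        data = m[(m["roi"] == "SLF") & (m["metric"] == "FA")].merge(p, on="subject_id")
        r_c = fit_roi_model(data, "SLF", "FA", DesignSpec(center=True))
        r_u = fit_roi_model(data, "SLF", "FA", DesignSpec(center=False))
        assert r_c["d"] == pytest.approx(r_u["d"], abs=1e-10)

    def test_group_sizes_recorded(self, study_cohort_harmonized):
        _, p, adj, _ = study_cohort_harmonized
        cc = run_case_control_battery(adj, p)
        fa = cc[cc["metric"] == "FA"]
        assert (fa["n1"] == 321).all() and (fa["n2"] == 265).all()
        md = cc[cc["metric"] == "MD"]
        assert (md["n1"] + md["n2"] == 505).all()


class TestSubgroupBattery:
    @pytest.fixture(scope="class")
    def eos_only_cohort(self):
        eff = {g: {m: {} for m in METRICS} for g in ("EOS", "AFP", "OTP")}
        eff["EOS"]["FA"] = {"SLF": -0.8}
        cfg = make_config(
            [("A", 80, 70, METRICS), ("B", 80, 70, METRICS)],
            {"CTR": 140, "EOS": 90, "AFP": 45, "OTP": 25},
            seed=9, effect_matrix=eff,
        )
        return generate_cohort(cfg)

    def test_effect_isolated_to_eos(self, eos_only_cohort):
        p, m = eos_only_cohort
        res = run_subgroup_battery(m[m["metric"] == "FA"], p)
        slf = res[res["roi"] == "SLF"].set_index("contrast")
        assert slf.loc["CTR-EOS", "p"] < 0.002
        assert slf.loc["CTR-AFP", "p"] > 0.002
        assert slf.loc["CTR-OTP", "p"] > 0.002

    def test_three_contrasts_per_cell(self, eos_only_cohort):
        p, m = eos_only_cohort
        res = run_subgroup_battery(m[m["metric"] == "FA"], p)
        assert set(res["contrast"]) == {"CTR-EOS", "CTR-AFP", "CTR-OTP"}
        assert len(res) == 25 * 3

    def test_small_subgroup_skipped_with_warning(self):
        cfg = make_config(
            [("A", 40, 40, METRICS), ("B", 40, 40, METRICS)],
            {"CTR": 80, "EOS": 50, "AFP": 28, "OTP": 2}, seed=10,
        )
        p, m = generate_cohort(cfg)
        with pytest.warns(UserWarning, match="OTP"):
            res = run_subgroup_battery(m[m["metric"] == "FA"], p)
        assert "CTR-OTP" not in set(res["contrast"])


class TestInteractionsAndStrata:
    @pytest.fixture(scope="class")
    def male_effect_cohort(self):
        """Case-control FA deficit present in males only."""
        cfg = make_config(
            [("A", 90, 80, METRICS), ("B", 90, 80, METRICS)],
            {"CTR": 160, "EOS": 110, "AFP": 45, "OTP": 25}, seed=12,
        )
        p, m = generate_cohort(cfg)
        male_cases = p[(p["sex"] == "M") & (p["diagnosis"] == "EOP")]["subject_id"]
        mask = (m["roi"] == "SLF") & (m["metric"] == "FA") & m["subject_id"].isin(male_cases)
        m = m.copy()
        m.loc[mask, "value"] -= 1.0 * 0.025
        return p, m

    def test_sex_interaction_detected(self, male_effect_cohort):
        p, m = male_effect_cohort
        res = run_interaction_models(m[m["metric"] == "FA"], p, "sex_x_dx")
        slf = res[res["roi"] == "SLF"].iloc[0]
        assert slf["p"] < 0.01

    def test_sex_recoding_flips_interaction_sign(self, male_effect_cohort):
        p, m = male_effect_cohort
        fa = m[m["metric"] == "FA"]
        res = run_interaction_models(fa, p, "sex_x_dx")
        p_flip = p.copy()
        p_flip["sex"] = p_flip["sex"].map({"F": "M", "M": "F"})
        res_flip = run_interaction_models(fa, p_flip, "sex_x_dx")
        a = res.set_index(["roi", "metric"])["t"]
        b = res_flip.set_index(["roi", "metric"])["t"]
        np.testing.assert_allclose(a.to_numpy(), -b.to_numpy(), atol=1e-8)

    def test_stratified_male_significant_female_null(self, male_effect_cohort):
        p, m = male_effect_cohort
        fa = m[m["metric"] == "FA"]
        males = run_stratified_battery(fa, p, "M")
        females = run_stratified_battery(fa, p, "F")
        assert males[males["roi"] == "SLF"]["p"].iloc[0] < 0.002
        assert females[females["roi"] == "SLF"]["p"].iloc[0] > 0.002

    def test_stratum_counts_match_filter(self, male_effect_cohort):
        p, m = male_effect_cohort
        males = run_stratified_battery(m[m["metric"] == "FA"], p, "M")
        n_case = ((p["sex"] == "M") & (p["diagnosis"] == "EOP")).sum()
        n_ctrl = ((p["sex"] == "M") & (p["diagnosis"] == "CTR")).sum()
        assert (males["n1"] == n_case).all() and (males["n2"] == n_ctrl).all()

    def test_null_interaction_p_uniform(self):
        """Without any interaction, interaction p-values are uniform
        (KS test over replicates of a small null cohort)."""
        pvals = []
        for seed in range(40):
            cfg = make_config(
                [("A", 30, 30, ("FA",)), ("B", 30, 30, ("FA",))],
                {"CTR": 60, "EOS": 40, "AFP": 15, "OTP": 5}, seed=100 + seed,
            )
            p, m = generate_cohort(cfg)
            res = run_interaction_models(
                m[(m["roi"] == "SLF") | (m["roi"] == "CC")], p, "sex_x_dx")
            pvals.extend(res["p"].tolist())
        from scipy.stats import kstest
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestGlobalAdjustment:
    @pytest.fixture(scope="class")
    def global_effect_cohort(self):
        """Uniform FA deficit across every tract and the periphery."""
        eff = {g: {m: {} for m in METRICS} for g in ("EOS", "AFP", "OTP")}
        from dtimega.rois import TRACTS, PERIPHERY
        for g in ("EOS", "AFP", "OTP"):
            eff[g]["FA"] = {t: -0.45 for t in TRACTS}
            eff[g]["FA"][PERIPHERY] = -0.45
        cfg = make_config(
            [("A", 90, 80, ("FA",)), ("B", 90, 80, ("FA",))],
            {"CTR": 160, "EOS": 110, "AFP": 45, "OTP": 25},
            seed=13, effect_matrix=eff,
        )
        return generate_cohort(cfg)

    def test_uniform_effect_abolished_by_average_adjustment(self, global_effect_cohort):
        p, m = global_effect_cohort
        plain = run_case_control_battery(m, p)
        adjusted = run_global_adjusted_battery(m, p, "average")
        assert plain["significant"].sum() >= 10
        assert adjusted["significant"].sum() <= 2

    def test_focal_core_effect_survives_periphery_adjustment(self):
        eff = {g: {m: {} for m in METRICS} for g in ("EOS", "AFP", "OTP")}
        for g in ("EOS", "AFP", "OTP"):
            eff[g]["FA"] = {"SLF": -0.6}
        cfg = make_config(
            [("A", 90, 80, ("FA",)), ("B", 90, 80, ("FA",))],
            {"CTR": 160, "EOS": 110, "AFP": 45, "OTP": 25},
            seed=14, effect_matrix=eff,
        )
        p, m = generate_cohort(cfg)
        adjusted = run_global_adjusted_battery(m, p, "periphery")
        slf = adjusted[adjusted["roi"] == "SLF"].iloc[0]
        assert slf["significant"]

    def test_zero_effect_no_significance(self):
        cfg = make_config(
            [("A", 60, 60, ("FA",)), ("B", 60, 60, ("FA",))],
            {"CTR": 120, "EOS": 80, "AFP": 30, "OTP": 10}, seed=15,
        )
        p, m = generate_cohort(cfg)
        plain = run_case_control_battery(m, p)
        adjusted = run_global_adjusted_battery(m, p, "core")
        assert plain["significant"].sum() == 0
        assert adjusted["significant"].sum() == 0

    def test_summary_excluded_as_outcome(self, global_effect_cohort):
        p, m = global_effect_cohort
        adjusted = run_global_adjusted_battery(m, p, "average")
        assert "Average" not in set(adjusted["roi"])
        assert len(adjusted[adjusted["metric"] == "FA"]) == 24


class TestPeripheryDerivation:
    def test_voxel_constants(self):
        assert V_TOTAL - V_CORE == V_PERIPHERY == 81_147

    def test_equal_inputs_fixed_point(self):
        assert derive_periphery(0.5, 0.5) == pytest.approx(0.5)

    def test_arithmetic_example(self):
        # (112889*0.5 - 31742*0.52)/81147
        assert derive_periphery(0.5, 0.52) == pytest.approx(0.4921767, abs=5e-6)

    def test_identity_reconstruction(self):
        rng = np.random.default_rng(16)
        avg = rng.uniform(0.4, 0.6, 50)
        core = rng.uniform(0.4, 0.6, 50)
        peri = derive_periphery(avg, core)
        np.testing.assert_allclose(avg * V_TOTAL, core * V_CORE + peri * V_PERIPHERY,
                                   rtol=1e-12)

    def test_negative_diffusivity_rejected(self):
        with pytest.raises(ModelError, match="periphery"):
            derive_periphery(0.1, 1.5, metric="MD")


class TestClinicalAssociations:
    @pytest.fixture(scope="class")
    def duration_effect_cohort(self):
        """Longer illness duration lowers ALIC MD in cases."""
        cfg = make_config(
            [("A", 90, 60, METRICS), ("B", 90, 60, METRICS)],
            {"CTR": 120, "EOS": 110, "AFP": 45, "OTP": 25}, seed=17,
        )
        p, m = generate_cohort(cfg)
        cases = p[p["diagnosis"] == "EOP"][["subject_id", "duration"]]
        m = m.merge(cases, on="subject_id", how="left")
        mask = (m["roi"] == "ALIC") & (m["metric"] == "MD") & m["duration"].notna()
        slope = -0.02  # MD units per year of illness
        m.loc[mask, "value"] += slope * m.loc[mask, "duration"]
        return p, m.drop(columns="duration")

    def test_duration_slope_recovered(self, duration_effect_cohort):
        p, m = duration_effect_cohort
        res = run_clinical_associations(m[m["metric"] == "MD"], p)
        dur = res[(res["contrast"] == "duration:slope") & (res["roi"] == "ALIC")].iloc[0]
        assert dur["coef"] < 0
        assert dur["significant"]

    def test_onset_model_only_adjusted_for_sex(self, duration_effect_cohort):
        """The age-at-onset model has residual df = n - 3 (intercept,
        onset, sex), confirming no age terms enter the design."""
        p, m = duration_effect_cohort
        res = run_clinical_associations(m[m["metric"] == "MD"], p)
        onset = res[res["contrast"] == "age_onset:slope"]
        full = res[res["contrast"] == "duration:slope"]
        n_onset = onset["n1"].iloc[0]
        assert (onset["df"] == n_onset - 3).all()
        n_dur = full["n1"].iloc[0]
        assert (full["df"] == n_dur - 7).all()

    def test_null_medication_contrasts_nonsignificant(self, duration_effect_cohort):
        p, m = duration_effect_cohort
        res = run_clinical_associations(m[m["metric"] == "FA"], p)
        meds = res[res["contrast"].str.contains("user")]
        assert len(meds) > 0
        assert meds["significant"].sum() == 0

    def test_cases_only(self, duration_effect_cohort):
        p, m = duration_effect_cohort
        res = run_clinical_associations(m[m["metric"] == "MD"], p)
        n_cases = (p["diagnosis"] == "EOP").sum()
        assert (res.loc[res["contrast"] == "duration:slope", "n1"] <= n_cases).all()
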