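"""Transforms, correlation structure, PFAS groups, mixed models, multiplicity."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import exposomekit as ek
from exposomekit.associations import (
    DEFAULT_PFAS_GROUPS,
    ModelSpec,
    adjust_multiplicity,
    correlation_structure,
    fit_lmm,
    group_and_sum,
    interaction_age_pregnancies,
    sensitivity_parous_only,
    transform_sqrt,
)


def simulate_repeated(n_subjects=80, beta=0.5, subject_sd=0.5, residual_sd=1.0,
                      seed=0, exposure_name="age"):
    """Two visits per subject, outcome = beta * exposure + u_i + eps."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        u = rng.normal(0, subject_sd)
        for v in (1, 2):
            x = rng.uniform(30, 60)
            rows.append({
                "participant_id": f"P{i}", exposure_name: x,
                "y": beta * x + u + rng.normal(0, residual_sd),
            })
    return pd.DataFrame(rows)


class TestTransformSqrt:
    def test_values(self):
        assert transform_sqrt([4.0, 0.0]).tolist() == [2.0, 0.0]

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            transform_sqrt([-1.0])

    def test_reduces_lognormal_skewness(self):
        rng = np.random.default_rng(8)
        raw = rng.lognormal(0.0, 1.0, size=10_000)
        assert abs(stats.skew(transform_sqrt(raw))) < abs(stats.skew(raw))

    def test_order_preserving(self):
        x = np.array([0.1, 2.0, 5.0, 0.4])
        assert (np.argsort(transform_sqrt(x)) == np.argsort(x)).all()


class TestCorrelationStructure:
    def test_monotone_nonlinear_pair(self):
        x = pd.DataFrame({"a": np.arange(1.0, 21.0)})
        rf = pd.DataFrame({"f": np.exp(np.arange(1.0, 21.0) / 4)})
        cs = correlation_structure(x, rf)
        assert cs.spearman_rho.loc["a", "f"] == pytest.approx(1.0)

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(1)
        x = pd.DataFrame({"a": rng.uniform(0, 5, 30)})
        cs = correlation_structure(x, pd.DataFrame(index=x.index))
        assert cs.pearson_r.loc["a", "a"] == pytest.approx(1.0)

    def test_constant_column_flagged_nan(self):
        x = pd.DataFrame({"a": [1.0] * 10, "b": np.arange(10.0)})
        rf = pd.DataFrame({"f": np.arange(10.0)})
        cs = correlation_structure(x, rf)
        assert np.isnan(cs.spearman_rho.loc["a", "f"])
        assert not np.isnan(cs.spearman_rho.loc["b", "f"])

    def test_independent_columns_mostly_within_null_band(self):
        # permutation-style oracle: at n=161 the null 95% band is |rho| < 0.16
        rng = np.random.default_rng(2)
        inside = 0
        n_rep = 200
        for _ in range(n_rep):
            rho, _ = stats.spearmanr(rng.normal(size=161), rng.normal(size=161))
            inside += abs(rho) < 0.16
        assert inside / n_rep >= 0.90


class TestGroupAndSum:
    def test_additivity(self):
        cols = ["PFOS (total)", "PFHpS (total)", "PFOA (total)", "PFHxS (total)"]
        t = pd.DataFrame(1.0, index=["s1", "s2"], columns=cols)
        scores = group_and_sum(t, {"Group 3": DEFAULT_PFAS_GROUPS["Group 3"]})
        assert (scores["Group 3"] == 4.0).all()

    def test_default_group_sizes(self):
        assert [len(m) for m in DEFAULT_PFAS_GROUPS.values()] == [3, 3, 4]

    def test_missing_member_named(self):
        t = pd.DataFrame({"PFDA": [1.0]})
        with pytest.raises(ValueError, match="PFNA"):
            group_and_sum(t, {"g": ("PFDA", "PFNA")})

    def test_empty_member_list_rejected(self):
        with pytest.raises(ValueError, match="no members"):
            group_and_sum(pd.DataFrame({"a": [1.0]}), {"g": ()})


class TestFitLmm:
    def test_zero_subject_variance_matches_ols(self):
        data = simulate_repeated(n_subjects=60, beta=0.5, subject_sd=0.0, seed=3)
        spec = ModelSpec(outcome="y", exposure="age", covariates=())
        res = fit_lmm(spec, data)
        import statsmodels.api as sm

        ols = sm.OLS(data["y"], sm.add_constant(data["age"])).fit()
        assert res.coefficient == pytest.approx(ols.params["age"], abs=1e-6)

    def test_recovers_planted_coefficient(self):
        data = simulate_repeated(n_subjects=150, beta=0.5, seed=4)
        res = fit_lmm(ModelSpec("y", "age", covariates=()), data)
        assert res.converged
        assert res.coefficient == pytest.approx(0.5, abs=3 * res.se)
        assert res.n_subjects == 150
        assert res.n_samples == 300

    def test_collinear_design_flagged(self):
        data = simulate_repeated(n_subjects=40, seed=5)
        data["n_pregnancies"] = data["age"] / 10.0
        spec = ModelSpec("y", "age", covariates=("n_pregnancies",))
        res = fit_lmm(spec, data)
        assert not res.converged

    def test_single_visit_data_falls_back_to_ols(self):
        data = simulate_repeated(n_subjects=50, seed=6)
        data = data.groupby("participant_id", as_index=False).first()
        with pytest.warns(UserWarning, match="OLS"):
            res = fit_lmm(ModelSpec("y", "age", covariates=()), data)
        assert res.method == "ols"
        assert res.converged

    def test_sign_invariant_to_affine_covariate_rescaling(self):
        data = simulate_repeated(n_subjects=80, beta=0.5, seed=7)
        data["z"] = np.random.default_rng(7).normal(size=len(data))
        base = fit_lmm(ModelSpec("y", "age", covariates=("z",)), data)
        scaled = data.assign(age=data["age"] * 12.0 + 5.0)
        res = fit_lmm(ModelSpec("y", "age", covariates=("z",)), scaled)
        assert res.coefficient * 12.0 == pytest.approx(base.coefficient, rel=1e-4)
        assert np.sign(res.coefficient) == np.sign(base.coefficient)

    def test_exposure_duplicated_in_covariates_rejected(self):
        data = simulate_repeated(n_subjects=10, seed=8)
        with pytest.raises(ValueError, match="duplicated"):
            fit_lmm(ModelSpec("y", "age", covariates=("age",)), data)

    def test_t_resid_p_reference_more_conservative(self):
        data = simulate_repeated(n_subjects=30, beta=0.1, seed=9)
        normal = fit_lmm(ModelSpec("y", "age", covariates=()), data)
        tref = fit_lmm(ModelSpec("y", "age", covariates=()), data,
                       p_reference="t-resid")
        assert tref.p_value >= normal.p_value


class TestInteraction:
    def _cohort_data(self, seed, beta_int=0.0):
        cohort = ek.synthetic_data.generate_cohort(seed=seed)
        data = cohort.covariate_frame()
        rng = np.random.default_rng(seed)
        u = {p: rng.normal(0, 0.5) for p in data["participant_id"].unique()}
        data["y"] = (
            0.01 * data["age"]
            - 0.05 * data["n_pregnancies"]
            + beta_int * (data["age"] - 43) * data["n_pregnancies"]
            + data["participant_id"].map(u)
            + rng.normal(0, 0.5, len(data))
        )
        return data

    def test_null_interaction_p_uniform(self):
        ps = []
        for rep in range(120):
            res = interaction_age_pregnancies(
                self._cohort_data(1000 + rep), "y",
                covariates=("n_pregnancies",),
            )
            if res.converged:
                ps.append(res.p_value)
        _, ks_p = stats.kstest(ps, "uniform")
        assert ks_p > 0.01

    def test_planted_interaction_detected(self):
        hits = 0
        n_rep = 60
        for rep in range(n_rep):
            res = interaction_age_pregnancies(
                self._cohort_data(2000 + rep, beta_int=0.05), "y",
                covariates=("n_pregnancies",),
            )
            hits += res.converged and res.p_value < 0.05
        assert hits / n_rep > 0.5

    def test_collinear_interaction_flagged(self):
        data = simulate_repeated(n_subjects=40, seed=10)
        data["n_pregnancies"] = data["age"] / 10.0
        res = interaction_age_pregnancies(data, "y", covariates=("n_pregnancies",))
        assert not res.converged


class TestSensitivityParousOnly:
    def test_all_parous_identical_to_full_fit(self):
        data = simulate_repeated(n_subjects=50, seed=11)
        data["n_pregnancies"] = 2
        spec = ModelSpec("y", "age", covariates=())
        full = fit_lmm(spec, data)
        sens = sensitivity_parous_only(spec, data)
        assert sens.coefficient == pytest.approx(full.coefficient)

    def test_all_nulliparous_rejected(self):
        data = simulate_repeated(n_subjects=10, seed=12)
        data["n_pregnancies"] = 0
        with pytest.raises(ValueError, match="parous"):
            sensitivity_parous_only(ModelSpec("y", "age", covariates=()), data)

    def test_same_sign_as_full_model_when_effect_uniform(self):
        # effect planted equally in all parity strata: subset and full model
        # should agree in direction nearly always
        agree = 0
        n_rep = 40
        for rep in range(n_rep):
            cohort = ek.synthetic_data.generate_cohort(seed=3000 + rep)
            effects = {"X": ek.synthetic_data.EffectSpec(
                0.0, {"age": 0.02}, subject_sd=0.3, residual_sd=0.5)}
            matrix, _ = ek.synthetic_data.generate_target_truth(
                cohort, effects, {"X": 1e-12}, seed=3000 + rep)
            data = cohort.covariate_frame()
            data["y"] = np.log(matrix.values.loc["X"].reindex(data.index))
            spec = ModelSpec("y", "age", covariates=())
            full = fit_lmm(spec, data)
            sens = sensitivity_parous_only(spec, data, by="pregnancies")
            agree += np.sign(full.coefficient) == np.sign(sens.coefficient)
        assert agree / n_rep >= 0.95

    def test_deliveries_subset_switch(self):
        data = simulate_repeated(n_subjects=30, seed=13)
        data["n_pregnancies"] = 1
        data["n_deliveries"] = 0
        with pytest.raises(ValueError, match="parous"):
            sensitivity_parous_only(
                ModelSpec("y", "age", covariates=()), data, by="deliveries"
            )


class TestMultiplicity:
    def test_untargeted_family_bonferroni_threshold(self):
        decision = adjust_multiplicity(np.full(16_758, 0.5))
        assert decision.bonferroni_threshold == pytest.approx(0.05 / 16_758)
        # the printed threshold at this family size rounds to 3.0e-6
        assert float(f"{decision.bonferroni_threshold:.1e}") == pytest.approx(3.0e-6)

    def test_single_test(self):
        decision = adjust_multiplicity([0.2])
        assert decision.bonferroni_threshold == pytest.approx(0.05)

    def test_tier_ordering(self):
        decision = adjust_multiplicity([0.004] + [0.5] * 9_999)
        flags = decision.flags.iloc[0]
        assert flags["pass_alpha"] and flags["pass_literature"]
        assert not flags["pass_bonferroni"]

    def test_tiers_nested_when_n_tests_at_least_10(self):
        rng = np.random.default_rng(14)
        decision = adjust_multiplicity(rng.uniform(0, 1, 50) ** 4)
        f = decision.flags
        assert (f["pass_bonferroni"] <= f["pass_literature"]).all()
        assert (f["pass_literature"] <= f["pass_alpha"]).all()

    def test_nonconverged_nan_excluded_from_count(self):
        decision = adjust_multiplicity([0.01, np.nan, 0.02])
        assert decision.n_tests == 2
        assert not decision.flags.iloc[1].any()

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            adjust_multiplicity([np.nan])
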