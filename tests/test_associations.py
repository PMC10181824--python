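import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from brainagekit.associations import (
    TestSpec,
    ancova_categorical,
    apoe_group,
    cohens_f2,
    default_battery,
    fdr_correct,
    fit_association,
    interaction_test,
    run_battery,
    select_extreme_deltas,
)


def _frame(n, rng, **cols):
    base = {
        "age": rng.uniform(44, 81, n),
        "sex": rng.choice(["female", "male"], n),
        "diagnosis": "CU",
    }
    base.update(cols)
    return pd.DataFrame(base, index=[f"s{i}" for i in range(n)])


class TestFitAssociation:
    def test_outcome_equal_to_zscored_predictor(self, rng):
        n = 60
        x = rng.normal(10, 3, n)
        d = _frame(n, rng, biomarker=x)
        d["delta"] = (x - x.mean()) / x.std(ddof=1)
        res = fit_association(TestSpec("biomarker"), d)
        assert res["beta"] == pytest.approx(1.0, abs=1e-10)
        assert res["p"] < 1e-20
        assert res["n"] == n

    def test_type_one_error_calibrated_under_null(self):
        hits = 0
        n_seeds = 300
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            d = _frame(200, rng, biomarker=rng.normal(0, 1, 200))
            d["delta"] = rng.normal(0, 2, 200)
            if fit_association(TestSpec("biomarker"), d)["p"] < 0.05:
                hits += 1
        assert 0.02 <= hits / n_seeds <= 0.09

    def test_planted_effect_recovered(self):
        betas = []
        for seed in range(40):
            rng = np.random.default_rng(1000 + seed)
            n = 500
            x = rng.normal(0, 1, n)
            d = _frame(n, rng, biomarker=x)
            d["delta"] = 0.3 * x + np.sqrt(1 - 0.09) * rng.normal(0, 1, n)
            betas.append(fit_association(TestSpec("biomarker"), d)["beta"])
        assert np.mean(betas) == pytest.approx(0.3, abs=0.05)

    def test_standardized_beta_invariant_to_affine_rescaling(self, rng):
        n = 120
        x = rng.normal(50, 10, n)
        d = _frame(n, rng, biomarker=x)
        d["delta"] = 0.4 * (x - x.mean()) / x.std() + rng.normal(0, 1, n)
        b1 = fit_association(TestSpec("biomarker"), d)["beta"]
        d2 = d.copy()
        d2["biomarker"] = 1000.0 * d2["biomarker"] - 77.0
        b2 = fit_association(TestSpec("biomarker"), d2)["beta"]
        assert b1 == pytest.approx(b2, abs=1e-12)

    def test_missing_rows_dropped_and_counted(self, rng):
        d = _frame(50, rng, biomarker=rng.normal(0, 1, 50))
        d["delta"] = rng.normal(0, 1, 50)
        d.loc[d.index[:10], "biomarker"] = np.nan
        res = fit_association(TestSpec("biomarker"), d)
        assert res["n"] == 40

    def test_empty_stratum_rejected(self, rng):
        d = _frame(10, rng, biomarker=np.nan)
        d["delta"] = 1.0
        with pytest.raises(ValueError, match="empty stratum|too few"):
            fit_association(TestSpec("biomarker"), d)

    def test_collinear_design_rejected(self, rng):
        n = 40
        d = _frame(n, rng, biomarker=rng.normal(0, 1, n))
        d["delta"] = rng.normal(0, 1, n)
        d["age2"] = d["age"]  # exact duplicate covariate
        spec = TestSpec("biomarker", covariates=("age", "age2", "sex"))
        with pytest.raises(ValueError, match="collinear"):
            fit_association(spec, d)

    def test_predictor_in_covariates_rejected(self):
        with pytest.raises(ValueError, match="covariates"):
            TestSpec("age")


class TestAncova:
    def test_identical_groups_give_null_contrast(self, rng):
        n = 400
        d = _frame(n, rng, group=rng.choice(["A-", "A+"], n))
        d["delta"] = rng.normal(0, 2, n)
        rows = ancova_categorical(TestSpec("group", kind="categorical", reference="A-"), d)
        assert abs(rows[0]["beta"]) < 0.25
        assert abs(rows[0]["effect_size"]) < 0.25

    def test_planted_shift_recovers_cohens_d(self):
        ds = []
        for seed in range(25):
            rng = np.random.default_rng(seed)
            n = 800
            group = rng.choice(["A-", "A+"], n)
            d = _frame(n, rng, group=group)
            d["delta"] = np.where(group == "A+", 1.0, 0.0) + rng.normal(0, 2.0, n)
            rows = ancova_categorical(
                TestSpec("group", kind="categorical", reference="A-"), d
            )
            ds.append(rows[0]["effect_size"])
        assert np.mean(ds) == pytest.approx(0.5, abs=0.15)

    def test_monotone_stage_shifts_recovered_in_order(self):
        ok = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 800
            stage = rng.choice(["A-T-", "A+T-", "A+T+"], n, p=[0.5, 0.3, 0.2])
            d = _frame(n, rng, at_stage=stage)
            shift = {"A-T-": 0.0, "A+T-": 0.5, "A+T+": 1.0}
            d["delta"] = [shift[s] for s in stage] + rng.normal(0, 1.0, n)
            rows = ancova_categorical(
                TestSpec("at_stage", kind="categorical", reference="A-T-"), d
            )
            by = {r["level"].split(" ")[0]: r["beta"] for r in rows}
            if by["A+T+"] > by["A+T-"] > 0:
                ok += 1
        assert ok >= 9

    def test_reference_level_must_exist(self, rng):
        d = _frame(20, rng, group=["A+"] * 20)
        d["delta"] = rng.normal(0, 1, 20)
        with pytest.raises(ValueError, match="reference"):
            ancova_categorical(TestSpec("group", kind="categorical", reference="A-"), d)

    def test_tiny_level_rejected(self, rng):
        d = _frame(20, rng, group=["A-"] * 19 + ["A+"])
        d["delta"] = rng.normal(0, 1, 20)
        with pytest.raises(ValueError, match="< 2"):
            ancova_categorical(TestSpec("group", kind="categorical", reference="A-"), d)


class TestCohensF2:
    def test_closed_form(self):
        assert cohens_f2(0.5, 0.3) == pytest.approx(0.4)
        assert cohens_f2(0.42, 0.42) == 0.0

    def test_validation(self):
        with pytest.raises(ValueError):
            cohens_f2(1.0, 0.5)
        with pytest.raises(ValueError):
            cohens_f2(0.3, 0.5)

    def test_matches_dual_route_from_fitted_models(self, rng):
        n = 200
        x = rng.normal(0, 1, n)
        age = rng.uniform(44, 81, n)
        y = 0.5 * x + 0.05 * age + rng.normal(0, 1, n)
        Xf = np.column_stack([np.ones(n), x, age])
        Xr = np.column_stack([np.ones(n), age])

        def r2(X):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            return 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))

        r2f, r2r = r2(Xf), r2(Xr)
        direct = (r2f - r2r) / (1 - r2f)
        assert cohens_f2(r2f, r2r) == pytest.approx(direct, rel=1e-12)


class TestInteraction:
    def test_relabeling_sexes_flips_product_beta(self, rng):
        n = 300
        x = rng.normal(0, 1, n)
        d = _frame(n, rng, biomarker=x)
        sexn = (d["sex"] == "female").astype(float)
        d["delta"] = 0.3 * x * sexn + rng.normal(0, 1, n)
        spec = TestSpec("biomarker", interaction="sex")
        b1 = interaction_test(spec, d)["beta"]
        d2 = d.copy()
        d2["sex"] = d["sex"].map({"female": "male", "male": "female"})
        b2 = interaction_test(spec, d2)["beta"]
        assert b1 == pytest.approx(-b2, abs=1e-10)

    def test_null_interaction_calibrated(self):
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            d = _frame(300, rng, biomarker=rng.normal(0, 1, 300))
            d["delta"] = 0.3 * d["biomarker"] + rng.normal(0, 1, 300)
            if interaction_test(TestSpec("biomarker", interaction="sex"), d)["p"] < 0.05:
                hits += 1
        assert 0.015 <= hits / n_seeds <= 0.10

    def test_planted_sex_moderation_detected(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 1000
            x = rng.normal(0, 1, n)
            d = _frame(n, rng, biomarker=x)
            fem = (d["sex"] == "female").to_numpy(float)
            d["delta"] = 0.3 * x * fem + rng.normal(0, 1, n)
            if interaction_test(TestSpec("biomarker", interaction="sex"), d)["p"] < 0.05:
                hits += 1
        assert hits >= 16

    def test_age_moderator_supported(self, rng):
        n = 400
        x = rng.normal(0, 1, n)
        d = _frame(n, rng, biomarker=x)
        age_c = d["age"] - d["age"].mean()
        d["delta"] = 0.02 * x * age_c + rng.normal(0, 1, n)
        res = interaction_test(TestSpec("biomarker", interaction="age"), d)
        assert res["predictor"] == "biomarker x age"
        assert np.isfinite(res["beta"])

    def test_constant_moderator_rejected(self, rng):
        d = _frame(50, rng, biomarker=rng.normal(0, 1, 50))
        d["sex"] = "female"
        d["delta"] = rng.normal(0, 1, 50)
        with pytest.raises(ValueError, match="constant"):
            interaction_test(TestSpec("biomarker", interaction="sex"), d)


class TestFDR:
    def test_hand_stepped_example(self):
        q = fdr_correct([0.01, 0.02, 0.04, 0.05])
        assert np.allclose(q, [0.04, 0.04, 0.05, 0.05])

    def test_all_equal_pvalues_unchanged(self):
        q = fdr_correct([0.03] * 7)
        assert np.allclose(q, 0.03)

    def test_matches_brute_force_definition_and_statsmodels(self, rng):
        for _ in range(50):
            p = rng.uniform(0, 1, rng.integers(2, 40))
            q = fdr_correct(p)
            # brute force from the step-up definition
            m = len(p)
            order = np.argsort(p)
            brute = np.empty(m)
            for rank_pos, i in enumerate(order):
                candidates = [
                    p[j] * m / (list(order).index(j) + 1)
                    for j in order[rank_pos:]
                ]
                brute[i] = min(1.0, min(candidates))
            assert np.allclose(q, brute)
            assert np.allclose(q, multipletests(p, method="fdr_bh")[1])

    def test_q_at_least_p(self, rng):
        p = rng.uniform(0, 1, 100)
        assert (fdr_correct(p) >= p - 1e-15).all()

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            fdr_correct([0.5, 1.2])


class TestExtremeDeltas:
    def test_enumerated_example_one_to_twenty(self):
        deltas = pd.Series(np.arange(1.0, 21.0), index=[f"s{i}" for i in range(20)])
        picked = select_extreme_deltas(deltas)
        values = sorted(deltas.loc[picked])
        # P10 = 2.9, P90 = 18.1 under linear-interpolation percentiles
        assert values == [1.0, 2.0, 19.0, 20.0]

    def test_symmetric_distribution_balanced_tails(self, rng):
        deltas = pd.Series(rng.normal(0, 1, 500))
        picked = select_extreme_deltas(deltas)
        vals = deltas.loc[picked]
        assert abs((vals > 0).sum() - (vals < 0).sum()) <= 10

    def test_constant_deltas_warn_and_return_empty(self):
        deltas = pd.Series(np.ones(15))
        with pytest.warns(UserWarning, match="tails empty"):
            picked = select_extreme_deltas(deltas)
        assert len(picked) == 0

    def test_small_cohort_rejected(self):
        with pytest.raises(ValueError, match="fewer than 10"):
            select_extreme_deltas(pd.Series([1.0, 2.0, 3.0]))

    def test_per_cohort_selection(self, rng):
        n = 100
        deltas = pd.Series(rng.normal(0, 1, n), index=[f"s{i}" for i in range(n)])
        cohort = pd.Series(["A"] * 50 + ["B"] * 50, index=deltas.index)
        picked = select_extreme_deltas(deltas, cohort)
        for c in ("A", "B"):
            block = deltas[cohort == c]
            sel = [i for i in picked if cohort[i] == c]
            assert len(sel) >= 10  # ~20% of 50, plus interpolation ties


class TestApoeGrouping:
    def test_mapping(self):
        out = apoe_group(pd.Series(["e33", "e22", "e23", "e34", "e44", "e24"]))
        assert out.tolist() == ["e33", "e2", "e2", "e4", "e4", "e24"]

    def test_unknown_genotype_rejected(self):
        with pytest.raises(ValueError, match="unknown APOE"):
            apoe_group(pd.Series(["e11"]))


class TestBattery:
    def _data(self, n=600, seed=0):
        rng = np.random.default_rng(seed)
        d = _frame(n, rng)
        d["diagnosis"] = rng.choice(["CU", "MCI"], n, p=[0.7, 0.3])
        d["delta"] = rng.normal(0, 2, n)
        d["abeta_status"] = rng.choice(["A-", "A+"], n)
        d["at_stage"] = rng.choice(["A-T-", "A+T-", "A+T+"], n)
        d["apoe"] = rng.choice(["e33", "e2", "e4", "e24"], n, p=[0.6, 0.1, 0.26, 0.04])
        d["wmh_prepared"] = rng.normal(0, 1, n)
        d["csf_nfl_z"] = rng.normal(0, 1, n)
        d["plasma_nfl_z"] = rng.normal(0, 1, n)
        d["signature_change"] = rng.normal(0, 0.02, n)
        return d

    def test_row_count_and_family_size_bookkeeping(self):
        d = self._data()
        result = run_battery(d)
        assert result.family_size == len(result.table)
        # every executed test got a q-value no smaller than its p
        assert (result.table["q"] >= result.table["p"] - 1e-15).all()
        # sex-interaction specs are skipped inside sex strata
        sub = result.table[result.table["sex"] != "all"]
        assert not sub["predictor"].str.contains("x sex").any()

    def test_null_battery_false_discoveries_rare(self):
        d = self._data(seed=3)
        result = run_battery(d)
        assert (result.table["q"] < 0.05).mean() < 0.1

    def test_planted_effects_selectively_recovered(self):
        found_planted, found_other = 0, 0
        n_seeds = 10
        for seed in range(n_seeds):
            d = self._data(n=800, seed=100 + seed)
            rng = np.random.default_rng(seed)
            d["plasma_nfl_z"] = 0.4 * d["delta"] / d["delta"].std() + rng.normal(
                0, 1, len(d)
            )
            result = run_battery(d, strata=[("CU", "all"), ("MCI", "all")])
            t = result.table
            planted = t[(t["predictor"] == "plasma_nfl_z")]
            others = t[
                (t["level"] == "")
                & (~t["predictor"].str.contains("plasma"))
                & (~t["predictor"].str.contains(" x "))
            ]
            found_planted += int((planted["q"] < 0.05).all())
            found_other += int((others["q"] < 0.05).any())
        assert found_planted >= 9
        assert found_other <= 2

    def test_sex_stratified_estimates_agree_when_effects_identical(self):
        # with identical female/male generating effects, the two stratified
        # betas differ by less than 2x their combined SE in nearly all seeds
        agree = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            n = 800
            x = rng.normal(0, 1, n)
            d = _frame(n, rng, biomarker=x)
            d["delta"] = 0.25 * x + rng.normal(0, 1, n)
            res = {}
            for sx in ("female", "male"):
                res[sx] = fit_association(
                    TestSpec("biomarker", covariates=("age",)), d[d["sex"] == sx]
                )
            gap = abs(res["female"]["beta"] - res["male"]["beta"])
            if gap < 2 * (res["female"]["se"] + res["male"]["se"]):
                agree += 1
        assert agree >= 18

    def test_spec_failures_recorded_not_raised(self):
        d = self._data(n=100)
        d["broken"] = np.nan
        specs = default_battery() + [TestSpec("broken")]
        result = run_battery(d, specs, strata=[("CU", "all")])
        assert any(s["predictor"] == "broken" for s in result.skipped)
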