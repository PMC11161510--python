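"""Survival machinery: KM, log-rank, Cox, c-index, stepwise selection,
association tests and the clinical grouping rules."""

import numpy as np
import pandas as pd
import pytest

from sarcomics import survival as sv
from sarcomics.synthetic import generate_survival


def two_group_records(n_per=150, log_hr=np.log(2), seed=0,
                      baseline=0.01, censor=0.004):
    rec = generate_survival(["a"] * n_per + ["b"] * n_per, baseline,
                            {"a": 0.0, "b": log_hr}, censor, seed=seed)
    rec["x"] = (rec["group"] == "b").astype(float)
    return rec


class TestKaplanMeier:
    def test_hand_product_limit(self):
        rec = pd.DataFrame({"time": [1, 2, 3], "event": [1, 1, 0]})
        km = sv.km_estimate(rec)
        assert km.probability_at(0.5) == 1.0
        assert km.probability_at(1) == pytest.approx(2 / 3)
        assert km.probability_at(2) == pytest.approx(1 / 3)
        assert km.probability_at(10) == pytest.approx(1 / 3)

    def test_all_censored_flat_one(self):
        rec = pd.DataFrame({"time": [1, 2, 3], "event": [0, 0, 0]})
        km = sv.km_estimate(rec)
        assert (km.survival == 1.0).all()

    def test_step_function_non_increasing(self, rng):
        rec = pd.DataFrame({"time": rng.exponential(10, 50).round(1) + 0.1,
                            "event": rng.integers(0, 2, 50)})
        km = sv.km_estimate(rec)
        assert (np.diff(km.survival) <= 1e-12).all()
        assert (km.greenwood_var >= 0).all()


class TestLogrank:
    def test_identical_groups_null(self):
        rec = pd.DataFrame({"time": [1, 2, 3, 1, 2, 3],
                            "event": [1, 1, 0, 1, 1, 0]})
        stat, df, p = sv.logrank_test(rec, ["a"] * 3 + ["b"] * 3)
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_planted_hazard_ratio_power(self):
        hits = 0
        for seed in range(20):
            rec = two_group_records(n_per=300, log_hr=np.log(3), seed=seed)
            _, _, p = sv.logrank_test(rec, rec["group"])
            hits += p < 0.001
        assert hits >= 19

    def test_single_group_rejected(self):
        rec = pd.DataFrame({"time": [1, 2], "event": [1, 1]})
        with pytest.raises(ValueError):
            sv.logrank_test(rec, ["a", "a"])


class TestCox:
    def test_planted_coefficient_recovery(self):
        rec = two_group_records(n_per=1000, seed=3)
        fit = sv.cox_fit(rec, ["x"])
        assert fit.coefficients.iloc[0] == pytest.approx(np.log(2), abs=0.15)
        assert fit.summary["hr"].iloc[0] == pytest.approx(
            np.exp(fit.coefficients.iloc[0]))
        assert fit.aic == pytest.approx(-2 * fit.log_likelihood + 2)

    def test_constant_covariate_rejected(self):
        rec = pd.DataFrame({"time": [1, 2, 3, 4], "event": [1, 1, 1, 0],
                            "x": [1.0, 1.0, 1.0, 1.0]})
        with pytest.raises(ValueError):
            sv.cox_fit(rec, ["x"])

    def test_missing_values_dropped_and_counted(self):
        rec = two_group_records(n_per=50, seed=4)
        rec.loc[rec.index[:5], "x"] = np.nan
        fit = sv.cox_fit(rec, ["x"])
        assert fit.n_dropped == 5
        assert fit.n_used == len(rec) - 5

    def test_categorical_reference_level(self):
        rec = two_group_records(n_per=200, seed=5)
        fit = sv.cox_fit(rec, ["group"])
        assert list(fit.coefficients.index) == ["group[b]"]
        num = sv.cox_fit(rec, ["x"])
        assert fit.coefficients.iloc[0] == pytest.approx(
            num.coefficients.iloc[0], abs=1e-6)

    def test_agrees_with_lifelines_direct(self):
        # same numbers as driving lifelines directly on the dummies
        from lifelines import CoxPHFitter
        rec = two_group_records(n_per=100, seed=6)
        fit = sv.cox_fit(rec, ["x"])
        cph = CoxPHFitter()
        cph.fit(rec[["time", "event", "x"]], "time", "event")
        assert fit.coefficients.iloc[0] == pytest.approx(cph.params_.iloc[0])


class TestStepwise:
    def test_noise_covariate_eliminated(self):
        removed = 0
        for seed in range(10):
            rec = two_group_records(n_per=400, seed=seed)
            rng = np.random.default_rng(seed)
            rec["noise"] = rng.normal(size=len(rec))
            fit, trace = sv.stepwise_backward_aic(rec, ["x", "noise"])
            removed += "noise" not in fit.covariates
        assert removed >= 9

    def test_single_covariate_unchanged(self):
        rec = two_group_records(n_per=100, seed=1)
        fit, trace = sv.stepwise_backward_aic(rec, ["x"])
        assert fit.covariates == ["x"]
        assert len(trace) == 1

    def test_final_aic_never_above_full(self):
        rec = two_group_records(n_per=150, seed=2)
        rng = np.random.default_rng(2)
        rec["n1"] = rng.normal(size=len(rec))
        rec["n2"] = rng.normal(size=len(rec))
        full = sv.cox_fit(rec, ["x", "n1", "n2"])
        fit, _ = sv.stepwise_backward_aic(rec, ["x", "n1", "n2"])
        assert fit.aic <= full.aic + 1e-9


class TestCindex:
    def test_perfect_ordering(self):
        rec = pd.DataFrame({"time": [1, 2, 3, 4], "event": [1, 1, 1, 1]})
        res = sv.harrell_cindex(-rec["time"], rec)
        assert res.cindex == 1.0

    def test_brute_force_pair_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(60):
            n = int(rng.integers(3, 7))
            r = rng.normal(size=n)
            if rng.uniform() < 0.3:
                r = np.round(r)  # induce risk ties
            t = rng.exponential(5, n).round(1) + 0.5
            e = rng.integers(0, 2, n)
            rec = pd.DataFrame({"time": t, "event": e})
            usable = conc = ties = 0
            for i in range(n):
                for j in range(n):
                    if t[i] < t[j] and e[i] == 1:
                        usable += 1
                        conc += r[i] > r[j]
                        ties += r[i] == r[j]
            if usable == 0:
                with pytest.raises(ValueError):
                    sv.harrell_cindex(r, rec)
                continue
            res = sv.harrell_cindex(r, rec)
            assert res.cindex == pytest.approx((conc + 0.5 * ties) / usable)
            assert res.n_usable == usable

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(1)
        rec = two_group_records(n_per=100, log_hr=0.0, seed=9)
        cs = [sv.harrell_cindex(rng.permutation(len(rec)), rec).cindex
              for _ in range(100)]
        assert np.mean(cs) == pytest.approx(0.5, abs=0.03)


class TestCrossValidation:
    def test_planted_signal_beats_chance(self):
        hits = 0
        for seed in range(10):
            rec = two_group_records(n_per=150, log_hr=1.2, seed=seed)
            res = sv.cv_cindex(rec, ["x"], seed=seed)
            hits += res.cindex > 0.6
        assert hits >= 9

    def test_deterministic_per_seed(self):
        rec = two_group_records(n_per=80, seed=3)
        a = sv.cv_cindex(rec, ["x"], seed=11)
        b = sv.cv_cindex(rec, ["x"], seed=11)
        assert a.per_fold == b.per_fold

    def test_same_spec_bootstrap_diff_null(self):
        rec = two_group_records(n_per=80, seed=5)
        diff, p, samples = sv.bootstrap_cindex_diff(rec, ["x"], ["x"], B=20,
                                                    seed=0)
        assert diff == pytest.approx(0.0, abs=1e-12)
        assert p >= 0.9
        assert diff == pytest.approx(samples.mean())

    def test_informative_beats_noise_model(self):
        rec = two_group_records(n_per=200, log_hr=1.2, seed=7)
        rng = np.random.default_rng(7)
        rec["noise"] = rng.normal(size=len(rec))
        diff, p, _ = sv.bootstrap_cindex_diff(rec, ["x"], ["noise"], B=40,
                                              seed=1)
        assert diff > 0
        assert p < 0.1


class TestAssociations:
    def test_chi_square_rxc_without_yates(self):
        stat, df, p = sv.chi_square_test([[14, 24], [18, 20], [9, 25]])
        assert df == 2
        assert p == pytest.approx(0.1867, abs=5e-5)

    def test_chi_square_2x2_with_yates(self):
        _, _, p1 = sv.chi_square_test([[24, 39], [17, 30]])
        _, _, p2 = sv.chi_square_test([[25, 40], [16, 29]])
        assert p1 == pytest.approx(0.9942, abs=5e-5)
        assert p2 == pytest.approx(0.9129, abs=5e-5)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            sv.chi_square_test([[0, 0], [3, 4]])

    def test_mannwhitney_brute_force_u(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            na, nb = rng.integers(3, 9, 2)
            a = rng.normal(size=na)
            b = rng.normal(size=nb)
            stat, _ = sv.rank_tests(np.concatenate([a, b]),
                                    ["a"] * na + ["b"] * nb)
            u = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
            assert stat == pytest.approx(u)

    def test_location_shift_power(self):
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(50):
            a = rng.normal(0, 1, 50)
            b = rng.normal(2, 1, 50)
            _, p = sv.rank_tests(np.concatenate([a, b]),
                                 ["a"] * 50 + ["b"] * 50)
            hits += p < 0.001
        assert hits >= 48

    def test_three_groups_kruskal(self):
        rng = np.random.default_rng(4)
        vals = np.concatenate([rng.normal(0, 1, 30), rng.normal(0, 1, 30),
                               rng.normal(3, 1, 30)])
        stat, p = sv.rank_tests(vals, ["a"] * 30 + ["b"] * 30 + ["c"] * 30)
        assert p < 1e-6


class TestClinicalRules:
    @pytest.mark.parametrize("pr_os,expected", [
        (0.51, "low"), (0.50, "low"), (0.52, "intermediate"),
        (0.66, "intermediate"), (0.67, "high"), (0.0, "low"), (1.0, "high"),
    ])
    def test_sarculator_thresholds(self, pr_os, expected):
        assert sv.sarculator_grouping(pr_os) == expected

    def test_sarculator_out_of_range(self):
        with pytest.raises(ValueError):
            sv.sarculator_grouping(1.2)

    @pytest.mark.parametrize("flags,expected", [
        ((True, True, False), "high risk"),
        ((True, False, False), "low risk"),
        ((False, False, False), "low risk"),
        ((True, True, True), "high risk"),
    ])
    def test_semantic_two_of_three(self, flags, expected):
        assert sv.semantic_radiophenotype(flags) == expected

    def test_combine_groups(self):
        rad = pd.Series(["A", "B", "A", None], index=list("wxyz"))
        rna = pd.Series(["A", "A", "B", "B"], index=list("wxyz"))
        df, n_excl = sv.combine_groups(rad, rna)
        assert n_excl == 1
        assert df.loc["w", "binary"] == "AxA"
        assert df.loc["x", "binary"] == "Others"
        assert df.loc["y", "binary"] == "Others"
        assert df.loc["w", "hybrid"] == "AxA"
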