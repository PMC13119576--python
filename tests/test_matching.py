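"""Propensity model, caliper matching, balance and comparison statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from copsway.core import ParticipantRecord
from copsway.matching import (
    fit_propensity,
    nn_caliper_match,
    records_frame,
    sensitivity_analyses,
    smd_table,
    welch_compare,
)
from copsway.synthetic_data import SynthCohortParams, gen_cohort


def _rec(pid, faller, age=70.0, sex=0, bmi=25.0, adl=1, illness=0, meds=1,
         disability=0, orthosis=0):
    return ParticipantRecord(pid, age, sex, bmi, adl, illness, meds, disability,
                             orthosis, 1 if faller else 0)


def _cohort(seed=0, n_f=20, n_n=40, confound=1.0):
    recs, _ = gen_cohort(
        SynthCohortParams(n_fallers=n_f, n_nonfallers=n_n, confound_strength=confound,
                          trials_per_condition=1, n_samples=100, seed=seed)
    )
    return recs


class TestPropensityFit:
    def test_single_binary_covariate_equals_log_odds_ratio(self):
        # 2x2 table: fallers 8 exposed / 4 unexposed, non-fallers 6 / 12
        recs = (
            [_rec(f"F{i}", True, sex=1) for i in range(8)]
            + [_rec(f"f{i}", True, sex=0) for i in range(4)]
            + [_rec(f"N{i}", False, sex=1) for i in range(6)]
            + [_rec(f"n{i}", False, sex=0) for i in range(12)]
        )
        fit = fit_propensity(recs, covariates=["sex"])
        assert fit.coefficients["sex"] == pytest.approx(math.log(4.0), abs=1e-5)

    def test_null_cohort_has_small_coefficients(self):
        recs = _cohort(seed=1, n_f=150, n_n=150, confound=0.0)
        fit = fit_propensity(recs)
        assert abs(fit.coefficients["age"]) < 0.05
        base_rate = np.mean([r.falls12m >= 1 for r in recs])
        assert np.allclose(fit.ps.mean(), base_rate, atol=0.02)

    def test_age_confound_recovered(self):
        fit = fit_propensity(_cohort(seed=2, n_f=100, n_n=100, confound=1.0))
        assert fit.coefficients["age"] > 0.05

    def test_separation_falls_back_to_ridge(self):
        # age separates the groups perfectly
        recs = [_rec(f"F{i}", True, age=80 + i) for i in range(6)] + [
            _rec(f"N{i}", False, age=60 + i) for i in range(6)
        ]
        with pytest.warns(UserWarning, match="ridge fallback"):
            fit = fit_propensity(recs, covariates=["age"])
        assert fit.penalized
        assert np.isfinite(fit.logit_ps).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            fit_propensity([_rec(f"F{i}", True) for i in range(5)])


class TestCaliperMatching:
    def test_toy_greedy_assignment_by_hand(self):
        # logit PS spread so the greedy descending-PS order is checkable:
        # treated T1 (highest PS) takes C1, T2 takes C2; T3 has no control
        # within the caliper.
        recs = [
            _rec("T1", True, age=80), _rec("T2", True, age=75), _rec("T3", True, age=95),
            _rec("C1", False, age=79), _rec("C2", False, age=74), _rec("C3", False, age=60),
        ]
        fit = fit_propensity(recs, covariates=["age"])
        res = nn_caliper_match(fit, recs)
        # brute-force greedy under descending-PS processing
        logit = fit.logit_ps
        treated = sorted(["T1", "T2", "T3"], key=lambda p: -fit.ps[p])
        avail, expected, unmatched = ["C1", "C2", "C3"], [], []
        for t in treated:
            d = [abs(logit[t] - logit[c]) for c in avail]
            j = int(np.argmin(d))
            if d[j] <= res.caliper:
                expected.append((t, avail.pop(j)))
            else:
                unmatched.append(t)
        assert res.pairs == expected
        assert res.unmatched == unmatched

    def test_all_controls_outside_caliper(self):
        recs = [_rec(f"T{i}", True, age=90) for i in range(3)] + [
            _rec(f"C{i}", False, age=60) for i in range(3)
        ]
        fit = fit_propensity(recs, covariates=["age"])
        res = nn_caliper_match(fit, recs, caliper_factor=1e-6)
        assert res.n_pairs == 0
        assert sorted(res.unmatched) == ["T0", "T1", "T2"]

    @pytest.mark.parametrize("seed", range(5))
    def test_caliper_and_no_reuse_invariants(self, seed):
        recs = _cohort(seed=seed)
        fit = fit_propensity(recs)
        res = nn_caliper_match(fit, recs)
        used = [c for _, c in res.pairs]
        assert len(used) == len(set(used))
        for t, c in res.pairs:
            assert abs(fit.logit_ps[t] - fit.logit_ps[c]) <= res.caliper + 1e-12
        n_f = sum(r.falls12m >= 1 for r in recs)
        assert res.n_pairs <= min(n_f, len(recs) - n_f)


class TestSMD:
    def test_identical_distributions_zero(self):
        recs = [_rec(f"F{i}", True, age=70 + i) for i in range(4)] + [
            _rec(f"N{i}", False, age=70 + i) for i in range(4)
        ]
        match = nn_caliper_match(fit_propensity(recs, covariates=["bmi"]), recs)
        smd = smd_table(recs, match)
        assert smd.loc["age", "smd_before"] == pytest.approx(0.0, abs=1e-12)

    def test_one_sd_separation_gives_unit_smd(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 2000)
        a = (a - a.mean()) / a.std(ddof=1)  # exactly unit sample variance
        recs = [_rec(f"F{i}", True, age=100 + v) for i, v in enumerate(a + 1.0)] + [
            _rec(f"N{i}", False, age=100 + v) for i, v in enumerate(a)
        ]
        fit = fit_propensity(recs, covariates=["bmi"])
        smd = smd_table(recs, nn_caliper_match(fit, recs))
        assert smd.loc["age", "smd_before"] == pytest.approx(1.0, abs=1e-9)

    def test_symmetric_under_group_swap(self):
        recs = _cohort(seed=3, n_f=15, n_n=30)
        fit = fit_propensity(recs)
        match = nn_caliper_match(fit, recs)
        smd = smd_table(recs, match)
        flipped = [
            ParticipantRecord(r.participant_id, r.age, r.sex, r.bmi, r.adl, r.illness,
                              r.n_medications, r.disability, r.orthosis,
                              0 if r.falls12m >= 1 else 1)
            for r in recs
        ]
        smd2 = smd_table(flipped, match)
        pd.testing.assert_frame_equal(smd, smd2)


class TestWelch:
    def _features(self, x1, x0):
        rows = []
        for i, v in enumerate(x1):
            rows.append({"participant_id": f"F{i}", "condition": "EO_firm", "faller": 1, "m": v})
        for i, v in enumerate(x0):
            rows.append({"participant_id": f"N{i}", "condition": "EO_firm", "faller": 0, "m": v})
        return pd.DataFrame(rows)

    def _match_all(self, n):
        from copsway.matching import MatchResult

        return MatchResult(pairs=[(f"F{i}", f"N{i}") for i in range(n)], caliper=1.0,
                           n_pairs=n, unmatched=[])

    def test_printed_toy_against_hand_formula(self):
        x1 = np.array([4.1, 5.2, 6.3, 5.8, 4.9])
        x0 = np.array([3.0, 7.5, 2.2, 8.1, 4.4])
        out = welch_compare(self._features(x1, x0), self._match_all(5))
        v1, v0 = x1.var(ddof=1) / 5, x0.var(ddof=1) / 5
        t_hand = (x1.mean() - x0.mean()) / math.sqrt(v1 + v0)
        df_hand = (v1 + v0) ** 2 / (v1**2 / 4 + v0**2 / 4)
        row = out.iloc[0]
        assert row["t"] == pytest.approx(t_hand, abs=1e-10)
        assert row["df"] == pytest.approx(df_hand, abs=1e-9)
        assert row["df"] <= 8

    def test_equal_means_give_zero_t(self):
        x = np.array([1.0, 2.0, 3.0])
        out = welch_compare(self._features(x, x.copy()), self._match_all(3))
        assert out.iloc[0]["t"] == 0.0

    def test_small_group_flagged(self):
        out = welch_compare(self._features([1.0], [1.0, 2.0, 3.0]), self._match_all(1))
        assert "n < 2" in out.iloc[0]["flag"]
        assert np.isnan(out.iloc[0]["p"])


class TestSensitivity:
    def test_age_driven_feature_vanishes_after_adjustment(self):
        recs = _cohort(seed=5, n_f=100, n_n=100, confound=1.2)
        df = records_frame(recs)
        rng = np.random.default_rng(0)
        # feature = pure age effect + noise: group difference is confounding only
        feat = pd.DataFrame(
            {
                "participant_id": df.index,
                "condition": "EO_firm",
                "faller": df["faller"].to_numpy(),
                "m": 0.5 * df["age"].to_numpy() + rng.normal(0, 0.5, len(df)),
            }
        )
        fit = fit_propensity(recs)
        g1 = feat[feat.faller == 1]["m"]
        g0 = feat[feat.faller == 0]["m"]
        raw_diff = g1.mean() - g0.mean()
        out = sensitivity_analyses(feat, recs, fit)
        adj = out.iloc[0]["adjusted_estimate"]
        assert abs(raw_diff) > 1.0  # confounded difference is large
        assert abs(adj) < 0.35 * abs(raw_diff)
        strat = out.iloc[0]["stratified_estimate"]
        assert abs(strat) < abs(raw_diff)

    def test_true_effect_recovered(self):
        recs = _cohort(seed=6, n_f=100, n_n=100, confound=0.8)
        df = records_frame(recs)
        rng = np.random.default_rng(1)
        y = rng.normal(0, 1, len(df)) + 1.0 * df["faller"].to_numpy()
        feat = pd.DataFrame(
            {"participant_id": df.index, "condition": "EO_firm",
             "faller": df["faller"].to_numpy(), "m": y}
        )
        out = sensitivity_analyses(feat, recs, fit_propensity(recs))
        assert out.iloc[0]["adjusted_estimate"] == pytest.approx(1.0, abs=0.3)
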