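"""Survival tests: median split, KM hand examples, log-rank/Cox oracles."""

import numpy as np
import pandas as pd
import pytest

import _oracles
from glycomsi.survival import (
    compare_groups,
    cox_fit,
    dichotomize_at_median,
    km_estimate,
    logrank_test,
    stratify_by_value,
)
from glycomsi.synthetic import SurvivalSimSpec, generate_survival


class TestDichotomize:
    def test_plain_split(self):
        got = dichotomize_at_median(pd.Series([1, 2, 3, 4], index=list("abcd")))
        assert got.tolist() == ["low", "low", "high", "high"]

    def test_ties_at_median_go_low(self):
        got = dichotomize_at_median(pd.Series([1, 2, 2, 3]))
        assert got.tolist() == ["low", "low", "low", "high"]

    def test_all_equal_collapses_to_one_group(self):
        values = pd.Series([5.0] * 6)
        got = dichotomize_at_median(values)
        assert (got == "low").all()
        rec = pd.DataFrame({"time": range(1, 7), "event": 1, "group": got})
        with pytest.raises(ValueError, match="2 groups"):
            compare_groups(rec)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            dichotomize_at_median(pd.Series([], dtype=float))


class TestKaplanMeier:
    def test_worked_example_with_censoring(self):
        """times {5, 10+, 15}: S(5)=2/3, S(10)=2/3, S(15)=0."""
        curve = km_estimate([5, 10, 15], [1, 0, 1])
        assert curve.survival_at(5) == pytest.approx(2 / 3)
        assert curve.survival_at(10) == pytest.approx(2 / 3)
        assert curve.survival_at(15) == pytest.approx(0.0)

    def test_all_censored_stays_at_one(self):
        curve = km_estimate([3, 7, 9], [0, 0, 0])
        assert (curve.table["survival"] == 1.0).all()

    def test_no_censoring_equals_one_minus_ecdf(self, rng):
        t = rng.exponential(5, 40)
        curve = km_estimate(t, np.ones(40))
        for ti in t:
            assert curve.survival_at(ti) == pytest.approx(np.mean(t > ti), abs=1e-12)

    def test_matches_hand_product_limit(self, rng):
        t = np.round(rng.exponential(5, 30), 1)
        e = rng.integers(0, 2, 30)
        if e.sum() == 0:
            e[0] = 1
        curve = km_estimate(t, e)
        byhand = _oracles.km_by_hand(t, e)
        for ti, s in byhand.items():
            assert curve.survival_at(ti) == pytest.approx(s, abs=1e-12)

    def test_record_order_invariance(self, rng):
        t = rng.exponential(5, 25)
        e = rng.integers(0, 2, 25)
        e[0] = 1
        perm = rng.permutation(25)
        pd.testing.assert_frame_equal(
            km_estimate(t, e).table, km_estimate(t[perm], e[perm]).table
        )

    def test_trailing_censoring_adds_no_drop(self):
        """A record censored after the last event contributes no
        product-limit factor: the curve stays flat beyond the last event
        (it does enlarge earlier risk sets, so absolute levels shift)."""
        c2 = km_estimate([2, 4, 6, 9], [1, 1, 1, 0])
        assert c2.survival_at(9) == pytest.approx(c2.survival_at(6))
        assert c2.table.loc[9.0, "events"] == 0

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            km_estimate([-1, 2], [1, 1])


class TestLogrank:
    def test_identical_groups_give_zero(self):
        t = [1, 2, 3, 4]
        rec_t = t + t
        rec_e = [1, 1, 0, 1] * 2
        grp = [0] * 4 + [1] * 4
        res = logrank_test(rec_t, rec_e, grp)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_group_label_symmetry(self, rng):
        t = rng.exponential(5, 40)
        e = rng.integers(0, 2, 40)
        e[:2] = 1
        g = rng.integers(0, 2, 40)
        g[:2] = [0, 1]
        r1 = logrank_test(t, e, g)
        r2 = logrank_test(t, e, 1 - g)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-10)

    def test_equals_cox_score_statistic_without_ties(self, rng):
        """Score-test/log-rank equivalence on untied data."""
        for seed in range(20):
            r = np.random.default_rng(seed)
            n = int(r.integers(20, 120))
            t = r.exponential(5, n)  # continuous: ties a.s. absent
            e = r.integers(0, 2, n).astype(float)
            g = r.integers(0, 2, n).astype(float)
            if e.sum() < 2 or len(np.unique(g)) < 2:
                continue
            lr = logrank_test(t, e, g)
            score = _oracles.cox_score_statistic(t, e, g)
            assert lr.statistic == pytest.approx(score, abs=1e-6)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            logrank_test([1, 2], [1, 1], [0, 0])

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            logrank_test([1, 2], [0, 0], [0, 1])


class TestCox:
    @staticmethod
    def _toy(seed, n=8):
        r = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "time": np.round(r.exponential(5, n), 2),
                "event": np.r_[1, 1, r.integers(0, 2, n - 2)],
                "x": r.normal(0, 1, n).round(2),
            }
        )

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_partial_likelihood(self, seed):
        rec = self._toy(seed)
        res = cox_fit(rec, ["x"])
        beta_star = _oracles.maximize_breslow(rec["time"], rec["event"], rec["x"])
        assert abs(beta_star) < 7.5, "toy dataset hit the search boundary"
        assert res.summary["beta"].iloc[0] == pytest.approx(beta_star, abs=1e-4)

    def test_paired_copies_give_null(self):
        base = pd.DataFrame({"time": [2.0, 4, 6, 8], "event": [1, 1, 1, 1]})
        rec = pd.concat([base.assign(x=0.0), base.assign(x=1.0)], ignore_index=True)
        res = cox_fit(rec, ["x"])
        assert res.summary["beta"].iloc[0] == pytest.approx(0.0, abs=1e-8)
        assert res.summary["hr"].iloc[0] == pytest.approx(1.0, abs=1e-8)

    def test_scale_equivariance(self):
        rec = self._toy(3, n=40)
        b1 = cox_fit(rec, ["x"]).summary["beta"].iloc[0]
        rec2 = rec.assign(x=2 * rec["x"])
        b2 = cox_fit(rec2, ["x"]).summary["beta"].iloc[0]
        assert b2 == pytest.approx(b1 / 2, abs=1e-6)

    def test_wald_ci_brackets_hr(self):
        rec = self._toy(5, n=60)
        s = cox_fit(rec, ["x"]).summary
        assert s["ci_low"].iloc[0] <= s["hr"].iloc[0] <= s["ci_high"].iloc[0]
        assert s["ci_low"].iloc[0] > 0

    def test_separation_flagged_not_raised(self):
        # group 1 events all strictly before group 0: monotone likelihood
        rec = pd.DataFrame(
            {"time": [1, 2, 3, 10, 11, 12], "event": [1] * 6,
             "x": [1, 1, 1, 0, 0, 0]}
        )
        res = cox_fit(rec, ["x"])
        assert not res.converged

    def test_constant_covariate_rejected(self):
        rec = self._toy(1).assign(x=1.0)
        with pytest.raises(ValueError, match="constant"):
            cox_fit(rec, ["x"])

    def test_parameter_recovery_with_censoring(self):
        """True log-HR log(0.25), n=300, ~30% censoring: estimates center on
        the truth and 95% CIs cover it at roughly nominal rate."""
        true = np.log(0.25)
        betas, covered = [], 0
        reps = 25
        for seed in range(reps):
            rec = generate_survival(
                np.tile([0, 1], 150),
                SurvivalSimSpec(n=300, log_hr=true, censoring_rate=0.3, seed=seed),
            )
            res = cox_fit(rec, ["group"])
            betas.append(res.summary["beta"].iloc[0])
            lo, hi = res.summary["ci_low"].iloc[0], res.summary["ci_high"].iloc[0]
            covered += lo <= np.exp(true) <= hi
        assert np.mean(betas) == pytest.approx(true, abs=0.1)
        assert 0.85 <= covered / reps <= 1.0


class TestGroupComparison:
    def test_high_vs_low_orientation(self):
        r = np.random.default_rng(4)
        n = 200
        score = pd.Series(r.normal(0, 1, n), index=[f"s{i}" for i in range(n)])
        groups = (score > score.median()).astype(int).to_numpy()
        rec = generate_survival(
            groups, SurvivalSimSpec(n=n, log_hr=np.log(0.3), censoring_rate=0.2,
                                    seed=11),
        )
        rec["sample_id"] = score.index
        comp = stratify_by_value(rec, score)
        assert comp.cox.hr() < 1  # high scorers at lower hazard
        assert comp.logrank.p_value < 0.01
        assert set(comp.curves) == {"high", "low"}
        assert comp.group_sizes["high"] == comp.group_sizes["low"] == n // 2
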