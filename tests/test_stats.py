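import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.stats import studentized_range

from tactsim.stats import (age_adjusted_cohens_d, analysis_report,
                           correlate_bonferroni, group_comparison,
                           partial_eta_squared_from_ss)


def frame(groups_to_values, age=None):
    rows = []
    for g, vals in groups_to_values.items():
        for i, v in enumerate(vals):
            rows.append({"group": g, "y": float(v),
                         "age_years": age[g][i] if age else np.nan})
    return pd.DataFrame(rows)


class TestCohensD:
    def test_hand_oracle_two_groups(self):
        # pooled SD 1, mean difference 2
        df = frame({"A": [1, 2, 3], "B": [3, 4, 5]})
        res = group_comparison(df, "y", age_col=None)
        assert abs(res.contrast("A", "B").cohens_d) == pytest.approx(2.0)

    def test_identical_groups_give_zero(self):
        df = frame({"A": [1, 2, 3, 4], "B": [1, 2, 3, 4]})
        res = group_comparison(df, "y", age_col=None)
        assert res.contrast("A", "B").cohens_d == pytest.approx(0.0)

    def test_fast_path_agrees_with_model_contrast(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({
            "group": ["TDC"] * 40 + ["ADHD"] * 30,
            "y": np.r_[rng.normal(10, 3, 40), rng.normal(12, 3, 30)],
            "age_years": rng.normal(10, 1.2, 70),
        })
        d_fast = age_adjusted_cohens_d(df, "y", "ADHD")
        res = group_comparison(df, "y")
        assert d_fast == pytest.approx(res.contrast("TDC", "ADHD").cohens_d,
                                       rel=1e-10)


class TestOneWayOracle:
    """F, Tukey p and eta^2 match a from-scratch sums-of-squares computation."""

    data = {"A": [27.0, 31.0, 29.0, 30.0, 33.0],
            "B": [32.0, 34.0, 36.0, 38.0, 30.0],
            "C": [40.0, 39.0, 38.0, 44.0, 44.0]}

    @staticmethod
    def _oracle(data):
        all_vals = np.concatenate([np.asarray(v) for v in data.values()])
        grand = all_vals.mean()
        k = len(data)
        n = all_vals.size
        ss_between = sum(len(v) * (np.mean(v) - grand) ** 2
                         for v in data.values())
        ss_within = sum(((np.asarray(v) - np.mean(v)) ** 2).sum()
                        for v in data.values())
        df_b, df_w = k - 1, n - k
        F = (ss_between / df_b) / (ss_within / df_w)
        p = sps.f.sf(F, df_b, df_w)
        mse = ss_within / df_w
        tukey = {}
        for ga, gb in itertools.combinations(sorted(data), 2):
            va, vb = data[ga], data[gb]
            q = abs(np.mean(vb) - np.mean(va)) / math.sqrt(
                mse / 2 * (1 / len(va) + 1 / len(vb)))
            tukey[(ga, gb)] = studentized_range.sf(q, k, df_w)
        return F, p, ss_between, ss_within, tukey

    def test_matches_to_four_decimals(self):
        F, p, ssb, ssw, tukey = self._oracle(self.data)
        res = group_comparison(frame(self.data), "y", age_col=None)
        assert res.F == pytest.approx(F, abs=1e-4)
        assert res.p == pytest.approx(p, abs=1e-4)
        assert res.partial_eta_sq == pytest.approx(ssb / (ssb + ssw),
                                                   abs=1e-4)
        for pair, p_exp in tukey.items():
            assert res.contrast(*pair).p_tukey == pytest.approx(p_exp,
                                                                abs=1e-4)

    def test_tukey_never_below_raw_p(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            df = frame({g: rng.normal(0, 1, 8) for g in "ABCD"})
            res = group_comparison(df, "y", age_col=None)
            for c in res.contrasts:
                p_raw = 2 * sps.t.sf(abs(c.t), c.df)
                assert c.p_tukey >= p_raw - 1e-12


class TestPartialEtaSquared:
    def test_direct_ratio(self):
        assert partial_eta_squared_from_ss(4.0, 12.0) == pytest.approx(0.25)

    def test_null_term(self):
        assert partial_eta_squared_from_ss(0.0, 10.0) == 0.0

    def test_perfect_fit(self):
        assert partial_eta_squared_from_ss(10.0, 0.0) == 1.0

    def test_zero_variation_rejected(self):
        with pytest.raises(ValueError):
            partial_eta_squared_from_ss(0.0, 0.0)


class TestAgeAdjustment:
    def test_age_confound_removed(self):
        # group difference purely mediated by age: adjusted d should shrink
        rng = np.random.default_rng(9)
        age_a = rng.normal(9, 1, 100)
        age_b = rng.normal(11, 1, 100)
        df = pd.DataFrame({
            "group": ["TDC"] * 100 + ["ADHD"] * 100,
            "y": np.r_[2.0 * age_a, 2.0 * age_b] + rng.normal(0, 1, 200),
            "age_years": np.r_[age_a, age_b],
        })
        raw = group_comparison(df, "y", age_col=None)
        adj = group_comparison(df, "y")
        assert abs(adj.contrast("TDC", "ADHD").cohens_d) < \
            abs(raw.contrast("TDC", "ADHD").cohens_d) / 3

    def test_interaction_flag(self):
        rng = np.random.default_rng(2)
        age = rng.normal(10, 1.2, 200)
        grp = np.r_[np.zeros(100), np.ones(100)]
        y = 3.0 * age * grp + rng.normal(0, 1, 200)
        df = pd.DataFrame({"group": np.where(grp == 1, "B", "A"), "y": y,
                           "age_years": age})
        assert group_comparison(df, "y").interaction_flag

    def test_requires_two_populated_groups(self):
        df = frame({"A": [1.0, 2.0], "B": [3.0]})
        with pytest.raises(ValueError):
            group_comparison(df, "y", age_col=None)


class TestBonferroni:
    def test_perfect_linear_pair(self):
        m = pd.Series([1.0, 2.0, 3.0, 4.0], name="m")
        scales = pd.DataFrame({"s": [2.0, 4.0, 6.0, 8.0]})
        (res,) = correlate_bonferroni(m, scales, multiplier=1)
        assert res.r == pytest.approx(1.0)

    def test_cap_at_one(self):
        rng = np.random.default_rng(3)
        m = pd.Series(rng.normal(size=30))
        scales = pd.DataFrame({"s": rng.normal(size=30)})
        (res,) = correlate_bonferroni(m, scales, multiplier=9)
        assert res.p_bonferroni == min(1.0, res.p_raw * 9)
        assert res.p_bonferroni <= 1.0

    def test_monotone_in_multiplier(self):
        rng = np.random.default_rng(4)
        m = pd.Series(rng.normal(size=50))
        scales = pd.DataFrame({"s": m + rng.normal(size=50)})
        p2 = correlate_bonferroni(m, scales, 2)[0].p_bonferroni
        p7 = correlate_bonferroni(m, scales, 7)[0].p_bonferroni
        assert p7 >= p2

    def test_too_few_pairs_rejected(self):
        m = pd.Series([1.0, 2.0, np.nan, np.nan])
        scales = pd.DataFrame({"s": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ValueError):
            correlate_bonferroni(m, scales, 1)

    def test_zero_variance_rejected(self):
        m = pd.Series([1.0, 1.0, 1.0, 1.0])
        scales = pd.DataFrame({"s": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ValueError):
            correlate_bonferroni(m, scales, 1)


@pytest.fixture(scope="module")
def report(tiny_cohort_spec):
    from tactsim.cohort import replicate_cohort
    pframe, outcomes, quest = replicate_cohort(tiny_cohort_spec, 31)
    return analysis_report(pframe, outcomes, quest), pframe, outcomes


class TestAnalysisReport:
    def test_sixteen_group_comparisons(self, report):
        rep, _, outcomes = report
        n_protocols = outcomes["protocol_id"].nunique()
        assert len(rep["group_comparisons"]) == n_protocols * 4

    def test_six_contrasts_per_family(self, report):
        rep, _, _ = report
        counts = rep["contrasts"].groupby(["protocol", "outcome"]).size()
        assert (counts == 6).all()

    def test_adhd_screen_excludes_comorbid_group(self, report):
        rep, pframe, _ = report
        adhd_rows = rep["correlations"].query("screen == 'adhd'")
        n_adhd_only = (pframe["group"] == "ADHD").sum()
        assert (adhd_rows["n"] <= n_adhd_only).all()

    def test_asd_screen_population(self, report):
        rep, pframe, _ = report
        asd_rows = rep["correlations"].query("screen == 'asd'")
        n_asd = pframe["group"].isin(["ASD", "ASD+ADHD"]).sum()
        assert len(asd_rows) > 0
        assert (asd_rows["n"] <= n_asd).all()

    def test_multipliers_follow_instruments(self, report):
        rep, _, _ = report
        mult = rep["correlations"].groupby("instrument")["multiplier"].first()
        assert mult["spm"] == 7 and mult["seq"] == 9
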