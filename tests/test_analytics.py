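"""Assessment analytics: dispersion, correlation, Welch's ANOVA, power."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from edsense import analytics as an
from edsense.simulator import CohortConfig, simulate_cohort
from edsense.skill_graph import build_default_topology


def welch_oracle(groups):
    """Independently coded textbook Welch (1951) statistic."""
    ns = [len(g) for g in groups]
    means = [sum(g) / len(g) for g in groups]
    variances = [sum((x - m) ** 2 for x in g) / (len(g) - 1)
                 for g, m in zip(groups, means)]
    k = len(groups)
    w = [n / v for n, v in zip(ns, variances)]
    sw = sum(w)
    grand = sum(wi * mi for wi, mi in zip(w, means)) / sw
    num = sum(wi * (mi - grand) ** 2 for wi, mi in zip(w, means)) / (k - 1)
    a = sum((1 - wi / sw) ** 2 / (ni - 1) for wi, ni in zip(w, ns))
    f = num / (1 + 2 * (k - 2) / (k ** 2 - 1) * a)
    df2 = (k ** 2 - 1) / (3 * a)
    return f, k - 1, df2


class TestPerSkillStats:
    def test_constant_series_zero_variance(self):
        df = pd.DataFrame({"skill": ["a"] * 4, "speed": [2.0] * 4,
                           "accuracy": [50.0] * 4})
        out = an.per_skill_stats(df)
        assert out[0].speed_variance == 0 and out[0].accuracy_sd == 0

    def test_sd_is_sqrt_of_variance(self, rng):
        df = pd.DataFrame({"skill": np.repeat(list("abc"), 20),
                           "speed": rng.normal(size=60),
                           "accuracy": rng.normal(50, 10, size=60)})
        for row in an.per_skill_stats(df):
            assert row.speed_sd**2 == pytest.approx(row.speed_variance, abs=1e-9)
            assert row.accuracy_sd**2 == pytest.approx(row.accuracy_variance,
                                                       abs=1e-9)

    def test_matches_two_pass_oracle(self, rng):
        vals = rng.normal(3, 2, size=25)
        df = pd.DataFrame({"skill": "x", "speed": vals, "accuracy": vals * 2})
        row = an.per_skill_stats(df)[0]
        mean = sum(vals) / len(vals)
        oracle = sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)
        assert row.speed_variance == pytest.approx(oracle, abs=1e-9)

    def test_single_record_skill_omitted_with_warning(self):
        df = pd.DataFrame({"skill": ["a", "a", "b"], "speed": [1.0, 2.0, 3.0],
                           "accuracy": [1.0, 2.0, 3.0]})
        with pytest.warns(UserWarning, match="'b'"):
            out = an.per_skill_stats(df)
        assert [r.skill_name for r in out] == ["a"]


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        assert an.pearson(x, 2 * x + 1).r == pytest.approx(1.0)
        assert an.pearson(x, x).r == pytest.approx(1.0)

    def test_constant_series_raises(self):
        with pytest.raises(ValueError):
            an.pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @given(st.floats(0.1, 100), st.floats(-50, 50), st.booleans())
    def test_affine_invariance_up_to_sign(self, scale, shift, flip):
        x = np.arange(12.0)
        y = np.sin(x)
        base = an.pearson(x, y).r
        s = -scale if flip else scale
        transformed = an.pearson(s * x + shift, y).r
        assert transformed == pytest.approx(base if s > 0 else -base,
                                            abs=1e-9)

    def test_preassessment_trade_off_correlations(self):
        res = an.speed_accuracy_correlations()
        assert res["variance"].r == pytest.approx(-0.5176, abs=0.002)
        assert res["sd"].r == pytest.approx(-0.5034, abs=0.002)
        assert res["variance"].n == 11


class TestWelchAnova:
    def test_zero_variance_group_raises(self):
        with pytest.raises(ValueError):
            an.welch_anova([[1.0, 1.0, 1.0], [2.0, 3.0, 4.0]])

    def test_matches_independent_oracle_on_seeded_sets(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            k = int(rng.integers(2, 6))
            groups = [rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3),
                                 size=int(rng.integers(5, 30)))
                      for _ in range(k)]
            res = an.welch_anova(groups)
            f, df1, df2 = welch_oracle([list(g) for g in groups])
            assert res.F == pytest.approx(f, abs=1e-8)
            assert res.df1 == df1
            assert res.df2 == pytest.approx(df2, abs=1e-8)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        groups = [rng.normal(m, s, size=n)
                  for m, s, n in [(0, 1, 20), (0.8, 2.5, 15), (-0.5, 0.7, 30)]]
        df = pd.DataFrame({
            "y": np.concatenate(groups),
            "g": np.repeat(range(3), [len(g) for g in groups])})
        ref = pingouin.welch_anova(data=df, dv="y", between="g")
        res = an.welch_anova(groups)
        assert res.F == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        assert res.p_value == pytest.approx(float(ref["p_unc"].iloc[0]),
                                            rel=1e-6)

    def test_equal_means_give_large_p(self):
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(200):
            groups = [rng.normal(0, rng.uniform(0.5, 2), size=15)
                      for _ in range(3)]
            ps.append(an.welch_anova(groups).p_value)
        assert np.mean(ps) > 0.4 and np.mean([p > 0.5 for p in ps]) > 0.4

    def test_near_classic_anova_under_equal_variances_and_sizes(self):
        """With equal sizes and (exactly) equal sample variances the
        Welch statistic stays within 5% of the classic one-way F."""
        from scipy import stats
        rng = np.random.default_rng(13)
        for _ in range(20):
            k, n = int(rng.integers(3, 6)), int(rng.integers(15, 40))
            groups = []
            for _ in range(k):
                z = rng.normal(size=n)
                z = (z - z.mean()) / z.std(ddof=1)   # exact unit variance
                groups.append(z + rng.uniform(-1, 1))
            classic = stats.f_oneway(*groups).statistic
            welch = an.welch_anova(groups).F
            assert welch == pytest.approx(classic, rel=0.05)


class TestPowerPairedT:
    def test_reported_configuration(self):
        res = an.power_paired_t(0.56, 0.05, 0.95)
        assert res.N == 44
        assert res.delta == pytest.approx(3.7146, abs=1e-4)
        assert res.t_crit == pytest.approx(2.0167, abs=1e-4)
        assert res.achieved_power == pytest.approx(0.9526, abs=5e-4)
        assert res.delta == pytest.approx(0.56 * np.sqrt(res.N), abs=1e-6)

    def test_huge_effect_needs_minimum_n(self):
        assert an.power_paired_t(50.0, 0.05, 0.8).N == 2

    def test_achieved_power_at_least_target(self):
        for dz in (0.2, 0.4, 0.8):
            res = an.power_paired_t(dz, 0.05, 0.9)
            assert res.achieved_power >= 0.9
            # and N-1 would not have sufficed
            if res.N > 2:
                _, prev = an._paired_t_power(dz, res.N - 1, 0.05)
                assert prev < 0.9

    def test_monotone_in_effect_alpha_and_power(self):
        n = lambda dz, a, pw: an.power_paired_t(dz, a, pw).N
        assert n(0.7, 0.05, 0.95) <= n(0.56, 0.05, 0.95) <= n(0.4, 0.05, 0.95)
        assert n(0.56, 0.10, 0.95) <= n(0.56, 0.05, 0.95) <= n(0.56, 0.01, 0.95)
        assert n(0.56, 0.05, 0.80) <= n(0.56, 0.05, 0.95) <= n(0.56, 0.05, 0.99)

    def test_matches_statsmodels(self):
        smp = pytest.importorskip("statsmodels.stats.power")
        res = an.power_paired_t(0.56, 0.05, 0.95)
        ref = smp.TTestPower().power(effect_size=0.56, nobs=res.N,
                                     alpha=0.05, alternative="two-sided")
        assert res.achieved_power == pytest.approx(float(ref), abs=1e-6)

    def test_matches_monte_carlo(self):
        """Noncentral-t power agrees with simulating the paired t test."""
        from scipy import stats
        res = an.power_paired_t(0.56, 0.05, 0.95)
        rng = np.random.default_rng(99)
        draws = rng.normal(0.56, 1.0, size=(100_000, res.N))
        t = draws.mean(axis=1) / (draws.std(axis=1, ddof=1) / np.sqrt(res.N))
        mc = float(np.mean(np.abs(t) > res.t_crit))
        assert mc == pytest.approx(res.achieved_power, abs=0.01)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            an.power_paired_t(-1.0)
        with pytest.raises(ValueError):
            an.power_paired_t(0.5, alpha=1.5)


@pytest.fixture(scope="module")
def small_cohort():
    graph = build_default_topology()
    return simulate_cohort(graph, CohortConfig(n_learners=8, seed=21))


class TestSummarizeSessions:
    def test_counts_match_recount_oracle(self, small_cohort):
        table = an.summarize_sessions(small_cohort)
        row = table.set_index("metric").loc["Correct_Answers_Level"]
        pairs = {(id(l), r["skill_id"]) for l in small_cohort
                 for r in l.records}
        assert row["count"] == len(pairs)
        total_correct = sum(r["correct"] for l in small_cohort
                            for r in l.records)
        assert row["mean"] * row["count"] == pytest.approx(total_correct)

    def test_single_record_mean_min_max_coincide(self, small_cohort):
        from edsense.controller import SessionLog
        log = SessionLog(records=[dict(small_cohort[0].records[0],
                                       correct=True)])
        table = an.summarize_sessions([log]).set_index("metric")
        row = table.loc["Correct_Answers_Questions"]
        assert row["mean"] == row["min"] == row["max"]

    def test_empty_metric_reports_zero_count(self):
        from edsense.controller import SessionLog
        rec = {"skill_id": "s", "correct": True, "error_case": "correct"}
        table = an.summarize_sessions([SessionLog(records=[rec])])
        row = table.set_index("metric").loc["Specific_Wrong_Level"]
        assert row["count"] == 0 and np.isnan(row["mean"])


class TestMasteryDiscrimination:
    def test_beats_uninformed_baseline(self, small_cohort):
        out = an.mastery_discrimination(small_cohort)
        assert out["ranking_accuracy"] > 0.5
        assert out["brier"] < 0.25

    def test_requires_both_classes(self):
        from edsense.controller import SessionLog
        recs = [{"skill_id": "s", "posterior_after": 0.9, "mastered": True}]
        with pytest.raises(ValueError):
            an.mastery_discrimination([SessionLog(records=recs)])
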