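import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from narsent.errors import ValidationError
from narsent.stats import (
    bonferroni_screen,
    compare_groups,
    mann_whitney_u,
    mixed_anova,
    pearson_correlation,
    t_from_summaries,
    two_sample_t_power,
)


def brute_force_u(a, b):
    """Independent oracle: pairwise wins of a, half credit for ties."""
    return sum(
        1.0 if x > y else 0.5 if x == y else 0.0 for x in a for y in b
    )


class TestCompareGroups:
    def test_normal_samples_take_t_branch(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 30), rng.normal(0.3, 1, 30)
        res = compare_groups(a, b)
        assert res.test == "student_t"
        assert res.df == 58
        assert res.gate_normal and res.gate_homogeneous

    def test_forced_mann_whitney_no_overlap(self):
        res = compare_groups([1, 2, 3], [4, 5, 6], force="mann_whitney")
        assert res.test == "mann_whitney"
        assert res.statistic == 0.0  # brute force: no wins for first group

    def test_identical_samples_null(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = compare_groups(a, list(a))
        assert res.p > 0.99
        assert abs(res.effect) < 1e-12

    def test_degenerate_samples_error(self):
        with pytest.raises(ValidationError, match="degenerate"):
            compare_groups([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])

    def test_skewed_data_takes_mw_branch(self):
        rng = np.random.default_rng(2)
        a = rng.lognormal(0, 2, 40)
        b = rng.lognormal(0.5, 2, 40)
        res = compare_groups(a, b)
        assert res.test == "mann_whitney"
        assert res.z is not None
        assert 0.0 <= res.effect <= 1.0

    def test_small_n_rejected(self):
        with pytest.raises(ValidationError):
            compare_groups([1, 2], [3, 4, 5])

    def test_t_branch_consistent_with_summaries(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.normal(0, 1, rng.integers(5, 30))
            b = rng.normal(0.5, 1.5, rng.integers(5, 30))
            res = compare_groups(a, b, force="student_t")
            s = t_from_summaries(
                a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
            )
            assert res.statistic == pytest.approx(s.t, rel=1e-10)
            assert res.p == pytest.approx(s.p, rel=1e-10)
            assert res.effect == pytest.approx(s.d, rel=1e-10)


class TestMannWhitneyOracle:
    @settings(max_examples=300, deadline=None)
    @given(
        st.lists(st.integers(0, 5), min_size=3, max_size=6),
        st.lists(st.integers(0, 5), min_size=3, max_size=6),
    )
    def test_u_equals_pairwise_wins(self, a, b):
        assert mann_whitney_u(a, b) == pytest.approx(brute_force_u(a, b))

    def test_exhaustive_tiny_instances(self):
        # all 0/1 samples with n1 = n2 = 3: complete enumeration
        for a in itertools.product([0, 1], repeat=3):
            for b in itertools.product([0, 1], repeat=3):
                assert mann_whitney_u(a, b) == pytest.approx(brute_force_u(a, b))


class TestTFromSummaries:
    # printed book-task group summaries -> printed statistics
    @pytest.mark.parametrize(
        "m1,sd1,m2,sd2,t_exp,d_exp",
        [
            (1.08, 1.38, 2.32, 2.78, 2.00, 0.58),
            (13.00, 7.35, 18.36, 10.04, 2.15, 0.62),
            (13.24, 7.48, 18.48, 8.48, 2.32, 0.67),
            (68.24, 32.64, 94.12, 42.48, 2.42, 0.70),
        ],
    )
    def test_published_values(self, m1, sd1, m2, sd2, t_exp, d_exp):
        res = t_from_summaries(m1, sd1, 25, m2, sd2, 25)
        assert res.df == 48
        assert round(abs(res.t), 2) == t_exp
        assert round(abs(res.d), 2) == d_exp

    def test_identical_groups(self):
        res = t_from_summaries(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert res.t == 0 and res.d == 0

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValidationError):
            t_from_summaries(1, 0, 10, 2, 1, 10)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        res = pearson_correlation(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)

    def test_published_r2(self):
        # r = .657 squares to .43 at two decimals
        assert round(0.657**2, 2) == 0.43

    def test_orthogonal_vectors(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        assert pearson_correlation(x, y).r == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            pearson_correlation([1, 1, 1], [1, 2, 3])

    def test_r2_is_square(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=20), rng.normal(size=20)
        res = pearson_correlation(x, y)
        assert res.r2 == pytest.approx(res.r**2)


def _long_table(values):
    """values: dict (group, subject, task) -> value"""
    return pd.DataFrame(
        [
            {"subject": s, "group": g, "task": t, "value": v}
            for (g, s, t), v in values.items()
        ]
    )


class TestMixedAnova:
    def test_injected_task_effect(self):
        rng = np.random.default_rng(5)
        values = {}
        for g in ("ASD", "TD"):
            for i in range(10):
                base = rng.normal(10, 1)
                values[(g, f"{g}{i}", "book")] = base + 5 + rng.normal(0, 0.5)
                values[(g, f"{g}{i}", "picture")] = base + rng.normal(0, 0.5)
        res = mixed_anova(_long_table(values))
        assert res.task.p < 0.001
        assert res.group.p > 0.05
        assert res.sphericity_ok
        assert res.task.df_den == res.n_complete - 2
        assert res.posthoc["task_overall"] < 0.001

    def test_constant_values_give_zero_f(self):
        values = {
            (g, f"{g}{i}", t): 3.0
            for g in ("ASD", "TD")
            for i in range(3)
            for t in ("book", "picture")
        }
        res = mixed_anova(_long_table(values))
        assert res.task.F == 0 and res.group.F == 0 and res.interaction.F == 0

    def test_eta2_matches_manual_decomposition(self):
        # 6-subject toy table, hand-computable sums of squares
        values = {
            ("ASD", "s1", "book"): 10.0, ("ASD", "s1", "picture"): 6.0,
            ("ASD", "s2", "book"): 12.0, ("ASD", "s2", "picture"): 7.0,
            ("ASD", "s3", "book"): 11.0, ("ASD", "s3", "picture"): 5.0,
            ("TD", "s4", "book"): 14.0, ("TD", "s4", "picture"): 9.0,
            ("TD", "s5", "book"): 13.0, ("TD", "s5", "picture"): 10.0,
            ("TD", "s6", "book"): 15.0, ("TD", "s6", "picture"): 8.0,
        }
        df = _long_table(values)
        x = df["value"].to_numpy()
        grand = x.mean()
        ss_total = ((x - grand) ** 2).sum()
        # from-scratch task SS: balanced design, 6 observations per task
        ss_task = sum(
            len(sub) * (sub["value"].mean() - grand) ** 2
            for _, sub in df.groupby("task")
        )
        res = mixed_anova(df)
        assert res.task.eta2 == pytest.approx(ss_task / ss_total, rel=1e-9)
        assert res.task.df_den == 4  # 6 complete subjects - 2

    def test_incomplete_subjects_dropped(self):
        values = {
            (g, f"{g}{i}", t): float(i + (t == "book"))
            for g in ("ASD", "TD")
            for i in range(4)
            for t in ("book", "picture")
        }
        df = _long_table(values)
        df = df[~((df.subject == "ASD0") & (df.task == "picture"))]
        res = mixed_anova(df)
        assert res.n_complete == 7

    def test_too_few_complete_subjects(self):
        values = {("ASD", "s1", t): 1.0 for t in ("book", "picture")}
        values.update({("TD", "s2", t): 2.0 for t in ("book", "picture")})
        with pytest.raises(ValidationError):
            mixed_anova(_long_table(values))


class TestBonferroniScreen:
    @staticmethod
    def _table(rng, n=20, m=5, shift=0.0):
        data = {"group": ["ASD"] * n + ["TD"] * n}
        for j in range(m):
            data[f"v{j}"] = np.concatenate(
                [rng.normal(0, 1, n), rng.normal(shift, 1, n)]
            )
        return pd.DataFrame(data)

    def test_adjustment_is_p_times_m(self):
        rng = np.random.default_rng(6)
        table = self._table(rng, m=70)
        report = bonferroni_screen(table, [f"v{j}" for j in range(70)])
        assert report.threshold == pytest.approx(0.05 / 70)
        for e in report.entries:
            assert e.p_adjusted == pytest.approx(min(1.0, e.result.p * 70))

    def test_raw_p_01_with_70_vars_not_significant(self):
        # p = .01 times m = 70 adjusts to .70
        assert min(1.0, 0.01 * 70) == pytest.approx(0.70)

    def test_single_variable_identity(self):
        rng = np.random.default_rng(7)
        table = self._table(rng, m=1)
        report = bonferroni_screen(table, ["v0"])
        (e,) = report.entries
        assert e.p_adjusted == pytest.approx(min(1.0, e.result.p))

    def test_familywise_error_under_null(self):
        # simulation oracle: FWER of the screen stays at or below alpha
        rng = np.random.default_rng(8)
        reps, m, hits = 300, 5, 0
        for _ in range(reps):
            table = self._table(rng, n=12, m=m)
            report = bonferroni_screen(table, [f"v{j}" for j in range(m)])
            hits += bool(report.survivors)
        fwer = hits / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert fwer <= 0.05 + 2 * se

    def test_strong_effect_survives(self):
        rng = np.random.default_rng(9)
        table = self._table(rng, n=40, m=3, shift=2.0)
        report = bonferroni_screen(table, ["v0", "v1", "v2"])
        assert set(report.survivors) == {"v0", "v1", "v2"}


class TestPower:
    def test_monotone_in_n(self):
        powers = [two_sample_t_power(0.5, n) for n in (10, 25, 50, 100)]
        assert powers == sorted(powers)

    def test_alpha_at_null(self):
        assert two_sample_t_power(0.0, 25) == pytest.approx(0.05, abs=1e-9)
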