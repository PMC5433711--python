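"""The four two-sample tests and the assumption-driven selection rule."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ccdkit import (
    AnalysisConfig,
    DegenerateDataError,
    GroupData,
    TestName,
    classify_normality,
    levene,
    mann_whitney_u,
    select_and_run,
    student_t,
    welch_t,
    welch_u,
)


def brute_force_mw_p(a, b):
    """Exact two-sided Mann-Whitney p by enumerating all group assignments.

    Independent of any U-distribution recursion: pools the data, walks
    every C(n1+n2, n1) split, and counts splits at least as extreme
    (distance of U from its null center) as the observed one.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n1, n2 = len(a), len(b)
    center = n1 * n2 / 2.0

    def u_of(idx):
        x = pooled[list(idx)]
        y = np.delete(pooled, list(idx))
        return sum((xi > y).sum() + 0.5 * (xi == y).sum() for xi in x)

    u_obs = u_of(range(n1))
    hits = total = 0
    for idx in itertools.combinations(range(n1 + n2), n1):
        total += 1
        if abs(u_of(idx) - center) >= abs(u_obs - center) - 1e-12:
            hits += 1
    return hits / total


class TestStudentT:
    def test_identical_samples_null(self):
        r = student_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0.0 and r.p == 1.0 and r.df == 4

    def test_hand_evaluated_pooled_formula(self):
        # pooled variance 1, se = sqrt(2/3): t = -3/sqrt(2/3)
        r = student_t([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        t_hand = -3.0 / math.sqrt(2.0 / 3.0)
        assert r.statistic == pytest.approx(t_hand, abs=1e-12)
        assert r.df == 4
        assert r.p == pytest.approx(2 * stats.t.sf(abs(t_hand), 4), abs=1e-12)
        assert r.p == pytest.approx(0.0213, abs=5e-4)

    def test_zero_pooled_variance_degenerate(self):
        with pytest.raises(DegenerateDataError):
            student_t([2.0, 2.0], [2.0, 2.0])


class TestWelchT:
    def test_reduces_to_student_for_equal_n_equal_var(self):
        a, b = [1.0, 2.0, 3.0], [11.0, 12.0, 13.0]
        rs, rw = student_t(a, b), welch_t(a, b)
        assert rw.statistic == pytest.approx(rs.statistic, abs=1e-12)
        assert rw.df == pytest.approx(4.0, abs=1e-12)
        assert rw.p == pytest.approx(rs.p, abs=1e-12)

    def test_independent_formula_evaluation(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([10.0, 20.0, 30.0, 40.0])
        va, vb = a.var(ddof=1) / 4, b.var(ddof=1) / 4
        t_hand = (a.mean() - b.mean()) / math.sqrt(va + vb)
        df_hand = (va + vb) ** 2 / (va**2 / 3 + vb**2 / 3)
        r = welch_t(a, b)
        assert r.statistic == pytest.approx(t_hand, abs=1e-10)
        assert r.df == pytest.approx(df_hand, abs=1e-10)
        assert r.p == pytest.approx(2 * stats.t.sf(abs(t_hand), df_hand), abs=1e-10)

    def test_zero_variance_degenerate(self):
        with pytest.raises(DegenerateDataError):
            welch_t([2.0, 2.0], [1.0, 3.0])


class TestMannWhitney:
    @pytest.mark.parametrize("a,b,u,p", [
        ([1.0, 2.0], [3.0, 4.0], 0.0, 2 / 6),
        ([1.0, 3.0], [2.0, 4.0], 1.0, 4 / 6),
    ])
    def test_exact_small_sample_values(self, a, b, u, p):
        r = mann_whitney_u(a, b)
        assert r.statistic == u
        assert r.p == pytest.approx(p, abs=1e-12)
        assert "exact" in r.method_detail

    @given(st.lists(st.integers(0, 10_000), min_size=6, max_size=10, unique=True))
    @settings(deadline=None, max_examples=40)
    def test_exact_p_equals_enumeration(self, pool):
        n1 = len(pool) // 2
        a, b = [float(v) for v in pool[:n1]], [float(v) for v in pool[n1:]]
        assert mann_whitney_u(a, b).p == pytest.approx(brute_force_mw_p(a, b),
                                                       abs=1e-12)

    def test_ties_force_asymptotic(self):
        r = mann_whitney_u([1.0, 2.0, 2.0], [2.0, 3.0, 4.0])
        assert "tie" in r.method_detail

    def test_large_sample_asymptotic(self):
        rng = np.random.default_rng(0)
        r = mann_whitney_u(rng.normal(size=15), rng.normal(size=15))
        assert "asymptotic" in r.method_detail or "approximation" in r.method_detail

    def test_monotone_transform_invariance(self):
        a, b = [0.1, 0.5, 0.9], [0.3, 0.7, 1.4]
        r0 = mann_whitney_u(a, b)
        r1 = mann_whitney_u(np.exp(a), np.exp(b))
        assert (r0.statistic, r0.p) == (r1.statistic, r1.p)


class TestWelchU:
    def test_identical_samples_null(self):
        r = welch_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0.0 and r.p == 1.0

    def test_hand_evaluated_on_ranks(self):
        # ranks {1,2} vs {3,4}: Welch t = -2/sqrt(1/2+1/2) = -2.828, df = 2
        r = welch_u([1.0, 2.0], [3.0, 4.0])
        assert r.statistic == pytest.approx(-2 * math.sqrt(2), abs=1e-12)
        assert r.df == pytest.approx(2.0, abs=1e-12)
        assert r.p == pytest.approx(2 * stats.t.sf(2 * math.sqrt(2), 2), abs=1e-12)
        assert r.p == pytest.approx(0.106, abs=5e-4)

    def test_monotone_transform_invariance(self):
        a, b = [0.2, 1.0, 2.5, 0.4], [0.9, 3.0, 5.0, 1.1]
        r0, r1 = welch_u(a, b), welch_u(np.exp(a), np.exp(b))
        assert (r0.statistic, r0.df, r0.p) == (r1.statistic, r1.df, r1.p)

    def test_all_identical_pooled_degenerate(self):
        with pytest.raises(DegenerateDataError):
            welch_u([7.0, 7.0], [7.0, 7.0])


@pytest.mark.parametrize("fn", [student_t, welch_t, welch_u])
def test_t_family_symmetry(fn, normal_pair):
    a, b = normal_pair
    r_ab, r_ba = fn(a, b), fn(b, a)
    assert r_ab.p == pytest.approx(r_ba.p, abs=1e-12)
    assert r_ab.statistic == pytest.approx(-r_ba.statistic, abs=1e-12)


def test_mann_whitney_symmetry(normal_pair):
    a, b = normal_pair
    assert mann_whitney_u(a, b).p == pytest.approx(mann_whitney_u(b, a).p, abs=1e-12)


class TestSelectAndRun:
    """All four branches of the selection table on constructed fixtures."""

    # deterministic samples (seeded): two clean normals; a gross lognormal
    NORM_A = np.random.default_rng(2).normal(0.0, 1.0, 10)
    NORM_B = np.random.default_rng(3).normal(0.0, 1.0, 10)
    NORM_WIDE = np.random.default_rng(3).normal(0.0, 8.0, 10)
    SKEWED = np.exp(np.random.default_rng(0).normal(0.0, 2.0, 10))

    def _run(self, a_vals, b_vals):
        cfg = AnalysisConfig()
        a = GroupData(label="a", values=tuple(a_vals))
        b = GroupData(label="b", values=tuple(b_vals))
        va = classify_normality(a.values, cfg)
        vb = classify_normality(b.values, cfg)
        var = levene(a.values, b.values, cfg)
        return select_and_run(a, b, va, vb, var, cfg), va, vb, var

    def test_both_normal_similar_variance_student(self):
        r, va, vb, var = self._run(self.NORM_A, self.NORM_B)
        assert va.is_normal and vb.is_normal and var.similar_variance
        assert r.test_name is TestName.STUDENT_T

    def test_both_normal_dissimilar_variance_welch(self):
        r, va, vb, var = self._run(self.NORM_A, self.NORM_WIDE)
        assert va.is_normal and vb.is_normal and not var.similar_variance
        assert r.test_name is TestName.WELCH_T

    def test_non_normal_similar_variance_mann_whitney(self):
        scaled = self.SKEWED / self.SKEWED.std(ddof=0)
        r, va, vb, var = self._run(self.NORM_A, scaled)
        assert not vb.is_normal and var.similar_variance
        assert r.test_name is TestName.MANN_WHITNEY_U

    def test_non_normal_dissimilar_variance_welch_u(self):
        r, va, vb, var = self._run(self.NORM_A, self.SKEWED)
        assert not vb.is_normal and not var.similar_variance
        assert r.test_name is TestName.WELCH_U

    def test_welch_u_agrees_with_asymptotic_mw_large_samples(self):
        rng = np.random.default_rng(31)
        a, b = rng.normal(0, 1, 40), rng.normal(0.3, 1, 40)
        p_wu = welch_u(a, b).p
        p_mw = mann_whitney_u(a, b).p
        assert abs(p_wu - p_mw) < 0.02
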