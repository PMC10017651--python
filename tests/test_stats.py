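"""Cohort statistics: classifier rule, exact tests vs brute-force oracles,
Spearman bands, summary tables."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import rankdata

from lungshrink.stats import (
    PFTRecord,
    classify_cohort,
    classify_functional,
    cohort_table,
    correlate_cohort,
    correlation_band,
    fisher_exact,
    mann_whitney,
    spearman,
)


def record(d_fvc=0.0, d_dlco=0.0, fvc0=90.0, dlco0=60.0):
    return PFTRecord(
        patient_id="p",
        vc_pct_base=85.0, vc_pct_follow=85.0,
        fvc_pct_base=fvc0, fvc_pct_follow=fvc0 + d_fvc,
        tlc_pct_base=70.0, tlc_pct_follow=70.0,
        dlco_pct_base=dlco0, dlco_pct_follow=dlco0 + d_dlco,
    )


class TestClassifier:
    @pytest.mark.parametrize(
        "d_fvc,d_dlco,expected",
        [
            (-12.0, 0.0, "deteriorated"),
            (-5.0, -5.0, "stable"),
            (-10.0, 0.0, "deteriorated"),  # boundary FVC decline is inclusive
            (-9.5, 0.0, "stable"),
            (0.0, -15.0, "deteriorated"),  # boundary DLco decline is inclusive
            (0.0, -14.5, "stable"),
            (5.0, 5.0, "stable"),
            (-10.0, -15.0, "deteriorated"),
        ],
    )
    def test_decline_rule(self, d_fvc, d_dlco, expected):
        assert classify_functional(record(d_fvc, d_dlco)) == expected

    def test_relative_mode_differs(self):
        # 9-point drop from 60 is a 15% relative decline but not absolute
        rec = record(d_fvc=0.0, d_dlco=-9.0, dlco0=60.0)
        assert classify_functional(rec) == "stable"
        assert classify_functional(rec, relative=True) == "deteriorated"

    def test_missing_value_names_field(self):
        with pytest.raises(ValueError, match="dlco_pct_follow"):
            PFTRecord(
                patient_id="p",
                vc_pct_base=85, vc_pct_follow=85,
                fvc_pct_base=90, fvc_pct_follow=90,
                tlc_pct_base=70, tlc_pct_follow=70,
                dlco_pct_base=60, dlco_pct_follow=float("nan"),
            )


def mw_permutation_oracle(a, b):
    """Full enumeration of group assignments; two-sided p from the
    symmetric U statistic."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    N = n1 * len(b)

    def u_stat(idx):
        x = pooled[list(idx)]
        y = np.delete(pooled, list(idx))
        return sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)

    u_obs = min(u_stat(range(n1)), N - u_stat(range(n1)))
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        u = u_stat(idx)
        if min(u, N - u) <= u_obs + 1e-12:
            count += 1
        total += 1
    return count / total


class TestMannWhitney:
    def test_identical_samples_give_p_one(self):
        _, p = mann_whitney([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert p == 1.0

    def test_fully_separated_small_samples(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_p_matches_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=rng.integers(3, 7))
        b = rng.normal(size=rng.integers(3, 7))
        _, p = mann_whitney(a, b)
        assert p == pytest.approx(mw_permutation_oracle(a, b), abs=1e-10)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


def fisher_hypergeom_oracle(table):
    """Sum of hypergeometric probabilities <= the observed table's."""
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(k):
        return (
            math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1)
        )

    p_obs = prob(a)
    return sum(
        prob(k)
        for k in range(max(0, c1 - r2), min(r1, c1) + 1)
        if prob(k) <= p_obs * (1 + 1e-9)
    )


class TestFisher:
    def test_balanced_table_p_one(self):
        assert fisher_exact([[1, 1], [1, 1]]) == 1.0

    def test_diagonal_table_closed_form(self):
        assert fisher_exact([[5, 0], [0, 5]]) == pytest.approx(2 / math.comb(10, 5))

    @pytest.mark.parametrize(
        "table",
        [
            [[23, 2], [21, 23]],  # morphologic worsening by functional group
            [[3, 7], [5, 2]],
            [[10, 0], [2, 8]],
            [[4, 4], [4, 4]],
        ],
    )
    def test_matches_hypergeometric_enumeration(self, table):
        assert fisher_exact(table) == pytest.approx(
            fisher_hypergeom_oracle(table), rel=1e-9
        )

    def test_bad_table_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, 2, 3], [4, 5, 6]])


class TestSpearman:
    def test_perfect_monotone(self):
        r = spearman([1, 2, 3, 4, 5], [10, 100, 1000, 1e4, 1e5])
        assert r.r == pytest.approx(1.0)
        assert r.band == "very strong"

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_rank_then_pearson_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=7)
        y = rng.normal(size=7)
        r = spearman(x, y)
        oracle = np.corrcoef(rankdata(x), rankdata(y))[0, 1]
        assert r.r == pytest.approx(oracle, abs=1e-12)

    @given(
        xs=st.lists(
            st.integers(-10**6, 10**6), min_size=5, max_size=30, unique=True
        ),
        seed=st.integers(0, 100),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_invariant_to_monotone_transforms(self, xs, seed):
        rng = np.random.default_rng(seed)
        ys = rng.normal(size=len(xs))
        xs = np.asarray(xs, dtype=float)
        r0 = spearman(xs, ys).r
        r1 = spearman(xs**3, ys).r  # strictly monotone in x
        r2 = spearman(xs, 2 * ys + 1).r
        assert r1 == pytest.approx(r0, abs=1e-12)
        assert r2 == pytest.approx(r0, abs=1e-12)

    @pytest.mark.parametrize(
        "r,band",
        [
            (0.1, "poor"),
            (0.2, "weak"),
            (0.394, "weak"),
            (0.438, "moderate"),
            (-0.438, "moderate"),
            (0.6, "strong"),
            (0.79, "strong"),
            (0.85, "very strong"),
        ],
    )
    def test_band_assignment(self, r, band):
        assert correlation_band(r) == band


class TestCohortTables:
    @pytest.fixture
    def cohort(self):
        rng = np.random.default_rng(0)
        n = 30
        group = np.array(["stable"] * 15 + ["deteriorated"] * 15)
        mean_lj = np.where(group == "stable", 0.0, -0.1) + 0.02 * rng.standard_normal(n)
        return pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(n)],
                "functional_group": group,
                "mean_logjac": mean_lj,
                "worsened": group == "deteriorated",
                "fvc_pct_base": rng.normal(88, 15, n),
            }
        )

    def test_group_table_layout_and_p(self, cohort):
        table = cohort_table(
            cohort, "functional_group", ["mean_logjac", "fvc_pct_base"], ["worsened"]
        )
        assert set(table["characteristic"]) == {
            "mean_logjac", "fvc_pct_base", "worsened",
        }
        p_lj = float(table.loc[table.characteristic == "mean_logjac", "p_value"].iloc[0])
        assert p_lj < 0.001  # the built-in group difference is detected
        assert "(" in table["all"].iloc[0]

    def test_correlate_cohort_skips_constant_columns(self, cohort):
        cohort["const"] = 1.0
        res = correlate_cohort(cohort, "mean_logjac", ["fvc_pct_base", "const"])
        assert [r.y_name for r in res] == ["fvc_pct_base"]

    def test_classify_cohort_vectorized(self):
        df = pd.DataFrame(
            {
                "patient_id": ["a", "b"],
                "vc_pct_base": [85, 85], "vc_pct_follow": [85, 85],
                "fvc_pct_base": [90, 90], "fvc_pct_follow": [78, 88],
                "tlc_pct_base": [70, 70], "tlc_pct_follow": [70, 70],
                "dlco_pct_base": [60, 60], "dlco_pct_follow": [60, 58],
            }
        )
        assert list(classify_cohort(df)) == ["deteriorated", "stable"]
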