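"""Nonparametric tests, Bonferroni, chi-square and ICC agreement,
validated against scipy's exact methods and hand-computed ANOVA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from chorobin.cohort_stats import (bonferroni, chi_square_2x2,
                                   icc_oneway_random,
                                   icc_twoway_mixed_absolute, mann_whitney_u,
                                   run_study_comparisons,
                                   wilcoxon_signed_rank)


# --- Wilcoxon signed-rank ---------------------------------------------------

def test_wilcoxon_three_positive_differences():
    res = wilcoxon_signed_rank([2, 4, 6], [1, 2, 3], mode="exact")
    assert res.statistic == 6.0
    assert res.p_value == pytest.approx(0.25)


def test_wilcoxon_identical_pairs_flagged():
    res = wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])
    assert res.p_value == 1.0
    assert "zero" in res.note


def test_wilcoxon_antisymmetric_differences():
    res = wilcoxon_signed_rank([5, 8], [8, 5], mode="exact")
    assert res.p_value == 1.0


@pytest.mark.parametrize("seed", range(8))
def test_wilcoxon_exact_matches_scipy_on_tie_free_data(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 11))
    d = rng.normal(0.3, 1.0, size=n)
    d = d[d != 0]
    mine = wilcoxon_signed_rank(d, np.zeros_like(d), mode="exact")
    ref = sps.wilcoxon(d, alternative="two-sided", method="exact")
    assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-12)


def test_wilcoxon_exact_and_approx_agree_at_n15():
    rng = np.random.default_rng(42)
    d = rng.normal(0.4, 1.0, size=15)
    exact = wilcoxon_signed_rank(d, np.zeros_like(d), mode="exact")
    approx = wilcoxon_signed_rank(d, np.zeros_like(d), mode="normal-approx")
    assert abs(exact.p_value - approx.p_value) <= 0.02


def test_wilcoxon_exact_handles_ties_by_midranks():
    # |d| = {1, 1, 2}: midranks {1.5, 1.5, 3}; enumeration stays exact
    res = wilcoxon_signed_rank([2, 2, 3], [1, 1, 1], mode="exact")
    assert res.statistic == 6.0
    assert res.p_value == pytest.approx(0.25)


# --- Mann-Whitney U ---------------------------------------------------------

def test_mwu_fully_separated_groups():
    res = mann_whitney_u([1, 2, 3], [4, 5, 6], mode="exact")
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(0.10)


def test_mwu_identical_multisets():
    res = mann_whitney_u([1, 2, 3], [1, 2, 3], mode="exact")
    assert res.p_value == 1.0


def test_mwu_shift_invariance_of_u():
    a, b = [1.0, 5.0, 2.0], [3.0, 4.0]
    u1 = mann_whitney_u(a, b).statistic
    u2 = mann_whitney_u([x + 100 for x in a], [x + 100 for x in b]).statistic
    assert u1 == u2


@pytest.mark.parametrize("seed", range(8))
def test_mwu_exact_matches_scipy_on_tie_free_data(seed):
    rng = np.random.default_rng(100 + seed)
    na, nb = int(rng.integers(2, 6)), int(rng.integers(2, 7))
    a = rng.normal(0.0, 1.0, size=na)
    b = rng.normal(0.5, 1.0, size=nb)
    mine = mann_whitney_u(a, b, mode="exact")
    ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-12)


# --- Bonferroni -------------------------------------------------------------

def test_bonferroni_examples():
    assert bonferroni([0.01], m=3) == [pytest.approx(0.03)]
    assert bonferroni([0.5], m=3) == [1.0]
    assert bonferroni([0.2], m=1) == [pytest.approx(0.2)]
    with pytest.raises(ValueError):
        bonferroni([0.1, 0.2], m=1)


def test_bonferroni_never_decreases():
    rng = np.random.default_rng(0)
    ps = rng.uniform(0, 1, size=20)
    adj = bonferroni(ps, m=20)
    assert all(a >= p for a, p in zip(adj, ps))
    assert all(0 <= a <= 1 for a in adj)


# --- chi-square -------------------------------------------------------------

def test_chi_square_on_cohort_sex_table():
    res = chi_square_2x2([[31, 9], [26, 14]])
    assert round(res.p_value, 2) == 0.22


def test_chi_square_identical_rows():
    res = chi_square_2x2([[10, 5], [10, 5]])
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


def test_chi_square_diagonal_table_closed_form():
    # n (ad - bc)^2 / (row1 row2 col1 col2) = 20 * 100^2 / 10^4 = 20
    res = chi_square_2x2([[10, 0], [0, 10]])
    assert res.statistic == pytest.approx(20.0)
    assert res.p_value == pytest.approx(sps.chi2.sf(20.0, 1))


def test_chi_square_zero_marginal_rejected():
    with pytest.raises(ValueError, match="marginal"):
        chi_square_2x2([[0, 0], [5, 5]])


# --- ICC --------------------------------------------------------------------

def _icc1_by_hand(m):
    """One-way ANOVA mean squares -> ICC(1,1)."""
    m = np.asarray(m, float)
    n, k = m.shape
    grand = m.mean()
    msb = k * ((m.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msw = ((m - m.mean(axis=1, keepdims=True)) ** 2).sum() / (n * (k - 1))
    return (msb - msw) / (msb + (k - 1) * msw)


def _icc2_by_hand(m):
    """Two-way ANOVA mean squares -> absolute-agreement single-measure ICC."""
    m = np.asarray(m, float)
    n, k = m.shape
    grand = m.mean()
    msr = k * ((m.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((m.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sst = ((m - grand) ** 2).sum()
    sse = sst - (msr * (n - 1) + msc * (k - 1))
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


def test_icc1_perfect_agreement():
    m = np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0], [9.0, 9.0]])
    res = icc_oneway_random(m)
    assert res.icc == pytest.approx(1.0)


def test_icc1_matches_hand_anova_on_toy_matrix():
    m = np.array([[9.0, 10.0], [6.0, 5.0], [8.0, 7.0], [2.0, 4.0]])
    res = icc_oneway_random(m)
    assert res.icc == pytest.approx(_icc1_by_hand(m), abs=1e-9)
    lo, hi = res.ci95
    assert lo <= res.icc <= hi


def test_icc1_near_zero_for_independent_noise():
    rng = np.random.default_rng(1)
    m = rng.normal(size=(500, 2))
    assert abs(icc_oneway_random(m).icc) < 0.15


def test_icc2_perfect_and_toy_matrix():
    same = np.tile(np.array([[1.0], [4.0], [6.0], [9.0], [2.0]]), (1, 2))
    assert icc_twoway_mixed_absolute(same).icc == pytest.approx(1.0)
    m = np.array([[7.0, 9.0], [5.0, 6.0], [8.0, 7.0], [3.0, 5.0], [9.0, 9.0]])
    res = icc_twoway_mixed_absolute(m)
    assert res.icc == pytest.approx(_icc2_by_hand(m), abs=1e-9)


def test_absolute_agreement_penalises_rater_offset():
    rng = np.random.default_rng(2)
    a = rng.normal(10, 3, size=60)
    m = np.column_stack([a, a + 5.0])          # systematic offset
    absolute = icc_twoway_mixed_absolute(m).icc
    consistency = _icc1_by_hand(m - m.mean(axis=0))  # offset removed
    assert absolute < consistency
    assert absolute < 0.9


def test_icc_estimators_recover_variance_components():
    """ICC approximates sigma_s^2 / (sigma_s^2 + sigma_e^2) on simulated
    data with known components (n = 500 subjects, 2 raters)."""
    rng = np.random.default_rng(3)
    sigma_s2, sigma_e2 = 4.0, 1.0
    subj = rng.normal(0, np.sqrt(sigma_s2), size=(500, 1))
    m = subj + rng.normal(0, np.sqrt(sigma_e2), size=(500, 2))
    truth = sigma_s2 / (sigma_s2 + sigma_e2)
    assert abs(icc_oneway_random(m).icc - truth) <= 0.05
    assert abs(icc_twoway_mixed_absolute(m).icc - truth) <= 0.05


def test_icc_requires_complete_matrix():
    with pytest.raises(ValueError):
        icc_oneway_random(np.array([[1.0, np.nan], [2.0, 3.0]]))
    with pytest.raises(ValueError):
        icc_twoway_mixed_absolute(np.ones((1, 2)))


# --- study-level battery ----------------------------------------------------

def _toy_cohort(n=8, effect=0.0, seed=0, ia=False):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        base = rng.normal(10, 2)
        rows.append({"case_id": f"CSC-{i:02d}", "group": "CSC",
                     "patient_id": i, "area": base + effect + rng.normal(0, 1)})
        rows.append({"case_id": f"fellow-{i:02d}", "group": "fellow",
                     "patient_id": i, "area": base + rng.normal(0, 1)})
        rows.append({"case_id": f"control-{i:02d}", "group": "control",
                     "patient_id": 100 + i, "area": rng.normal(10, 2)})
    df = pd.DataFrame(rows)
    if ia:
        grades = ["very severe", "severe", "moderate", "mild"]
        df.loc[df["group"] == "CSC", "ia_grade"] = [
            grades[i % 4] for i in range(n)]
    return df


def test_report_structure_and_bonferroni_family():
    report = run_study_comparisons(_toy_cohort(ia=True), measurements=["area"])
    res = report["group_comparisons"]["area"]
    assert set(res) == {"csc_vs_fellow", "csc_vs_control", "fellow_vs_control"}
    for r in res.values():
        assert 0 <= r.p_value <= 1
        assert r.adjusted_p == pytest.approx(min(1.0, 3 * r.p_value))
    assert "area" in report["ia_comparisons"]


def test_missing_group_is_an_error():
    df = _toy_cohort()
    with pytest.raises(ValueError, match="control"):
        run_study_comparisons(df[df["group"] != "control"], measurements=["area"])


def test_unpaired_rows_are_an_error():
    df = _toy_cohort()
    df = df.drop(df[(df["group"] == "fellow")].index[:2])
    with pytest.raises(ValueError, match="paired"):
        run_study_comparisons(df, measurements=["area"])


def test_family_wise_type_one_error_controlled():
    """Under the null, the Bonferroni-corrected family rejects at most
    ~5% of replicates."""
    hits = 0
    n_rep = 300
    for rep in range(n_rep):
        report = run_study_comparisons(_toy_cohort(n=10, effect=0.0, seed=rep),
                                       measurements=["area"])
        res = report["group_comparisons"]["area"]
        if any(r.adjusted_p < 0.05 for r in res.values()):
            hits += 1
    assert hits / n_rep <= 0.05 + 2.6 * np.sqrt(0.05 * 0.95 / n_rep)


def test_power_under_large_effect():
    """A large CSC shift is detected in nearly every replicate."""
    hits = 0
    n_rep = 60
    for rep in range(n_rep):
        report = run_study_comparisons(
            _toy_cohort(n=40, effect=3.0, seed=1000 + rep),
            measurements=["area"])
        if report["group_comparisons"]["area"]["csc_vs_control"].adjusted_p < 0.05:
            hits += 1
    assert hits / n_rep > 0.9
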