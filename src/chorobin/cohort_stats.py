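"""Statistical battery for cohort comparison and rater agreement.

Implements the tests used to analyse binarized choroid measurements:
paired Wilcoxon signed-rank (CSC vs fellow eyes of the same patients),
Mann-Whitney U (between-subject contrasts and the IA hyperpermeability
dichotomy), Bonferroni correction over the three pairwise group
contrasts, Pearson chi-square on 2x2 demographics tables, and
intraclass correlation coefficients (one-way random for intra-rater,
two-way absolute-agreement single-measure for inter-rater designs).

Small-sample exact p-values are computed by literal enumeration —
all 2^n sign assignments for the signed-rank test, all C(n, n_a) group
labelings for the U test — with midranks, so ties are handled exactly.
Larger samples fall back to the tie-corrected normal approximations in
:mod:`scipy.stats`.  ICC point estimates and F-based confidence
intervals are delegated to :func:`pingouin.intraclass_corr`.

All tests are two-sided.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "ICCResult",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "bonferroni",
    "chi_square_2x2",
    "icc_oneway_random",
    "icc_twoway_mixed_absolute",
    "run_study_comparisons",
]

#: sample-size cutoffs below which exact enumeration is used by default
EXACT_WILCOXON_N = 15
EXACT_MWU_N = 12

#: IA hyperpermeability grades pooled into the "high" group
IA_HIGH_GRADES = frozenset({"very severe", "severe"})


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: int
    adjusted_p: float | None = None
    note: str | None = None

    def to_dict(self) -> dict:
        return {"statistic": self.statistic, "p_value": self.p_value,
                "adjusted_p": self.adjusted_p, "method": self.method,
                "n": self.n, "note": self.note}


@dataclass
class ICCResult:
    icc: float
    ci95: tuple[float, float]
    p_value: float
    method: str
    n_subjects: int
    n_raters: int

    def to_dict(self) -> dict:
        return {"icc": self.icc, "ci95": list(self.ci95),
                "p_value": self.p_value, "method": self.method,
                "n_subjects": self.n_subjects, "n_raters": self.n_raters}


def _two_sided_from_dist(dist: np.ndarray, observed: float) -> float:
    """Two-sided p from an enumerated null distribution: twice the
    smaller tail (inclusive), capped at 1."""
    lo = np.mean(dist <= observed + 1e-12)
    hi = np.mean(dist >= observed - 1e-12)
    return float(min(1.0, 2.0 * min(lo, hi)))


def wilcoxon_signed_rank(values_a, values_b, mode: str = "auto") -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped before ranking.  ``mode="exact"``
    enumerates all 2^n sign assignments of the midranked absolute
    differences (exact under ties); ``mode="normal-approx"`` uses the
    tie-corrected normal approximation; ``mode="auto"`` picks exact for
    n <= 15 after zero removal.  The reported statistic is W+, the sum
    of ranks of positive differences.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D arrays")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult(statistic=0.0, p_value=1.0, n=0,
                          method="wilcoxon signed-rank",
                          note="all differences zero; no signal")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if mode == "auto":
        mode = "exact" if n <= EXACT_WILCOXON_N else "normal-approx"
    if mode == "exact":
        signs = (np.arange(2 ** n)[:, None] >> np.arange(n)) & 1
        dist = signs @ ranks
        p = _two_sided_from_dist(dist, w_plus)
        method = "wilcoxon signed-rank (exact enumeration)"
    elif mode == "normal-approx":
        res = sps.wilcoxon(d, zero_method="wilcox", correction=True,
                           alternative="two-sided", method="approx")
        p = float(res.pvalue)
        method = "wilcoxon signed-rank (normal approximation)"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return TestResult(statistic=w_plus, p_value=p, method=method, n=n)


def mann_whitney_u(group_a, group_b, mode: str = "auto") -> TestResult:
    """Two-sided Mann-Whitney U test on two independent samples.

    ``mode="exact"`` enumerates all C(n_a+n_b, n_a) group labelings of
    the pooled midranks (exact under ties); ``mode="normal-approx"``
    uses scipy's tie-corrected normal approximation with continuity
    correction; ``mode="auto"`` picks exact for n_a+n_b <= 12.  The
    statistic is U for the first group.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    na, nb = a.size, b.size
    n = na + nb
    pooled_ranks = sps.rankdata(np.concatenate([a, b]))
    u_a = float(pooled_ranks[:na].sum() - na * (na + 1) / 2.0)
    if mode == "auto":
        mode = "exact" if n <= EXACT_MWU_N else "normal-approx"
    if mode == "exact":
        dist = np.array([sum(pooled_ranks[i] for i in comb)
                         for comb in itertools.combinations(range(n), na)])
        dist -= na * (na + 1) / 2.0
        p = _two_sided_from_dist(dist, u_a)
        method = "mann-whitney U (exact enumeration)"
    elif mode == "normal-approx":
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
        method = "mann-whitney U (normal approximation)"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return TestResult(statistic=u_a, p_value=p, method=method, n=n)


def bonferroni(p_values, m: int | None = None) -> list[float]:
    """Bonferroni adjustment: ``min(1, p * m)`` for each p.

    ``m`` defaults to the number of comparisons and must not be smaller.
    Never decreases a p-value.
    """
    ps = list(p_values)
    if m is None:
        m = len(ps)
    if m < len(ps):
        raise ValueError(f"m = {m} smaller than the {len(ps)} comparisons")
    return [min(1.0, p * m) for p in ps]


def chi_square_2x2(table) -> TestResult:
    """Pearson chi-square (no continuity correction) on a 2x2 table,
    df = 1.  Raises ValueError on a zero marginal (undefined test)."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero marginal: chi-square undefined")
    chi2, p, dof, _ = sps.chi2_contingency(t, correction=False)
    assert dof == 1
    return TestResult(statistic=float(chi2), p_value=float(p),
                      method="pearson chi-square (df=1, no continuity correction)",
                      n=int(t.sum()))


def _icc_from_pingouin(ratings: np.ndarray, icc_type: str) -> tuple:
    import pingouin as pg  # deferred: heavy import

    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2:
        raise ValueError("ratings must be a subjects x raters matrix")
    ns, nr = ratings.shape
    if ns < 2 or nr < 2:
        raise ValueError("need at least 2 subjects and 2 raters/sessions")
    if np.isnan(ratings).any():
        raise ValueError("ratings matrix must be complete")
    df = pd.DataFrame({
        "subject": np.repeat(np.arange(ns), nr),
        "rater": np.tile(np.arange(nr), ns),
        "score": ratings.ravel(),
    })
    table = pg.intraclass_corr(data=df, targets="subject", raters="rater",
                               ratings="score")
    table = table.set_index("Type")
    ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
    row = table.loc[icc_type]
    ci = tuple(float(v) for v in row[ci_col])
    return float(row["ICC"]), ci, float(row["pval"]), ns, nr


def icc_oneway_random(ratings) -> ICCResult:
    """ICC(1,1): one-way random effects, single measurement.

    For intra-rater designs (one rater, repeated sessions as columns):
    ICC = (MSB - MSW) / (MSB + (k-1) MSW) from the one-way ANOVA
    decomposition, with an F-based 95% CI.
    """
    icc, ci, p, ns, nr = _icc_from_pingouin(ratings, "ICC(1,1)")
    return ICCResult(icc=icc, ci95=ci, p_value=p,
                     method="ICC(1,1) one-way random, single measure",
                     n_subjects=ns, n_raters=nr)


def icc_twoway_mixed_absolute(ratings) -> ICCResult:
    """Single-measure absolute-agreement ICC from the two-way ANOVA
    decomposition (subjects, raters, residual):

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    For inter-rater designs with a fixed rater panel (mixed model); the
    absolute-agreement estimator penalises systematic rater offsets,
    unlike the consistency variant.  CI per McGraw & Wong.
    """
    icc, ci, p, ns, nr = _icc_from_pingouin(ratings, "ICC(A,1)")
    return ICCResult(icc=icc, ci95=ci, p_value=p,
                     method="ICC(A,1) two-way mixed, absolute agreement, single measure",
                     n_subjects=ns, n_raters=nr)


# --- study-level orchestration ---------------------------------------------

def _paired_frames(cohort: pd.DataFrame, g1: str, g2: str, key: str):
    a = cohort[cohort["group"] == g1].set_index(key).sort_index()
    b = cohort[cohort["group"] == g2].set_index(key).sort_index()
    if not a.index.equals(b.index):
        raise ValueError(f"{g1}/{g2} rows are not paired on {key!r}")
    return a, b


def run_study_comparisons(cohort: pd.DataFrame,
                          measurements: list[str] | None = None,
                          paired_controls: bool = False) -> dict:
    """Run the full group-comparison battery on a cohort table.

    For every measurement column: CSC vs fellow by paired Wilcoxon
    signed-rank (eyes of the same patients, paired on ``patient_id``),
    CSC vs control and fellow vs control by unpaired Mann-Whitney U
    (different subjects), with Bonferroni correction over the family of
    three pairwise contrasts per measurement.  ``paired_controls=True``
    instead pairs controls to patients on ``match_id`` (the age-match
    index) and uses the signed-rank test for all three contrasts.

    If the table has an ``ia_grade`` column, CSC eyes are additionally
    dichotomised into high ({very severe, severe}) vs low ({moderate,
    mild}) hyperpermeability and compared per measurement with the
    Mann-Whitney U test.

    Returns a nested dict: ``{"group_comparisons": {measurement:
    {contrast: TestResult}}, "ia_comparisons": {...}}``.
    """
    for g in ("CSC", "fellow", "control"):
        if (cohort["group"] == g).sum() == 0:
            raise ValueError(f"group {g!r} is empty or missing")
    if measurements is None:
        skip = {"case_id", "group", "patient_id", "match_id", "ia_grade"}
        measurements = [c for c in cohort.columns
                        if c not in skip and pd.api.types.is_numeric_dtype(cohort[c])]
    pair_key = "patient_id" if "patient_id" in cohort.columns else "case_id"

    report: dict = {"group_comparisons": {}, "ia_comparisons": {}}
    for mcol in measurements:
        csc, flw = _paired_frames(cohort, "CSC", "fellow", pair_key)
        res = {"csc_vs_fellow": wilcoxon_signed_rank(csc[mcol], flw[mcol])}
        if paired_controls:
            key = "match_id" if "match_id" in cohort.columns else pair_key
            csc_m, ctl_m = _paired_frames(cohort, "CSC", "control", key)
            flw_m, ctl_m2 = _paired_frames(cohort, "fellow", "control", key)
            res["csc_vs_control"] = wilcoxon_signed_rank(csc_m[mcol], ctl_m[mcol])
            res["fellow_vs_control"] = wilcoxon_signed_rank(flw_m[mcol], ctl_m2[mcol])
        else:
            ctl = cohort.loc[cohort["group"] == "control", mcol]
            res["csc_vs_control"] = mann_whitney_u(
                cohort.loc[cohort["group"] == "CSC", mcol], ctl)
            res["fellow_vs_control"] = mann_whitney_u(
                cohort.loc[cohort["group"] == "fellow", mcol], ctl)
        order = ["csc_vs_fellow", "csc_vs_control", "fellow_vs_control"]
        adj = bonferroni([res[k].p_value for k in order], m=3)
        for k, ap in zip(order, adj):
            res[k].adjusted_p = ap
        report["group_comparisons"][mcol] = res

    if "ia_grade" in cohort.columns:
        graded = cohort[(cohort["group"] == "CSC") & cohort["ia_grade"].notna()]
        high = graded[graded["ia_grade"].isin(IA_HIGH_GRADES)]
        low = graded[~graded["ia_grade"].isin(IA_HIGH_GRADES)]
        if len(high) and len(low):
            for mcol in measurements:
                report["ia_comparisons"][mcol] = mann_whitney_u(
                    high[mcol], low[mcol])
    return report
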