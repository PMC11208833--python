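"""Trial statistics: group and day comparisons of the sleep/HRV measures.

The comparison scheme of a two-arm, three-measurement-day trial:

* between groups, per day and measure: two-tailed two-sample t tests
  (Welch by default) and a Pearson correlation as the effect-size column;
* within groups: one-way ANOVA across conditions with Games-Howell pairwise
  post-hoc comparisons (unequal variances allowed: Welch-Satterthwaite
  degrees of freedom and the studentized-range distribution);
* Bonferroni rechecking by multiplying raw p values by the number of
  comparisons k — uncapped by default, matching the reporting convention in
  which adjusted values may exceed 1 (equivalently, testing at alpha/k).

Table builders emit three data frames shaped like the trial's report: group
means/SDs with between-group tests per (day, measure); within-group
comparisons among the stage-duration measures per day; and within-group day
contrasts of LF, HF and LF/HF with raw and Bonferroni-adjusted p values.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "t_test_two_tailed",
    "pearson_r",
    "one_way_anova",
    "games_howell",
    "bonferroni_adjust",
    "build_tables",
    "DURATION_MEASURES",
    "SPECTRAL_MEASURES",
]

DURATION_MEASURES = ("total", "S", "PS_shallow", "PS_deep")
SPECTRAL_MEASURES = ("LF", "HF", "LF_HF")
ALL_MEASURES = DURATION_MEASURES + SPECTRAL_MEASURES


@dataclass
class TestResult:
    """Statistic, degrees of freedom, p value and effect size of one contrast."""

    statistic: float
    df: float
    p: float
    effect: float = math.nan  # Pearson r or mean difference, per test
    label: str = ""
    p_adjusted: float | None = None

    def __post_init__(self) -> None:
        if not (math.isnan(self.p) or 0.0 <= self.p <= 1.0):
            raise ValueError("raw p must lie in [0, 1]")


def _as_sample(x, name: str, min_n: int) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if a.size < min_n:
        raise ValueError(f"{name} needs at least {min_n} observations")
    if np.any(~np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")
    return a


def t_test_two_tailed(x, y, variant: str = "welch", label: str = "") -> TestResult:
    """Two-sample two-tailed t test (Welch by default, Student optional).

    Degenerate convention: if both samples have zero variance, the result
    is t = 0, p = 1 for equal means and the limit t = +/-inf, p = 0 for
    unequal means.
    """
    a = _as_sample(x, "x", 2)
    b = _as_sample(y, "y", 2)
    if variant not in ("welch", "student"):
        raise ValueError("variant must be 'welch' or 'student'")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = float(a.mean() - b.mean())
    if va == 0.0 and vb == 0.0:
        df = float(a.size + b.size - 2)
        if diff == 0.0:
            return TestResult(0.0, df, 1.0, effect=0.0, label=label)
        return TestResult(math.copysign(math.inf, diff), df, 0.0, effect=diff, label=label)
    res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return TestResult(
        float(res.statistic), float(res.df), float(res.pvalue), effect=diff, label=label
    )


def pearson_r(x, y, label: str = "") -> TestResult:
    """Pearson correlation with the two-tailed t-based p value.

    ``t = r sqrt((n-2) / (1-r^2))`` on n-2 degrees of freedom.
    """
    a = _as_sample(x, "x", 3)
    b = _as_sample(y, "y", 3)
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    if a.var(ddof=1) == 0.0 or b.var(ddof=1) == 0.0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(a, b)
    n = a.size
    if abs(r) < 1.0:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
    else:
        t = math.copysign(math.inf, r)
    return TestResult(float(t), float(n - 2), float(p), effect=float(r), label=label)


def one_way_anova(groups: list, label: str = "") -> TestResult:
    """One-way ANOVA: F = MS_between / MS_within on (k-1, N-k) df."""
    gs = [_as_sample(g, f"group {i}", 2) for i, g in enumerate(groups)]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    allv = np.concatenate(gs)
    if np.ptp(allv) == 0.0:
        raise ValueError("all observations identical: F undefined")
    f, p = stats.f_oneway(*gs)
    k = len(gs)
    n = allv.size
    res = TestResult(float(f), float(k - 1), float(p), label=label)
    res.df2 = float(n - k)  # type: ignore[attr-defined]
    return res


def _welch_df(vi: float, ni: int, vj: float, nj: int) -> float:
    num = (vi / ni + vj / nj) ** 2
    den = (vi / ni) ** 2 / (ni - 1) + (vj / nj) ** 2 / (nj - 1)
    return num / den


def games_howell(groups: list, labels: list | None = None) -> list[TestResult]:
    """Games-Howell pairwise comparisons for unequal variances/sizes.

    For the pair (i, j): ``SE = sqrt(s_i^2/n_i + s_j^2/n_j)``,
    ``q = |mean_i - mean_j| * sqrt(2) / SE``, Welch-Satterthwaite df, and the
    p value from the studentized-range distribution with k groups.  At k = 2
    this reduces to the two-tailed Welch t test.  Pairs with zero variance
    on both sides and equal means get p = 1 by convention.
    """
    gs = [_as_sample(g, f"group {i}", 2) for i, g in enumerate(groups)]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    k = len(gs)
    names = labels if labels is not None else [str(i) for i in range(k)]
    out: list[TestResult] = []
    for i, j in itertools.combinations(range(k), 2):
        a, b = gs[i], gs[j]
        vi, vj = a.var(ddof=1), b.var(ddof=1)
        diff = float(a.mean() - b.mean())
        lab = f"{names[i]} vs {names[j]}"
        if vi == 0.0 and vj == 0.0:
            # degenerate pair: p = 1 for equal means, limit p = 0 otherwise
            p0 = 1.0 if diff == 0.0 else 0.0
            stat = 0.0 if diff == 0.0 else math.inf
            out.append(
                TestResult(stat, float(a.size + b.size - 2), p0, effect=diff, label=lab)
            )
            continue
        se = math.sqrt(vi / a.size + vj / b.size)
        q = abs(diff) * math.sqrt(2.0) / se
        df = _welch_df(vi, a.size, vj, b.size)
        p = float(stats.studentized_range.sf(q, k, df))
        p = min(max(p, 0.0), 1.0)
        out.append(TestResult(q, df, p, effect=diff, label=lab))
    return out


def bonferroni_adjust(p: float, k: int, cap: bool = False) -> float:
    """Multiply a raw p value by the number of comparisons k.

    Uncapped by default: adjusted values above 1 are reported as-is
    (the alpha/k testing convention); ``cap=True`` clips at 1.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if k < 1:
        raise ValueError("k must be >= 1")
    adj = p * k
    return min(1.0, adj) if cap else adj


# ---------------------------------------------------------------------------
# Trial-shaped tables


def _check_cells(summaries: pd.DataFrame, groups, days) -> None:
    missing = [
        (g, d)
        for g in groups
        for d in days
        if summaries.query("group == @g and day == @d").empty
    ]
    if missing:
        raise ValueError(f"missing (group, day) cells: {missing}")


def build_tables(
    summaries: pd.DataFrame,
    groups: tuple = ("Mi", "nMi"),
    days: tuple = (1, 5, 9),
    t_variant: str = "welch",
    bonferroni_cap: bool = False,
    alpha: float = 0.05,
) -> dict:
    """Build the three trial-shaped tables from per-subject-night summaries.

    ``summaries`` needs one row per (group, subject, day) with measure
    columns ``total, S, PS_shallow, PS_deep, LF, HF, LF_HF`` (durations in
    minutes; LF/HF amplitudes in ms).

    Returns ``{"group_means": ..., "stage_contrasts": ..., "day_contrasts": ...}``:

    * ``group_means`` — per (day, measure): group means/SDs, the
      between-group t-test p, and the Pearson r of the two groups' subject
      vectors paired by within-group subject order (the pairing of two
      independent arms is a reporting convention, exposed generically).
    * ``stage_contrasts`` — per (group, day): Games-Howell comparisons among
      the four duration measures.
    * ``day_contrasts`` — per (group, spectral measure): one-way ANOVA
      across days plus Games-Howell day pairs with raw and
      Bonferroni-adjusted p (k = number of day pairs).
    """
    need = {"group", "subject", "day", *ALL_MEASURES}
    if not need.issubset(summaries.columns):
        raise ValueError(f"summaries is missing columns: {sorted(need - set(summaries.columns))}")
    _check_cells(summaries, groups, days)
    ga, gb = groups

    def cell(g, d, m) -> np.ndarray:
        sub = summaries.query("group == @g and day == @d").sort_values("subject")
        return sub[m].to_numpy(float)

    rows1 = []
    for d in days:
        for m in ALL_MEASURES:
            xa, xb = cell(ga, d, m), cell(gb, d, m)
            tt = t_test_two_tailed(xa, xb, variant=t_variant)
            try:
                pr = pearson_r(xa[: min(len(xa), len(xb))], xb[: min(len(xa), len(xb))])
                r_val, r_p = pr.effect, pr.p
            except ValueError:
                r_val, r_p = math.nan, math.nan
            rows1.append(
                {
                    "day": d,
                    "measure": m,
                    f"{ga}_mean": xa.mean(),
                    f"{ga}_sd": xa.std(ddof=1),
                    f"{ga}_n": len(xa),
                    f"{gb}_mean": xb.mean(),
                    f"{gb}_sd": xb.std(ddof=1),
                    f"{gb}_n": len(xb),
                    "t": tt.statistic,
                    "t_df": tt.df,
                    "t_p": tt.p,
                    "significant": tt.p < alpha,
                    "pearson_r": r_val,
                    "pearson_p": r_p,
                }
            )
    table1 = pd.DataFrame(rows1)

    rows2 = []
    for g in groups:
        for d in days:
            samples = [cell(g, d, m) for m in DURATION_MEASURES]
            for res in games_howell(samples, labels=list(DURATION_MEASURES)):
                rows2.append(
                    {
                        "group": g,
                        "day": d,
                        "contrast": res.label,
                        "q": res.statistic,
                        "df": res.df,
                        "p": res.p,
                        "significant": res.p < alpha,
                    }
                )
    table2 = pd.DataFrame(rows2)

    rows3 = []
    n_pairs = len(list(itertools.combinations(days, 2)))
    for g in groups:
        for m in SPECTRAL_MEASURES:
            samples = [cell(g, d, m) for d in days]
            an = one_way_anova(samples, label=f"{g} {m} across days")
            gh = games_howell(samples, labels=[f"day {d}" for d in days])
            for res in gh:
                rows3.append(
                    {
                        "group": g,
                        "measure": m,
                        "contrast": res.label,
                        "anova_F": an.statistic,
                        "anova_p": an.p,
                        "q": res.statistic,
                        "df": res.df,
                        "p": res.p,
                        "bonferroni": bonferroni_adjust(res.p, n_pairs, cap=bonferroni_cap),
                        "significant": res.p < alpha,
                    }
                )
    table3 = pd.DataFrame(rows3)
    return {"group_means": table1, "stage_contrasts": table2, "day_contrasts": table3}
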