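"""Repeated-measures statistics for phase comparisons.

One-way repeated-measures ANOVA with Greenhouse-Geisser sphericity
correction, a mixed two-way (one between-subject, one within-subject
factor) ANOVA, Holm-Sidak step-down and Tukey/Bonferroni multiple
comparisons, Welch's t, and within-subject omega-squared effect size.

The ANOVA decompositions are computed from sums of squares directly; tail
probabilities come from scipy's F and studentized-range distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synth import ParameterError


@dataclass
class AnovaResult:
    """One F test, with epsilon-scaled degrees of freedom when corrected."""

    F: float
    df_num: float
    df_den: float
    p: float
    epsilon: float = 1.0
    term: str = "condition"
    ss: dict = field(default_factory=dict)  # sums of squares / df for effect sizes


@dataclass
class ComparisonSet:
    """Pairwise comparisons with raw and adjusted p values."""

    labels: list[tuple]
    p_raw: np.ndarray
    p_adj: np.ndarray
    method: str
    statistic: np.ndarray | None = None


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    degenerate: bool = False


def _as_matrix(table) -> np.ndarray:
    x = np.asarray(table, dtype=float)
    if x.ndim != 2:
        raise ParameterError("repeated-measures table must be 2-D (subjects x conditions)")
    if np.isnan(x).any():
        raise ParameterError("repeated-measures table must be complete (no missing cells)")
    return x


# ---------------------------------------------------------------------------
# Greenhouse-Geisser epsilon
# ---------------------------------------------------------------------------

def gg_epsilon(table) -> float:
    """Greenhouse-Geisser sphericity estimate from the condition covariance.

    Box's epsilon computed from the sample covariance S of the k conditions,
    clamped to its theoretical range [1/(k-1), 1]. Location shifts of any
    cell column leave the estimate unchanged.
    """
    x = _as_matrix(table)
    n, k = x.shape
    if k < 2:
        raise ParameterError("need at least 2 conditions")
    if k == 2:
        return 1.0  # two-level within designs are always spherical
    S = np.cov(x, rowvar=False)
    mean_diag = np.trace(S) / k
    grand = S.mean()
    row_means = S.mean(axis=1)
    num = (k * (mean_diag - grand)) ** 2
    den = (k - 1) * (np.sum(S * S) - 2 * k * np.sum(row_means**2) + k * k * grand**2)
    if den <= 0:
        return 1.0
    eps = num / den
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


# ---------------------------------------------------------------------------
# one-way repeated measures ANOVA
# ---------------------------------------------------------------------------

def rm_anova_one_way(table, gg: bool = True) -> AnovaResult:
    """Within-subject one-way ANOVA with subject blocking.

    ``table`` is subjects x conditions. With ``gg`` set, both degrees of
    freedom are scaled by the Greenhouse-Geisser epsilon before the p value
    is taken from the F distribution (the F statistic is unchanged).
    """
    x = _as_matrix(table)
    n, k = x.shape
    if n < 2 or k < 2:
        raise ParameterError("need >= 2 subjects and >= 2 conditions")
    grand = x.mean()
    ss_total = float(((x - grand) ** 2).sum())
    ss_subj = float(k * ((x.mean(axis=1) - grand) ** 2).sum())
    ss_cond = float(n * ((x.mean(axis=0) - grand) ** 2).sum())
    ss_err = ss_total - ss_subj - ss_cond
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    F = ms_cond / ms_err if ms_err > 0 else (0.0 if ms_cond == 0 else np.inf)
    eps = gg_epsilon(x) if gg else 1.0
    p = float(sps.f.sf(F, df1 * eps, df2 * eps)) if np.isfinite(F) else 0.0
    return AnovaResult(
        F=float(F), df_num=df1 * eps, df_den=df2 * eps, p=p, epsilon=eps,
        ss={"ss_total": ss_total, "ss_subj": ss_subj, "ss_cond": ss_cond,
            "ss_err": ss_err, "ms_cond": ms_cond, "ms_err": ms_err,
            "ms_subj": ss_subj / (n - 1), "df_cond": df1, "df_err": df2,
            "n": n, "k": k},
    )


def omega_squared_within(res: AnovaResult) -> float:
    """Within-subject omega-squared from one-way RM ANOVA sums of squares:
    df_effect * (MS_effect - MS_error) / (SS_total + MS_subjects), clamped
    at zero."""
    ss = res.ss
    if not ss:
        raise ParameterError("AnovaResult lacks sums of squares")
    w2 = ss["df_cond"] * (ss["ms_cond"] - ss["ms_err"]) / (ss["ss_total"] + ss["ms_subj"])
    return float(max(w2, 0.0))


# ---------------------------------------------------------------------------
# mixed two-way ANOVA (one between, one within factor)
# ---------------------------------------------------------------------------

def rm_anova_two_way(table, groups, gg: bool = True) -> dict[str, AnovaResult]:
    """Mixed-design ANOVA: between-subject ``groups``, within-subject columns.

    ``table`` is subjects x within-levels (complete); ``groups`` assigns each
    subject to a between-factor level. Returns F tests for the between main
    effect (tested against subjects-within-groups), the within main effect
    and the interaction (tested against the within-error term, with
    Greenhouse-Geisser correction on the within degrees of freedom when
    ``gg`` is set, estimated from the pooled within-group covariance).
    """
    x = _as_matrix(table)
    groups = np.asarray(groups)
    n, k = x.shape
    if groups.shape[0] != n:
        raise ParameterError("one group label per subject required")
    levels = np.unique(groups)
    g = levels.size
    if g < 2 or k < 2 or n < g + 1:
        raise ParameterError("need >= 2 groups, >= 2 within levels, and spare subjects")

    grand = x.mean()
    subj_mean = x.mean(axis=1)
    time_mean = x.mean(axis=0)
    ss_total = float(((x - grand) ** 2).sum())
    ss_betsub = float(k * ((subj_mean - grand) ** 2).sum())
    ss_group = 0.0
    ss_inter = 0.0
    pooled = np.zeros((k, k))
    for lev in levels:
        sel = groups == lev
        nj = int(sel.sum())
        if nj < 2:
            raise ParameterError("each group needs >= 2 subjects")
        gmean = x[sel].mean()
        ss_group += k * nj * (gmean - grand) ** 2
        cell = x[sel].mean(axis=0)
        ss_inter += nj * np.sum((cell - gmean - time_mean + grand) ** 2)
        pooled += (nj - 1) * np.cov(x[sel], rowvar=False)
    pooled /= n - g
    ss_subj_within = ss_betsub - ss_group
    ss_time = float(n * ((time_mean - grand) ** 2).sum())
    ss_err = ss_total - ss_betsub - ss_time - ss_inter
    # snap floating residue to exact zero so degenerate terms give F = 0
    tiny = 1e-12 * max(ss_total, 1e-300)
    ss_time, ss_inter, ss_err = (0.0 if abs(v) < tiny else v
                                 for v in (ss_time, ss_inter, ss_err))

    df_g, df_sw = g - 1, n - g
    df_t, df_e = k - 1, (n - g) * (k - 1)
    ms = {"group": ss_group / df_g, "subj_within": ss_subj_within / df_sw,
          "time": ss_time / df_t, "inter": ss_inter / (df_g * df_t),
          "err": ss_err / df_e}
    eps = 1.0
    if gg and k > 2:
        mean_diag = np.trace(pooled) / k
        gmean = pooled.mean()
        rmeans = pooled.mean(axis=1)
        num = (k * (mean_diag - gmean)) ** 2
        den = (k - 1) * (np.sum(pooled**2) - 2 * k * np.sum(rmeans**2) + k * k * gmean**2)
        eps = float(np.clip(num / den, 1.0 / (k - 1), 1.0)) if den > 0 else 1.0

    def _mk(term, msn, df1, df2, scale):
        den = ms["subj_within"] if term == "group" else ms["err"]
        if den > 0:
            F = float(msn / den)
        else:
            F = 0.0 if msn == 0 else np.inf
        p = float(sps.f.sf(F, df1 * scale, df2 * scale)) if np.isfinite(F) else 0.0
        return AnovaResult(F=F, df_num=df1 * scale, df_den=df2 * scale, p=p,
                           epsilon=scale, term=term)

    return {
        "between": _mk("group", ms["group"], df_g, df_sw, 1.0),
        "within": _mk("time", ms["time"], df_t, df_e, eps),
        "interaction": _mk("interaction", ms["inter"], df_g * df_t, df_e, eps),
    }


# ---------------------------------------------------------------------------
# multiple comparisons
# ---------------------------------------------------------------------------

def holm_sidak_adjust(pvals) -> np.ndarray:
    """Holm-Sidak step-down adjustment, returned in the input order.

    Sort ascending; adjusted_(i) = max_{j<=i} of 1 - (1 - p_(j))^(m - j + 1),
    clamped to 1. Adjusted values are monotone along the sorted order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def bonferroni_adjust(pvals) -> np.ndarray:
    """Plain Bonferroni (Bonferroni-Dunn) adjustment on the family."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p values must lie in [0, 1]")
    return np.minimum(p * p.size, 1.0)


def pairwise_rm(table, labels=None, method: str = "holm_sidak") -> ComparisonSet:
    """All pairwise condition comparisons within a repeated-measures table.

    ``holm_sidak`` / ``bonferroni_dunn``: paired t tests with step-down or
    Bonferroni adjustment. ``tukey``: studentized-range test on the condition
    means against the RM-ANOVA error term (Tukey HSD for repeated measures).
    """
    x = _as_matrix(table)
    n, k = x.shape
    labels = list(labels) if labels is not None else list(range(k))
    pairs = [(labels[i], labels[j]) for i in range(k) for j in range(i + 1, k)]

    if method == "tukey":
        res = rm_anova_one_way(x, gg=False)
        ms_err, df_err = res.ss["ms_err"], res.ss["df_err"]
        means = x.mean(axis=0)
        q = np.array([abs(means[i] - means[j]) / np.sqrt(ms_err / n)
                      for i in range(k) for j in range(i + 1, k)])
        p_raw = sps.studentized_range.sf(q, k, df_err)
        return ComparisonSet(labels=pairs, p_raw=p_raw, p_adj=p_raw,
                             method="tukey", statistic=q)

    t_stats, p_raw = [], []
    for i in range(k):
        for j in range(i + 1, k):
            d = x[:, i] - x[:, j]
            sd = d.std(ddof=1)
            if sd == 0:
                t = 0.0 if d.mean() == 0 else np.inf
            else:
                t = d.mean() / (sd / np.sqrt(n))
            t_stats.append(t)
            p_raw.append(float(2 * sps.t.sf(abs(t), n - 1)) if np.isfinite(t) else 0.0)
    p_raw = np.asarray(p_raw)
    if method == "holm_sidak":
        p_adj = holm_sidak_adjust(p_raw)
    elif method == "bonferroni_dunn":
        p_adj = bonferroni_adjust(p_raw)
    else:
        raise ParameterError(f"unknown method {method!r}")
    return ComparisonSet(labels=pairs, p_raw=p_raw, p_adj=p_adj, method=method,
                         statistic=np.asarray(t_stats))


# ---------------------------------------------------------------------------
# Welch's t
# ---------------------------------------------------------------------------

def welch_t(x, y) -> TTestResult:
    """Unpaired t with Welch's correction (Satterthwaite df), two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ParameterError("each sample needs n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = x.size, y.size
    if vx == 0 and vy == 0:
        equal = x.mean() == y.mean()
        return TTestResult(t=0.0 if equal else np.inf, df=nx + ny - 2,
                           p=1.0 if equal else 0.0, degenerate=True)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = float(2 * sps.t.sf(abs(t), df))
    return TTestResult(t=float(t), df=float(df), p=p)


def multiple_welch_t(xs: list, ys: list, method: str = "holm_sidak") -> ComparisonSet:
    """Per-point Welch t tests between two groups with family-wise adjustment."""
    p_raw = np.array([welch_t(x, y).p for x, y in zip(xs, ys)])
    t = np.array([welch_t(x, y).t for x, y in zip(xs, ys)])
    adj = holm_sidak_adjust(p_raw) if method == "holm_sidak" else bonferroni_adjust(p_raw)
    return ComparisonSet(labels=list(range(len(p_raw))), p_raw=p_raw, p_adj=adj,
                         method=method, statistic=t)


def results_to_frame(results: dict[str, AnovaResult] | AnovaResult,
                     comparisons: ComparisonSet | None = None) -> pd.DataFrame:
    """Tidy export: one row per ANOVA term plus one per pairwise comparison."""
    if isinstance(results, AnovaResult):
        results = {results.term: results}
    rows = [{"term": r.term, "F": r.F, "df1": r.df_num, "df2": r.df_den,
             "epsilon": r.epsilon, "p": r.p, "p_adj": np.nan, "method": "anova"}
            for r in results.values()]
    if comparisons is not None:
        for lab, praw, padj in zip(comparisons.labels, comparisons.p_raw,
                                   comparisons.p_adj):
            rows.append({"term": f"{lab[0]} vs {lab[1]}" if isinstance(lab, tuple)
                         else str(lab),
                         "F": np.nan, "df1": np.nan, "df2": np.nan,
                         "epsilon": np.nan, "p": praw, "p_adj": padj,
                         "method": comparisons.method})
    return pd.DataFrame(rows)
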