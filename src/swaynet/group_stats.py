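"""Group-level statistics for the 2 (group) x 2 (visual condition) design.

* demographics: pooled-variance independent t (Welch optional) and Pearson
  chi-square without continuity correction;
* 2x2 mixed-design ANOVA (group between, condition within) with classical
  sums-of-squares partition, F at df (1, N-2), and partial eta squared
  ``SS_effect / (SS_effect + SS_error)`` — equivalently ``F/(F + df2)`` when
  df1 = 1;
* simple effects after a significant interaction: independent contrast per
  condition, paired contrast per group, Bonferroni-adjusted within each
  two-test family;
* multiplicity control: Bonferroni over the three global network metrics,
  Benjamini–Hochberg FDR over the ten nodal values;
* Pearson brain–behavior correlations with the t-based two-sided p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SampleSummary",
    "CorrelationResult",
    "pooled_t_test",
    "welch_t_test",
    "chi_square_2x2",
    "levene_test",
    "mixed_anova_2x2",
    "simple_effects",
    "fdr_bh",
    "bonferroni",
    "pearson_corr_test",
    "partial_eta_squared",
]


@dataclass(frozen=True)
class SampleSummary:
    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.sd < 0 or self.n < 2:
            raise ValueError("need sd >= 0 and n >= 2")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p: float


def pooled_t_test(a: SampleSummary, b: SampleSummary) -> tuple[float, int, float]:
    """Equal-variance two-sample t from summaries; df = n1 + n2 - 2."""
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    se = np.sqrt(sp2 * (1 / a.n + 1 / b.n))
    if se == 0:
        if a.mean == b.mean:
            return 0.0, df, 1.0
        raise ZeroDivisionError("zero pooled variance with unequal means")
    t = (a.mean - b.mean) / se
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), int(df), float(p)


def welch_t_test(a: SampleSummary, b: SampleSummary) -> tuple[float, float, float]:
    """Unequal-variance alternative (Welch–Satterthwaite df)."""
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    se = np.sqrt(va + vb)
    if se == 0:
        if a.mean == b.mean:
            return 0.0, float(a.n + b.n - 2), 1.0
        raise ZeroDivisionError("zero variance with unequal means")
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    t = (a.mean - b.mean) / se
    return float(t), float(df), float(2 * stats.t.sf(abs(t), df))


def chi_square_2x2(table) -> tuple[float, int, float]:
    """Pearson chi-square, no continuity correction: n(ad-bc)^2 / (row*col)."""
    tbl = np.asarray(table, dtype=float)
    if tbl.shape != (2, 2) or (tbl < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    (a, b), (c, d) = tbl
    n = tbl.sum()
    if n <= 0:
        raise ValueError("empty table")
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        raise ValueError("zero marginal in contingency table")
    chi2 = n * (a * d - b * c) ** 2 / margins
    return float(chi2), 1, float(stats.chi2.sf(chi2, 1))


def levene_test(*groups, center: str = "mean") -> tuple[float, float]:
    """Levene's homogeneity-of-variance test (mean-centred by default;
    ``center='median'`` gives the Brown–Forsythe variant)."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with n >= 2 each")
    w, p = stats.levene(*groups, center=center)
    return float(w), float(p)


def partial_eta_squared(f: float, df1: float, df2: float) -> float:
    """eta_p^2 = F*df1 / (F*df1 + df2)."""
    return f * df1 / (f * df1 + df2)


def _pivot_2x2(data: pd.DataFrame, dv: str, subject: str, between: str,
               within: str):
    groups = sorted(data[between].unique())
    conds = sorted(data[within].unique())
    if len(groups) != 2 or len(conds) != 2:
        raise ValueError("mixed_anova_2x2 requires exactly 2 groups and 2 conditions")
    wide = data.pivot_table(index=[subject, between], columns=within,
                            values=dv, aggfunc="mean")
    missing = wide.index[wide.isna().any(axis=1)]
    if len(missing):
        raise ValueError(f"participant(s) missing a condition: "
                         f"{[m[0] for m in missing]}")
    wide = wide.reset_index()
    return wide, groups, conds


def mixed_anova_2x2(data: pd.DataFrame, dv: str = "value",
                    subject: str = "participant", between: str = "group",
                    within: str = "condition") -> pd.DataFrame:
    """Classical mixed-ANOVA partition for the 2x2 design.

    Between-subjects stratum: SS(group) against SS(subjects within group);
    within-subjects stratum: SS(condition) and SS(group x condition) against
    SS(condition x subjects within group). With two conditions the within
    stratum reduces exactly to an analysis of per-subject condition
    differences. All F have df (1, N-2); effects use unweighted (cell-mean)
    contrasts, which coincides with the classical partition for equal group
    sizes.

    Returns a table with rows condition / group / interaction and columns
    F, df1, df2, p, eta_p_sq, SS_effect, SS_error.
    """
    wide, groups, conds = _pivot_2x2(data, dv, subject, between, within)
    g_labels = wide[between].to_numpy()
    y1 = wide[conds[0]].to_numpy(float)
    y2 = wide[conds[1]].to_numpy(float)
    n_tot = y1.size
    n_g = np.array([(g_labels == g).sum() for g in groups])
    if (n_g < 2).any():
        raise ValueError("each group needs at least 2 participants")
    df2 = n_tot - 2

    # between-subjects stratum on subject means (x2 for the 2 conditions)
    m_i = (y1 + y2) / 2.0
    m_g = np.array([m_i[g_labels == g].mean() for g in groups])
    m_bar_u = m_g.mean()
    # unweighted group contrast == pooled t on subject means
    ss_sub = 2.0 * sum(((m_i[g_labels == g] - m_g[k]) ** 2).sum()
                       for k, g in enumerate(groups))
    ss_group = 2.0 * (m_g[0] - m_g[1]) ** 2 / (1 / n_g[0] + 1 / n_g[1])
    f_group = (ss_group / 1.0) / (ss_sub / df2)

    # within-subjects stratum on condition differences
    d_i = y2 - y1
    d_g = np.array([d_i[g_labels == g].mean() for g in groups])
    ss_err_w = 0.5 * sum(((d_i[g_labels == g] - d_g[k]) ** 2).sum()
                         for k, g in enumerate(groups))
    d_bar_u = d_g.mean()
    ss_cond = 0.5 * d_bar_u**2 / ((1 / n_g[0] + 1 / n_g[1]) / 4.0)
    ss_int = 0.5 * (d_g[0] - d_g[1]) ** 2 / (1 / n_g[0] + 1 / n_g[1])
    ms_err_w = ss_err_w / df2
    f_cond = ss_cond / ms_err_w if ms_err_w > 0 else (0.0 if ss_cond == 0 else np.inf)
    f_int = ss_int / ms_err_w if ms_err_w > 0 else (0.0 if ss_int == 0 else np.inf)
    f_group = f_group if ss_sub > 0 else (0.0 if ss_group == 0 else np.inf)

    rows = []
    for name, f, ss_e, ss_err in (
        ("condition", f_cond, ss_cond, ss_err_w),
        ("group", f_group, ss_group, ss_sub),
        ("interaction", f_int, ss_int, ss_err_w),
    ):
        p = float(stats.f.sf(f, 1, df2)) if np.isfinite(f) else 0.0
        eta = ss_e / (ss_e + ss_err) if (ss_e + ss_err) > 0 else 0.0
        rows.append({"effect": name, "F": float(f), "df1": 1, "df2": int(df2),
                     "p": p, "eta_p_sq": float(eta),
                     "SS_effect": float(ss_e), "SS_error": float(ss_err)})
    return pd.DataFrame(rows).set_index("effect")


def simple_effects(data: pd.DataFrame, dv: str = "value",
                   subject: str = "participant", between: str = "group",
                   within: str = "condition") -> pd.DataFrame:
    """Post-interaction contrasts.

    Between-group independent t within each condition and within-group
    paired t across conditions; two-sided p, Bonferroni-adjusted (factor 2)
    within each contrast family. Callers should only consult this after a
    significant interaction.
    """
    wide, groups, conds = _pivot_2x2(data, dv, subject, between, within)
    g_labels = wide[between].to_numpy()
    rows = []
    for cond in conds:  # between-group at each condition
        a = wide.loc[g_labels == groups[0], cond].to_numpy(float)
        b = wide.loc[g_labels == groups[1], cond].to_numpy(float)
        if a.size < 2 or b.size < 2:
            raise ValueError(f"too few observations in condition {cond}")
        t, p = stats.ttest_ind(a, b, equal_var=True)
        rows.append({"contrast": f"{groups[0]} vs {groups[1]} @ {cond}",
                     "family": "between", "statistic": float(t),
                     "df": a.size + b.size - 2, "p": float(p)})
    for k, g in enumerate(groups):  # within-group across conditions
        sub = wide[g_labels == g]
        a = sub[conds[0]].to_numpy(float)
        b = sub[conds[1]].to_numpy(float)
        t, p = stats.ttest_rel(a, b)
        rows.append({"contrast": f"{conds[0]} vs {conds[1]} @ {g}",
                     "family": "within", "statistic": float(t),
                     "df": a.size - 1, "p": float(p)})
    out = pd.DataFrame(rows)
    out["p_adj"] = out.groupby("family")["p"].transform(
        lambda p: np.minimum(1.0, p * len(p)))
    return out


def fdr_bh(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bonferroni(pvalues, m: int | None = None) -> np.ndarray:
    """min(1, m*p); ``m`` defaults to the number of tests supplied."""
    p = np.asarray(pvalues, dtype=float)
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("family size m cannot be smaller than the number of tests")
    return np.minimum(1.0, m * p)


def pearson_corr_test(x, y) -> CorrelationResult:
    """Sample Pearson r with two-sided p from t = r sqrt((n-2)/(1-r^2))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), n=int(x.size), p=float(p))
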