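"""Group-level and trait statistics.

Chi-square tests on activation ratios with Cramer's V, two-sample t
tests (Student or Welch) with Cohen's d, classical mixed-design two-way
ANOVA with partial eta squared and an optional between-subject
covariate, Bonferroni-corrected Spearman correlations, partial
correlation, and framewise displacement from rigid-body motion traces.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ChiSquareResult",
    "chi_square_2x2",
    "TTestResult",
    "two_sample_t",
    "two_sample_t_from_stats",
    "MixedAnovaResult",
    "mixed_anova",
    "posthoc_pairwise",
    "CorrelationReport",
    "spearman_with_bonferroni",
    "partial_correlation",
    "FdSeries",
    "framewise_displacement",
]


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p: float
    cramers_v: float
    table: np.ndarray


def chi_square_2x2(
    table: np.ndarray, continuity_correction: bool = False
) -> ChiSquareResult:
    """Pearson chi-square on a 2x2 group x outcome table.

    No continuity correction by default. Cramer's V = sqrt(chi2 / N).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 with nonnegative counts")
    N = t.sum()
    if N <= 0:
        raise ValueError("empty table")
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero marginal; chi-square undefined")
    a, b, c, d = t.ravel()
    num = abs(a * d - b * c)
    if continuity_correction:
        num = max(num - N / 2.0, 0.0)
    chi2 = N * num**2 / (rows[0] * rows[1] * cols[0] * cols[1])
    return ChiSquareResult(
        statistic=float(chi2),
        df=1,
        p=float(stats.chi2.sf(chi2, 1)),
        cramers_v=float(np.sqrt(chi2 / N)),
        table=t,
    )


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    cohens_d: float
    mode: str


def _pooled_d(m1, s1, n1, m2, s2, n2) -> float:
    sp = np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    return float((m1 - m2) / sp) if sp > 0 else 0.0


def two_sample_t_from_stats(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    mode: str = "welch",
) -> TTestResult:
    """Two-sample t test from summary statistics.

    Welch uses the Satterthwaite degrees of freedom; Cohen's d uses the
    pooled SD in either mode.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs n >= 2")
    if sd1 == 0 and sd2 == 0:
        raise ValueError("both samples have zero variance")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    if mode == "welch":
        t = (mean1 - mean2) / np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    elif mode == "student":
        sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
        t = (mean1 - mean2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
    else:
        raise ValueError(f"unknown mode {mode!r}")
    p = 2 * stats.t.sf(abs(t), df)
    return TTestResult(
        t=float(t), df=float(df), p=float(p),
        cohens_d=_pooled_d(mean1, sd1, n1, mean2, sd2, n2), mode=mode,
    )


def two_sample_t(x, y, mode: str = "welch") -> TTestResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return two_sample_t_from_stats(
        x.mean(), x.std(ddof=1), x.size, y.mean(), y.std(ddof=1), y.size, mode
    )


@dataclass
class MixedAnovaResult:
    """F tests for the between-group, within-factor and interaction
    effects of a two-way mixed design, with partial eta squared."""

    effects: pd.DataFrame  # rows: group, within, interaction
    covariate: str | None = None

    def effect(self, name: str) -> pd.Series:
        return self.effects.loc[name]


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    within: str,
    between: str,
    subject: str,
    covariate: str | None = None,
) -> MixedAnovaResult:
    """Classical mixed-design two-way ANOVA on a long-format table.

    The between-subject effect is tested against subjects-within-groups
    error; the within effect and the interaction against the
    subject x within error. Requires a complete (balanced-within)
    design: every subject measured at every within level. An optional
    participant-level covariate is grand-mean centered and entered in
    the between-subject stratum only (ANCOVA on subject means).
    """
    df = data[[subject, between, within, dv] + ([covariate] if covariate else [])]
    wide = df.pivot_table(index=[subject, between], columns=within, values=dv)
    if wide.isna().any().any():
        raise ValueError("missing cells: every subject needs every within level")
    Y = wide.to_numpy()
    subjects = wide.index.get_level_values(0)
    groups = wide.index.get_level_values(1).to_numpy()
    n_subj, k = Y.shape
    gnames = np.unique(groups)
    g = len(gnames)
    gm = Y.mean()
    subj_mean = Y.mean(axis=1)
    grp_mean = {gn: Y[groups == gn].mean() for gn in gnames}
    lvl_mean = Y.mean(axis=0)
    cell_mean = {gn: Y[groups == gn].mean(axis=0) for gn in gnames}
    ng = {gn: int((groups == gn).sum()) for gn in gnames}

    ss_group = k * sum(ng[gn] * (grp_mean[gn] - gm) ** 2 for gn in gnames)
    ss_subj = k * sum(
        (subj_mean[i] - grp_mean[groups[i]]) ** 2 for i in range(n_subj)
    )
    ss_within = n_subj * ((lvl_mean - gm) ** 2).sum()
    ss_inter = sum(
        ng[gn] * ((cell_mean[gn] - grp_mean[gn] - lvl_mean + gm) ** 2).sum()
        for gn in gnames
    )
    ss_total = ((Y - gm) ** 2).sum()
    ss_err_w = ss_total - ss_group - ss_subj - ss_within - ss_inter

    df_group, df_serr = g - 1, n_subj - g
    df_w, df_werr = k - 1, (n_subj - g) * (k - 1)

    if covariate is None:
        f_group = (ss_group / df_group) / (ss_subj / df_serr)
        p_group = stats.f.sf(f_group, df_group, df_serr)
        peta_group = ss_group / (ss_group + ss_subj)
        ss_g_adj, ss_s_adj = ss_group, ss_subj
    else:
        # ANCOVA in the between stratum: subject means adjusted for the
        # centered covariate
        cov = (
            df.drop_duplicates(subject).set_index(subject)[covariate]
            .reindex(subjects).to_numpy(dtype=float)
        )
        cov = cov - cov.mean()
        G = np.zeros((n_subj, g))
        for j, gn in enumerate(gnames):
            G[groups == gn, j] = 1.0
        Xf = np.column_stack([G, cov])
        Xr = np.column_stack([np.ones(n_subj), cov])
        rss_f = _rss(Xf, subj_mean)
        rss_r = _rss(Xr, subj_mean)
        df_serr = n_subj - g - 1
        ss_g_adj = k * (rss_r - rss_f)
        ss_s_adj = k * rss_f
        f_group = (ss_g_adj / df_group) / (ss_s_adj / df_serr)
        p_group = stats.f.sf(f_group, df_group, df_serr)
        peta_group = ss_g_adj / (ss_g_adj + ss_s_adj)

    f_w = (ss_within / df_w) / (ss_err_w / df_werr)
    f_i = (ss_inter / (df_group * df_w)) / (ss_err_w / df_werr)
    rows = [
        {
            "effect": "group", "ss": ss_g_adj, "df1": df_group, "df2": df_serr,
            "F": f_group, "p": p_group,
            "partial_eta_sq": peta_group,
        },
        {
            "effect": "within", "ss": ss_within, "df1": df_w, "df2": df_werr,
            "F": f_w, "p": stats.f.sf(f_w, df_w, df_werr),
            "partial_eta_sq": ss_within / (ss_within + ss_err_w),
        },
        {
            "effect": "interaction", "ss": ss_inter, "df1": df_group * df_w,
            "df2": df_werr, "F": f_i,
            "p": stats.f.sf(f_i, df_group * df_w, df_werr),
            "partial_eta_sq": ss_inter / (ss_inter + ss_err_w),
        },
    ]
    eff = pd.DataFrame(rows).set_index("effect")
    return MixedAnovaResult(effects=eff, covariate=covariate)


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def posthoc_pairwise(
    data: pd.DataFrame,
    dv: str,
    within: str,
    subject: str,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Paired t tests across within-factor levels, Bonferroni-corrected.

    Corrected p = min(1, m * raw p) with m the number of level pairs.
    """
    wide = data.pivot_table(index=subject, columns=within, values=dv)
    levels = list(wide.columns)
    pairs = list(combinations(levels, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        diff = (wide[a] - wide[b]).dropna()
        if diff.std(ddof=1) == 0:
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(wide[a].dropna(), wide[b].dropna())
        rows.append(
            {
                "level_a": a, "level_b": b,
                "t": float(t), "df": len(diff) - 1, "p_uncorrected": float(p),
                "p_corrected": float(min(1.0, m * p))
                if correction == "bonferroni" else float(p),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CorrelationReport:
    table: pd.DataFrame  # score, rho, n, p, significant flags
    corrected_threshold: float


def spearman_with_bonferroni(
    x, scores: pd.DataFrame, alpha: float = 0.05
) -> CorrelationReport:
    """Spearman rho of ``x`` against each score column.

    Significance is flagged both uncorrected at ``alpha`` and at the
    Bonferroni-corrected threshold alpha / n_scores.
    """
    x = np.asarray(x, dtype=float)
    m = scores.shape[1]
    if m < 1:
        raise ValueError("need at least one score")
    if x.size < 4:
        raise ValueError("need n >= 4")
    if np.std(x) == 0:
        raise ValueError("constant x; rank correlation undefined")
    thr = alpha / m
    rows = []
    for col in scores.columns:
        y = scores[col].to_numpy(dtype=float)
        if np.std(y) == 0:
            raise ValueError(f"constant score {col!r}")
        rho, p = stats.spearmanr(x, y)
        rows.append(
            {
                "score": col, "rho": float(rho), "n": int(x.size), "p": float(p),
                "significant_uncorrected": bool(p < alpha),
                "significant_bonferroni": bool(p < thr),
            }
        )
    return CorrelationReport(table=pd.DataFrame(rows), corrected_threshold=thr)


def partial_correlation(x, y, covariate) -> tuple[float, int, float]:
    """Pearson correlation of x and y after removing a covariate.

    Both variables are residualized on the covariate (with intercept);
    returns (r, df, p) with df = n - 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.asarray(covariate, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need n >= 4")
    X = np.column_stack([np.ones(n), c])
    rx = x - X @ np.linalg.lstsq(X, x, rcond=None)[0]
    ry = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    tol = 1e-10
    if np.std(rx) <= tol * max(np.std(x), 1e-30) or np.std(ry) <= tol * max(
        np.std(y), 1e-30
    ):
        raise ValueError("covariate is collinear with x or y")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 3
    t = r * np.sqrt(df / (1 - r**2)) if abs(r) < 1 else np.inf
    p = float(2 * stats.t.sf(abs(t), df))
    return r, df, p


@dataclass
class FdSeries:
    fd: np.ndarray  # per-volume framewise displacement, mm
    mean_fd: float


def framewise_displacement(
    motion: np.ndarray, rotation_radius_mm: float = 50.0
) -> FdSeries:
    """Framewise displacement from a volumes x 6 motion trace.

    FD_t = sum |delta translations| + radius * sum |delta rotations|
    (rotations in radians converted to arc length on a 50-mm sphere);
    the first volume has FD = 0.
    """
    m = np.atleast_2d(np.asarray(motion, dtype=float))
    if m.shape[1] != 6:
        raise ValueError("motion must have 6 columns")
    fd = np.zeros(m.shape[0])
    if m.shape[0] > 1:
        d = np.abs(np.diff(m, axis=0))
        fd[1:] = d[:, :3].sum(axis=1) + rotation_radius_mm * d[:, 3:].sum(axis=1)
    return FdSeries(fd=fd, mean_fd=float(fd.mean()))
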