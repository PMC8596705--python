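"""Statistical layer of the light-stimulation cohort analysis.

Operates on tidy cohort tables (columns ``subject``, ``group``,
``timepoint``, ``count``) from the generator or from detection: per-subject
percent change from baseline, group x timepoint summary tables, the
between-within (split-plot) repeated-measures ANOVA with group tested
against the subject-within-group stratum and time / group x time tested
against the subject x time residual, a one-way repeated-measures ANOVA over
the pooled population, a paired Wilcoxon signed-rank test with exact small-n
p-values, the Shapiro-Wilk normality check, and median/IQR subgroup tables.

All tests are two-sided at alpha = 0.05.  The split-plot decomposition is
computed directly from the balanced-design sums of squares; Greenhouse-
Geisser corrected p-values are reported alongside the uncorrected ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05


@dataclass
class AnovaResult:
    """Between-within ANOVA decomposition.

    ``table`` has one row per stratum (group, subject-within-group, time,
    group x time, residual) with columns ``effect``, ``ss``, ``df``, ``ms``,
    ``F``, ``p``, ``p_gg`` (Greenhouse-Geisser corrected, tested effects
    only); ``epsilon_gg`` is the sphericity correction factor.
    """

    table: pd.DataFrame
    epsilon_gg: float = float("nan")

    def effect(self, name: str) -> pd.Series:
        return self.table.set_index("effect").loc[name]

    def p(self, name: str, corrected: bool = False) -> float:
        row = self.effect(name)
        return float(row["p_gg"] if corrected else row["p"])


def _pivot(cohort: pd.DataFrame) -> pd.DataFrame:
    """Subject x timepoint wide count matrix; validates the balanced design."""
    required = {"subject", "group", "timepoint", "count"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table lacks columns {sorted(missing)}")
    wide = cohort.pivot_table(
        index="subject", columns="timepoint", values="count", aggfunc="count"
    )
    if wide.isna().any().any() or (wide != 1).any().any():
        raise ValueError("unbalanced design: every subject needs exactly one row per timepoint")
    return cohort.pivot(index="subject", columns="timepoint", values="count")


def timepoint_order(cohort: pd.DataFrame) -> list[str]:
    """Timepoints in first-appearance order (baseline first by construction)."""
    return list(dict.fromkeys(cohort["timepoint"]))


def percent_change(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-subject percent change from baseline, 100 * (c_t - c_0) / c_0.

    Baseline is the first timepoint in table order.  Subjects with a zero
    baseline get NaN at every timepoint (excluded from group means).
    Returns the tidy table with columns ``subject``, ``group``,
    ``timepoint``, ``pct_change``.
    """
    tps = timepoint_order(cohort)
    _pivot(cohort)  # balance check
    base = (
        cohort[cohort["timepoint"] == tps[0]]
        .set_index("subject")["count"]
        .astype(float)
    )
    out = cohort.copy()
    b = base.reindex(out["subject"]).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * (out["count"].to_numpy() - b) / b
    pct[b == 0] = np.nan
    out["pct_change"] = pct
    return out[["subject", "group", "timepoint", "pct_change"]]


def percent_change_summary(cohort: pd.DataFrame) -> pd.DataFrame:
    """Group x timepoint mean and sample SD (n-1) of percent change."""
    pct = percent_change(cohort)
    return (
        pct.groupby(["group", "timepoint"], sort=False)["pct_change"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count")
        .reset_index()
    )


def summarize(cohort: pd.DataFrame) -> pd.DataFrame:
    """Group x timepoint mean/SD/n plus an equal-n pooled row per timepoint.

    The pooled rows (group label ``"pooled"``) average over all subjects of
    both groups, which for a balanced design equals the unweighted mean of
    the group means.
    """
    _pivot(cohort)
    per_group = (
        cohort.groupby(["group", "timepoint"], sort=False)["count"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1) if len(s) > 1 else np.nan, n="count")
        .reset_index()
    )
    pooled = (
        cohort.groupby("timepoint", sort=False)["count"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1) if len(s) > 1 else np.nan, n="count")
        .reset_index()
    )
    pooled.insert(0, "group", "pooled")
    return pd.concat([per_group, pooled], ignore_index=True)


def _gg_epsilon(resid_wide: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the within-subject covariance of the
    (subject x timepoint) data after removing subject-level structure."""
    k = resid_wide.shape[1]
    if k < 2:
        return float("nan")
    S = np.cov(resid_wide, rowvar=False, ddof=1)
    # double-centre the covariance matrix
    S = S - S.mean(axis=0, keepdims=True) - S.mean(axis=1, keepdims=True) + S.mean()
    tr = np.trace(S)
    denom = (k - 1) * np.sum(S**2)
    if denom <= 0:
        return float("nan")
    eps = tr**2 / denom
    return float(min(1.0, max(eps, 1.0 / (k - 1))))


def rm_anova(cohort: pd.DataFrame) -> AnovaResult:
    """Between-within (split-plot) ANOVA of counts on group and time.

    Group is tested against the subject-within-group mean square; time and
    group x time against the subject x time residual mean square.  Requires a
    complete balanced design with at least two subjects per group.  Raises a
    degenerate-model error when the residual variance is zero.
    """
    wide = _pivot(cohort)
    groups = cohort.drop_duplicates("subject").set_index("subject")["group"]
    tps = timepoint_order(cohort)
    wide = wide[tps]
    glabels = sorted(groups.unique())
    if any((groups == g).sum() < 2 for g in glabels):
        raise ValueError("need at least two subjects per group")

    y = wide.to_numpy(dtype=float)
    n, k = y.shape
    gidx = groups.reindex(wide.index).to_numpy()
    grand = y.mean()

    subj_mean = y.mean(axis=1)
    time_mean = y.mean(axis=0)
    group_means = {g: y[gidx == g].mean() for g in glabels}
    cell_means = {g: y[gidx == g].mean(axis=0) for g in glabels}
    n_g = {g: int((gidx == g).sum()) for g in glabels}

    ss_group = k * sum(n_g[g] * (group_means[g] - grand) ** 2 for g in glabels)
    ss_subj = k * sum(
        ((subj_mean[gidx == g] - group_means[g]) ** 2).sum() for g in glabels
    )
    ss_time = n * ((time_mean - grand) ** 2).sum()
    ss_inter = sum(
        n_g[g] * ((cell_means[g] - time_mean - group_means[g] + grand) ** 2).sum()
        for g in glabels
    )
    ss_total = ((y - grand) ** 2).sum()
    ss_resid = ss_total - ss_group - ss_subj - ss_time - ss_inter

    a = len(glabels)
    df_group = a - 1
    df_subj = n - a
    df_time = k - 1
    df_inter = (a - 1) * (k - 1)
    df_resid = (n - a) * (k - 1)

    ms_subj = ss_subj / df_subj
    ms_resid = ss_resid / df_resid
    if ms_resid <= 0 or ms_subj <= 0:
        raise ValueError("degenerate model: zero residual variance")

    # residual structure for the sphericity estimate: remove the per-group
    # cell means, keeping the subject x time fluctuations
    resid = y.copy()
    for g in glabels:
        resid[gidx == g] -= cell_means[g]
    eps = _gg_epsilon(resid)

    def frow(effect, ss, df, ms_err, df_err, gg):
        ms = ss / df
        F = ms / ms_err
        p = float(sps.f.sf(F, df, df_err))
        if gg and np.isfinite(eps):
            p_gg = float(sps.f.sf(F, df * eps, df_err * eps))
        else:
            p_gg = np.nan
        return dict(effect=effect, ss=ss, df=df, ms=ms, F=F, p=p, p_gg=p_gg)

    rows = [
        frow("group", ss_group, df_group, ms_subj, df_subj, gg=False),
        dict(effect="subject(group)", ss=ss_subj, df=df_subj, ms=ms_subj,
             F=np.nan, p=np.nan, p_gg=np.nan),
        frow("time", ss_time, df_time, ms_resid, df_resid, gg=True),
        frow("group:time", ss_inter, df_inter, ms_resid, df_resid, gg=True),
        dict(effect="residual", ss=ss_resid, df=df_resid, ms=ms_resid,
             F=np.nan, p=np.nan, p_gg=np.nan),
    ]
    return AnovaResult(table=pd.DataFrame(rows), epsilon_gg=eps)


def one_way_time_anova(cohort: pd.DataFrame) -> AnovaResult:
    """One-way repeated-measures ANOVA of counts on time, all subjects pooled
    (subjects, time and residual strata; time tested against the residual)."""
    wide = _pivot(cohort)[timepoint_order(cohort)]
    y = wide.to_numpy(dtype=float)
    n, k = y.shape
    grand = y.mean()
    ss_subj = k * ((y.mean(axis=1) - grand) ** 2).sum()
    ss_time = n * ((y.mean(axis=0) - grand) ** 2).sum()
    ss_total = ((y - grand) ** 2).sum()
    ss_resid = ss_total - ss_subj - ss_time
    df_subj, df_time = n - 1, k - 1
    df_resid = (n - 1) * (k - 1)
    ms_resid = ss_resid / df_resid
    if ms_resid <= 0:
        raise ValueError("degenerate model: zero residual variance")
    resid = y - y.mean(axis=0, keepdims=True)
    eps = _gg_epsilon(resid)
    ms_time = ss_time / df_time
    F = ms_time / ms_resid
    p = float(sps.f.sf(F, df_time, df_resid))
    p_gg = float(sps.f.sf(F, df_time * eps, df_resid * eps)) if np.isfinite(eps) else np.nan
    rows = [
        dict(effect="subject", ss=ss_subj, df=df_subj, ms=ss_subj / df_subj,
             F=np.nan, p=np.nan, p_gg=np.nan),
        dict(effect="time", ss=ss_time, df=df_time, ms=ms_time, F=F, p=p, p_gg=p_gg),
        dict(effect="residual", ss=ss_resid, df=df_resid, ms=ms_resid,
             F=np.nan, p=np.nan, p_gg=np.nan),
    ]
    return AnovaResult(table=pd.DataFrame(rows), epsilon_gg=eps)


def _wilcoxon_exact_pratt(d: np.ndarray) -> tuple[float, float]:
    """Exact two-sided signed-rank p with Pratt zero handling and average
    ranks for ties, by dynamic programming over the 2^n sign assignments.

    Zeros are ranked together with the non-zero differences and then dropped
    from the statistic (Pratt); the null distribution enumerates sign flips
    of the non-zero ranks.  Ranks are doubled internally so tied (half-)
    ranks become integers.
    """
    ranks = sps.rankdata(np.abs(d))  # zeros included in the ranking (Pratt)
    nz = d != 0
    r2 = np.round(ranks[nz] * 2).astype(int)  # doubled ranks, integer
    signs = d[nz] > 0
    w_plus2 = int(r2[signs].sum())
    total2 = int(r2.sum())
    # distribution of doubled W+ over uniform sign assignments
    dist = np.zeros(total2 + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: dist.size - r]
        dist = dist + shifted
    dist /= dist.sum()
    mean2 = total2 / 2.0
    # two-sided: sum of probabilities of outcomes at least as extreme
    dev = abs(w_plus2 - mean2)
    idx = np.arange(dist.size)
    p = float(dist[np.abs(idx - mean2) >= dev - 1e-9].sum())
    w_plus = w_plus2 / 2.0
    return min(w_plus, total2 / 2.0 - w_plus + 0.0), min(1.0, p)


def paired_wilcoxon(a, b, exact_max_n: int = 25) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test of paired samples.

    Zero differences are handled by Pratt's method and ties by average
    ranks.  For n <= ``exact_max_n`` non-zero-inclusive pairs the p-value is
    exact (full enumeration of sign assignments via dynamic programming);
    beyond that the normal approximation with tie and zero corrections is
    used.  All differences zero gives p = 1 by convention.

    Returns ``(statistic, p)`` where the statistic is min(W+, W-) computed
    from the non-zero differences.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 1:
        raise ValueError("need two equal-length 1-D samples")
    d = a - b
    if np.all(d == 0):
        return 0.0, 1.0
    if len(d) <= exact_max_n:
        return _wilcoxon_exact_pratt(d)
    res = sps.wilcoxon(a, b, zero_method="pratt", correction=True, method="approx")
    return float(res.statistic), float(res.pvalue)


def normality_check(values) -> tuple[float, float, bool]:
    """Shapiro-Wilk W, p and a non-normality flag at p < 0.05.

    Requires 3 <= n <= 5000; constant input yields (nan, nan, False) since W
    is undefined there.
    """
    x = np.asarray(values, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk defined for 3 <= n <= 5000")
    if np.ptp(x) == 0:
        return float("nan"), float("nan"), False
    w, p = sps.shapiro(x)
    return float(w), float(p), bool(p < ALPHA)


def subgroup_medians(cohort: pd.DataFrame, labels: dict) -> pd.DataFrame:
    """Median and IQR per subgroup x timepoint.

    ``labels`` maps subject id to subgroup label and must cover every
    subject.  Quartiles use linear interpolation (type-7).  Returns columns
    ``subgroup``, ``timepoint``, ``median``, ``q25``, ``q75``, ``n``.
    """
    missing = set(cohort["subject"]) - set(labels)
    if missing:
        raise ValueError(f"subjects without subgroup label: {sorted(missing)}")
    df = cohort.copy()
    df["subgroup"] = df["subject"].map(labels)
    out = (
        df.groupby(["subgroup", "timepoint"], sort=False)["count"]
        .agg(
            median="median",
            q25=lambda s: float(np.percentile(s, 25)),
            q75=lambda s: float(np.percentile(s, 75)),
            n="count",
        )
        .reset_index()
    )
    return out
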