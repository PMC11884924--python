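"""Statistical machinery: descriptives, repeated-measures ANOVA with
partial eta squared, paired and Welch t tests, exact Mann-Whitney for
small samples, and optional Holm adjustment."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "DescriptiveSummary",
    "descriptive_summary",
    "rm_anova_eta2",
    "paired_t",
    "welch_t",
    "mann_whitney_exact",
    "holm_adjust",
    "phase_contrast_table",
]


@dataclass
class TestResult:
    statistic: float
    p_value: float
    effect_size: float  # partial eta^2 or Cohen's d
    df: float | tuple[float, float]
    n: int
    method: str = ""


@dataclass
class DescriptiveSummary:
    mean: float
    sd: float  # n-1 denominator; NaN for a single value
    n: int


def descriptive_summary(values) -> DescriptiveSummary:
    """Mean and sample standard deviation (n-1 denominator)."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("descriptive_summary requires at least one value")
    sd = float(np.std(x, ddof=1)) if x.size >= 2 else float("nan")
    return DescriptiveSummary(mean=float(np.mean(x)), sd=sd, n=int(x.size))


def rm_anova_eta2(values) -> TestResult:
    """One-way within-subject ANOVA with partial eta squared.

    ``values`` is a subjects x conditions matrix; rows with any missing
    value are dropped (listwise deletion).  Partial eta squared is
    SS_condition / (SS_condition + SS_error).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a subjects x conditions matrix")
    x = x[~np.isnan(x).any(axis=1)]
    n_s, n_c = x.shape
    if n_c < 2:
        raise ValueError("need at least 2 conditions")
    if n_s < 3:
        raise ValueError("need at least 3 complete subjects")

    grand = x.mean()
    ss_cond = n_s * float(np.sum((x.mean(axis=0) - grand) ** 2))
    ss_subj = n_c * float(np.sum((x.mean(axis=1) - grand) ** 2))
    ss_total = float(np.sum((x - grand) ** 2))
    ss_err = ss_total - ss_cond - ss_subj
    df_cond = n_c - 1
    df_err = (n_c - 1) * (n_s - 1)
    if ss_err <= 0:
        if ss_cond == 0:
            return TestResult(0.0, 1.0, 0.0, (df_cond, df_err), n_s, "rm_anova")
        return TestResult(float("inf"), 0.0, 1.0, (df_cond, df_err), n_s, "rm_anova")
    f = (ss_cond / df_cond) / (ss_err / df_err)
    p = float(sps.f.sf(f, df_cond, df_err))
    eta2 = ss_cond / (ss_cond + ss_err)
    return TestResult(float(f), p, float(eta2), (df_cond, df_err), n_s, "rm_anova")


def paired_t(values_a, values_b) -> TestResult:
    """Two-sided paired t test; Cohen's d = mean(diff) / sd(diff)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("paired_t needs two equal-length vectors of length >= 2")
    diff = a - b
    sd = diff.std(ddof=1)
    n = diff.size
    if sd == 0:
        warnings.warn("zero-variance differences: p undefined", stacklevel=2)
        return TestResult(0.0, float("nan"), float("nan"), n - 1, n, "paired_t")
    t = diff.mean() / (sd / np.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), n - 1))
    d = diff.mean() / sd
    return TestResult(float(t), p, float(d), n - 1, n, "paired_t")


def welch_t(group_a, group_b) -> TestResult:
    """Two-sided Welch t test with Satterthwaite df; d uses the pooled SD."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t needs at least 2 values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    if se2 == 0:
        warnings.warn("zero variance in both groups: p undefined", stacklevel=2)
        return TestResult(0.0, float("nan"), float("nan"), na + nb - 2, na + nb, "welch_t")
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    pooled = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    d = (a.mean() - b.mean()) / pooled if pooled > 0 else float("nan")
    return TestResult(float(t), p, float(d), float(df), na + nb, "welch_t")


def _u_statistic(pooled: np.ndarray, idx_a: tuple[int, ...]) -> float:
    """Mann-Whitney U for group A given mid-ranks of the pooled sample."""
    ranks = sps.rankdata(pooled)
    n_a = len(idx_a)
    r_a = float(np.sum(ranks[list(idx_a)]))
    return r_a - n_a * (n_a + 1) / 2.0


def mann_whitney_exact(group_a, group_b, exact_max_n: int = 12) -> TestResult:
    """Two-sided Mann-Whitney U test.

    For pooled n <= ``exact_max_n`` the p value is exact, from full
    enumeration of all group assignments of the observed pooled values
    (ties handled by mid-ranks inside the enumeration).  Larger samples
    fall back to the tie-corrected normal approximation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("each group needs at least one value")
    pooled = np.concatenate([a, b])
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    u_obs = _u_statistic(pooled, tuple(range(n_a)))
    mu = n_a * n_b / 2.0

    if n <= exact_max_n:
        dev_obs = abs(u_obs - mu)
        count = 0
        total = 0
        for idx in combinations(range(n), n_a):
            u = _u_statistic(pooled, idx)
            if abs(u - mu) >= dev_obs - 1e-12:
                count += 1
            total += 1
        p = count / total
        method = "mann_whitney_exact"
    else:
        ranks = sps.rankdata(pooled)
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(counts**3 - counts))
        sigma2 = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if sigma2 <= 0:
            p = 1.0
        else:
            z = max(abs(u_obs - mu) - 0.5, 0.0) / np.sqrt(sigma2)  # continuity corr.
            p = 2.0 * float(sps.norm.sf(z))
        method = "mann_whitney_normal"
    # rank-biserial correlation as effect size
    rbc = 1.0 - 2.0 * u_obs / (n_a * n_b)
    return TestResult(float(u_obs), min(float(p), 1.0), float(rbc), float("nan"), n, method)


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p values (monotone, >= raw)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def phase_contrast_table(table: pd.DataFrame, phases=("Pre", "On", "Post")) -> pd.DataFrame:
    """Per-index phase ANOVA plus pairwise paired-t contrasts.

    ``table`` is a tidy :func:`hrvdbs.paradigm.phase_indices` frame; values
    are averaged per (subject, phase) across days and blocks first.
    """
    rows = []
    for name, sub in table.groupby("index"):
        wide = sub.pivot_table(index="subject", columns="phase", values="value",
                               aggfunc="mean")
        cols = [p for p in phases if p in wide.columns]
        if len(cols) < 2:
            continue
        mat = wide[cols].to_numpy()
        try:
            res = rm_anova_eta2(mat)
            rows.append({"index": name, "contrast": "phase_anova",
                         "statistic": res.statistic, "p_value": res.p_value,
                         "effect_size": res.effect_size, "n": res.n})
        except ValueError:
            pass
        for pa, pb in combinations(cols, 2):
            pair = wide[[pa, pb]].dropna()
            if len(pair) < 2:
                continue
            res = paired_t(pair[pb], pair[pa])
            rows.append({"index": name, "contrast": f"{pb}_vs_{pa}",
                         "statistic": res.statistic, "p_value": res.p_value,
                         "effect_size": res.effect_size, "n": res.n})
    return pd.DataFrame(rows)
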