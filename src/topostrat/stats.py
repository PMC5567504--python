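"""Group comparison layer.

One-way ANOVA (from raw data or from printed group summaries), ANCOVA via
nested linear models, Student two-sample t, Benjamini-Hochberg FDR over a
measure family, and Bonferroni-corrected pairwise post-hocs with direction
flags (the "a>b, a>c" notation of clinical tables).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class StatResult:
    F: float
    df: tuple[int, int]
    p: float
    p_corrected: float | None = None
    posthoc: str | None = None


def _as_groups(values_by_group) -> dict:
    if isinstance(values_by_group, dict):
        return {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    return {i: np.asarray(v, dtype=float) for i, v in enumerate(values_by_group)}


def anova_raw(values_by_group) -> StatResult:
    """Classical one-way F test: F = MS_between / MS_within, df (k-1, N-k)."""
    groups = _as_groups(values_by_group)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for name, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    arrays = list(groups.values())
    if all(np.var(a) == 0 for a in arrays):
        raise ValueError("zero within-group variance in every group")
    F, p = sps.f_oneway(*arrays)
    k = len(arrays)
    N = sum(a.size for a in arrays)
    return StatResult(float(F), (k - 1, N - k), float(p))


def anova_from_summary(means, sds, ns) -> StatResult:
    """One-way ANOVA reconstructed from per-group mean, sample SD and n.

    SS_between = sum n_g (mean_g - grand)^2 over groups;
    SS_within  = sum (n_g - 1) SD_g^2.  Equals :func:`anova_raw` exactly on
    any raw data with those summaries, which is what makes published
    group-summary tables reproducible without subject-level data.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=int)
    if not means.shape == sds.shape == ns.shape or means.ndim != 1:
        raise ValueError("means, sds, ns must be 1-D and equal length")
    if len(means) < 2:
        raise ValueError("need at least 2 groups")
    if (ns < 2).any():
        raise ValueError("every group needs n >= 2")
    N = int(ns.sum())
    k = len(means)
    grand = (ns * means).sum() / N
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((ns - 1) * sds**2).sum())
    if ss_within == 0:
        raise ValueError("zero within-group variance")
    df = (k - 1, N - k)
    F = (ss_between / df[0]) / (ss_within / df[1])
    return StatResult(F, df, float(sps.f.sf(F, *df)))


def ancova(values, group_labels, covariates) -> StatResult:
    """Group effect adjusted for covariates, by nested OLS comparison.

    Full model: intercept + covariates + group indicators; reduced model
    drops the group terms.  F is the extra-sum-of-squares test with
    df (k - 1, N - p_full).
    """
    y = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    X_cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if X_cov.shape[0] != y.size:
        X_cov = X_cov.T
    if X_cov.shape[0] != y.size:
        raise ValueError("covariates do not match the number of observations")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need at least 2 groups")
    intercept = np.ones((y.size, 1))
    X_red = np.hstack([intercept, X_cov])
    if np.linalg.matrix_rank(X_red) < X_red.shape[1]:
        raise ValueError("covariate matrix is rank deficient (collinear)")
    dummies = np.column_stack([(labels == g).astype(float) for g in uniq[1:]])
    X_full = np.hstack([X_red, dummies])
    full = sm.OLS(y, X_full).fit()
    reduced = sm.OLS(y, X_red).fit()
    F, p, df_num = full.compare_f_test(reduced)
    return StatResult(float(F), (int(df_num), int(full.df_resid)), float(p))


def two_sample_t(a, b) -> tuple[float, float]:
    """Student pooled-variance t with df n_a + n_b - 2."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("zero pooled variance")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def bh_correct(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control over one measure family.

    Returns (reject flags, adjusted p-values); rejection at level ``q``
    means all p-values ranked at or below the largest i with
    p_(i) <= (i/m) q.
    """
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def bonferroni_posthoc(
    values_by_group, pairs=None, alpha: float = 0.05
) -> dict:
    """Pairwise pooled-variance t-tests with Bonferroni correction.

    Run only on measures that survived the omnibus test.  Each pair's p is
    multiplied by the number of pairs (capped at 1); the direction string
    orders the two group names by their sample means ("a>b").
    """
    groups = _as_groups(values_by_group)
    names = list(groups)
    if pairs is None:
        pairs = [
            (names[i], names[j])
            for i in range(len(names))
            for j in range(i + 1, len(names))
        ]
    m = len(pairs)
    out = {}
    for a, b in pairs:
        t, p = two_sample_t(groups[a], groups[b])
        p_corr = min(1.0, p * m)
        if groups[a].mean() >= groups[b].mean():
            direction = f"{a}>{b}"
        else:
            direction = f"{a}<{b}"
        out[(a, b)] = {
            "t": t,
            "p_corrected": p_corr,
            "significant": bool(p_corr < alpha),
            "direction": direction,
        }
    return out


def compare_measures(
    table: pd.DataFrame,
    group_labels,
    covariates=None,
    q: float = 0.05,
    posthoc_alpha: float = 0.05,
) -> pd.DataFrame:
    """Omnibus test per column of ``table`` with BH correction across the
    family, plus Bonferroni post-hocs on surviving measures.

    With ``covariates`` the omnibus test is the ANCOVA group F; without, a
    plain one-way ANOVA.  Returns a tidy frame: measure, F, df1, df2, p,
    p_corrected, significant, posthoc ("a>b, a>c" for significant pairs).
    """
    labels = np.asarray(group_labels)
    rows = []
    for col in table.columns:
        y = table[col].to_numpy(dtype=float)
        ok = ~np.isnan(y)
        groups = {g: y[ok & (labels == g)] for g in np.unique(labels)}
        if covariates is None:
            res = anova_raw(groups)
        else:
            cov = np.asarray(covariates, dtype=float)
            res = ancova(y[ok], labels[ok], cov[ok])
        rows.append((col, res.F, res.df[0], res.df[1], res.p))
    out = pd.DataFrame(rows, columns=["measure", "F", "df1", "df2", "p"])
    reject, p_adj = bh_correct(out["p"].to_numpy(), q=q)
    out["p_corrected"] = p_adj
    out["significant"] = reject
    posthocs = []
    for col, sig in zip(out["measure"], out["significant"]):
        if not sig:
            posthocs.append("")
            continue
        y = table[col].to_numpy(dtype=float)
        ok = ~np.isnan(y)
        groups = {g: y[ok & (labels == g)] for g in np.unique(labels)}
        ph = bonferroni_posthoc(groups, alpha=posthoc_alpha)
        posthocs.append(
            ", ".join(v["direction"] for v in ph.values() if v["significant"])
        )
    out["posthoc"] = posthocs
    return out
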