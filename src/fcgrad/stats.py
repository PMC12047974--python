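"""Group inference: confound regression, parcel-wise linear-model t-maps,
rank-based (Mann-Whitney) comparisons with eta-squared effect sizes, BH-FDR,
clinical-score screening/imputation and metric-clinical correlations.

Conventions: all tests are two-sided; FDR is applied within explicitly declared
families (per gradient x contrast for parcel maps, per metric family x contrast
for network tests, per correlation matrix for clinical analyses); the rank-test
effect size is eta-squared = Z^2 / N.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class StatResult:
    """One test result: estimate, two-sided p, BH-adjusted q, effect size."""

    estimate: float
    p: float
    q: float | None = None
    effect_size: float | None = None
    contrast: str = ""
    note: str = ""


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def residualize(
    features: pd.DataFrame | np.ndarray, covariates: pd.DataFrame
) -> pd.DataFrame:
    """OLS residuals of each feature on the covariates, grand mean added back.

    Adding the mean back keeps the residualized features in interpretable units;
    it changes no subsequent rank test or correlation.
    """
    x = np.column_stack([np.ones(len(covariates)), np.asarray(covariates, float)])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("collinear covariates (rank-deficient design)")
    if x.shape[0] <= x.shape[1]:
        raise ValueError("need n > number of covariates + 1")
    was_df = isinstance(features, pd.DataFrame)
    y = np.atleast_2d(np.asarray(features, dtype=float))
    if y.shape[0] != x.shape[0]:
        y = y.T
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta + y.mean(axis=0, keepdims=True)
    if was_df:
        return pd.DataFrame(resid, index=features.index, columns=features.columns)
    return pd.DataFrame(resid)


def _exact_mwu_p(pooled_ranks: np.ndarray, n_a: int, u_obs: float) -> float:
    """Two-sided exact p by full enumeration of group assignments.

    Enumerates all C(n, n_a) assignments of the pooled midranks to group a and
    doubles the smaller tail of the resulting U distribution (ties enter through
    the midranks).
    """
    n = pooled_ranks.size
    offset = n_a * (n_a + 1) / 2.0
    us = np.array(
        [sum(pooled_ranks[list(idx)]) - offset
         for idx in combinations(range(n), n_a)]
    )
    total = comb(n, n_a)
    lo = np.sum(us <= u_obs + 1e-12) / total
    hi = np.sum(us >= u_obs - 1e-12) / total
    return float(min(1.0, 2.0 * min(lo, hi)))


def mann_whitney(a, b, exact_max_n: int = 12) -> StatResult:
    """Mann-Whitney U test with midrank ties, two-sided p and eta-squared.

    The U statistic is reported for sample ``a``. p comes from full enumeration
    when n_a + n_b <= ``exact_max_n``, otherwise from the normal approximation
    with tie and continuity corrections. The effect size is eta^2 = Z^2 / N with
    Z taken from the (tie-corrected, no-continuity) normal approximation.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    pooled = np.concatenate([a, b])
    ranks = scipy.stats.rankdata(pooled)
    u_a = ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0

    if np.all(pooled == pooled[0]):
        return StatResult(estimate=u_a, p=1.0, effect_size=0.0,
                          note="all values identical across both samples")

    mu = n_a * n_b / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    sigma2 = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    sigma = np.sqrt(sigma2)
    z_plain = (u_a - mu) / sigma
    eta_sq = float(z_plain**2 / n)

    if n <= exact_max_n:
        p = _exact_mwu_p(ranks, n_a, u_a)
    else:
        z_cc = (u_a - mu - 0.5 * np.sign(u_a - mu)) / sigma
        p = float(2.0 * scipy.stats.norm.sf(abs(z_cc)))
        p = min(1.0, p)
    return StatResult(estimate=float(u_a), p=p, effect_size=eta_sq)


def regional_glm(
    scores: pd.DataFrame | np.ndarray,
    group: pd.Series | np.ndarray,
    contrast: tuple[str, object],
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Parcel-wise fixed-effects linear model t-map for a two-level group contrast.

    Per parcel, OLS of the gradient score on a group indicator (1 for the second
    member of ``contrast``; the second member may be a list of labels pooled as
    "patients combined") plus covariates. Returns a tidy frame with t, p and q
    (BH-FDR across the parcels of this map — one FDR family per gradient x
    contrast).
    """
    ref, other = contrast
    group = pd.Series(np.asarray(group))
    other_set = {other} if isinstance(other, str) else set(other)
    mask = group.isin(other_set | {ref}).to_numpy()
    if mask.sum() < 4:
        raise ValueError("too few subjects in contrasted groups")
    g = group[mask].isin(other_set).to_numpy().astype(float)
    if g.sum() < 2 or (1 - g).sum() < 2:
        raise ValueError("need >= 2 subjects per contrasted group")
    y = np.atleast_2d(np.asarray(scores, dtype=float))[mask]
    cols = [np.ones(mask.sum()), g]
    if covariates is not None:
        cols.append(np.asarray(covariates, float)[mask])
    x = np.column_stack(cols)
    n, k = x.shape
    if np.linalg.matrix_rank(x) < k or n <= k:
        raise ValueError("degenerate design (rank deficient or n <= parameters)")
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    dof = n - k
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[1] / se
    p = 2.0 * scipy.stats.t.sf(np.abs(t), dof)
    out = pd.DataFrame({
        "parcel_id": np.arange(y.shape[1]),
        "t": t,
        "p": p,
        "q": fdr_bh(p),
    })
    out.attrs["contrast"] = f"{ref} vs {other}"
    out.attrs["dof"] = dof
    return out


def screen_and_impute_clinical(
    cohort: pd.DataFrame,
    clinical_columns: list[str],
    group_column: str = "group",
    max_missing_fraction: float = 0.30,
) -> tuple[pd.DataFrame, dict]:
    """Exclude subjects with > 30% missing clinical entries; impute the rest.

    Remaining missing values are replaced by the median of the subject's group
    for that column (strictly-more-than rule: exactly 30% missing is retained).
    Returns the screened/imputed table and a report of counts.
    """
    if group_column not in cohort.columns:
        raise ValueError(f"missing group column {group_column!r}")
    clin = cohort[clinical_columns]
    frac = clin.isna().mean(axis=1)
    keep = frac <= max_missing_fraction + 1e-12
    out = cohort.loc[keep].copy()
    n_imputed = 0
    for col in clinical_columns:
        for grp, sub in out.groupby(group_column, observed=True):
            vals = sub[col]
            if vals.isna().all():
                raise ValueError(
                    f"clinical column {col!r} entirely missing within group {grp!r}"
                )
            miss = vals.isna()
            if miss.any():
                out.loc[vals.index[miss], col] = vals.median()
                n_imputed += int(miss.sum())
    report = {"n_dropped": int((~keep).sum()), "n_imputed": n_imputed}
    return out, report


def clinical_correlations(
    metrics: pd.DataFrame,
    clinical: pd.DataFrame,
    method: str = "spearman",
) -> pd.DataFrame:
    """Correlation of every (metric, clinical score) pair with BH-FDR.

    Spearman by default (consistent with the rank-based group tests); Pearson by
    ``method="pearson"``. Constant columns yield NA and are excluded from the
    FDR family. Rows must be matched subjects in both tables.
    """
    if len(metrics) != len(clinical):
        raise ValueError("metrics and clinical tables must have matching subjects")
    corr = scipy.stats.spearmanr if method == "spearman" else scipy.stats.pearsonr
    rows = []
    for mcol in metrics.columns:
        for ccol in clinical.columns:
            x = metrics[mcol].to_numpy(dtype=float)
            y = clinical[ccol].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                rows.append((mcol, ccol, np.nan, np.nan))
                continue
            r, p = corr(x, y)
            rows.append((mcol, ccol, float(r), float(p)))
    out = pd.DataFrame(rows, columns=["metric", "clinical", "r", "p"])
    valid = out["p"].notna()
    out["q"] = np.nan
    if valid.any():
        out.loc[valid, "q"] = fdr_bh(out.loc[valid, "p"].to_numpy())
    return out


def explained_variance_anova(
    values, groups
) -> tuple[StatResult, tuple[int, int]]:
    """One-way fixed-effects F-test of explained-variance ratios across groups."""
    values = np.asarray(values, dtype=float)
    groups = pd.Series(np.asarray(groups))
    samples = [values[(groups == g).to_numpy()] for g in pd.unique(groups)]
    if len(samples) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs >= 2 subjects")
    f, p = scipy.stats.f_oneway(*samples)
    df1 = len(samples) - 1
    df2 = values.size - len(samples)
    return StatResult(estimate=float(f), p=float(p)), (df1, df2)


def network_comparisons(
    metrics: pd.DataFrame,
    cohort: pd.DataFrame,
    contrasts: list[tuple[str, object]],
    covariate_columns: tuple[str, ...] = ("age", "sex", "mean_fd"),
    group_column: str = "group",
) -> pd.DataFrame:
    """Mann-Whitney comparison of every differentiation metric, per contrast.

    Metrics are confound-regressed (age, sex, mean FD) over the full cohort
    first; each contrast then compares the reference group against one patient
    group (or a pooled patient list). BH-FDR is applied within each declared
    family (metric family x contrast).
    """
    from .differentiation import metric_family

    resid = residualize(metrics, cohort[list(covariate_columns)])
    group = cohort[group_column]
    rows = []
    for ref, other in contrasts:
        other_set = {other} if isinstance(other, str) else set(other)
        label = f"{ref} vs {'+'.join(sorted(other_set)) if not isinstance(other, str) else other}"
        a_mask = (group == ref).to_numpy()
        b_mask = group.isin(other_set).to_numpy()
        for col in metrics.columns:
            res = mann_whitney(resid.loc[a_mask, col], resid.loc[b_mask, col])
            rows.append({
                "contrast": label,
                "family": metric_family(col),
                "unit": col,
                "estimate": res.estimate,
                "p": res.p,
                "effect_size": res.effect_size,
            })
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    for (_, _), idx in out.groupby(["contrast", "family"]).groups.items():
        out.loc[idx, "q"] = fdr_bh(out.loc[idx, "p"].to_numpy())
    return out
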