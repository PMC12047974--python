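"""Empirical-Bayes batch harmonization of feature tables across acquisition sites.

Implements the classic parametric location/scale model (Johnson, Li & Rabinovic):
feature-wise linear fit of site and preserved biological covariates, feature
standardization, empirical-Bayes shrinkage of per-site location (Normal prior)
and scale (Inverse-Gamma prior) via the standard iterative conditional updates,
then adjustment and restoration of the preserved effects. Deterministic; matches
the canonical reference implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CombatResult:
    """Harmonized features plus the per-site location/scale estimates."""

    adjusted: pd.DataFrame
    gamma_star: pd.DataFrame  # sites x features, EB-shrunk additive site effects
    delta_sq_star: pd.DataFrame  # sites x features, EB-shrunk multiplicative site effects


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def _it_sol(
    sdat: np.ndarray,
    g_hat: np.ndarray,
    d_hat: np.ndarray,
    g_bar: float,
    t2: float,
    a: float,
    b: float,
    conv: float = 1e-4,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative conditional posterior-mean updates for one site.

    sdat: features x subjects standardized data for the site.
    """
    n = sdat.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    while True:
        g_new = (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)
        sum2 = ((sdat - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old) / np.abs(g_old)),
            np.max(np.abs(d_new - d_old) / d_old),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            return g_new, d_new


def combat_adjust(
    features: pd.DataFrame,
    site: pd.Series | np.ndarray,
    design: pd.DataFrame | None = None,
    allow_single_site: bool = False,
    conv: float = 1e-4,
) -> CombatResult:
    """Harmonize a subjects-by-features table across sites.

    Parameters
    ----------
    features:
        Rows = subjects, columns = features (e.g. per-parcel gradient scores or
        derived metrics). No missing entries.
    site:
        Per-subject site label; every site needs >= 2 subjects.
    design:
        Biological covariates to preserve (group indicators, age, sex, mean FD),
        one row per subject; must be full column rank. An intercept is implicit
        (the site indicators span it). May be None.
    allow_single_site:
        Normally a lone site is an error (nothing can be harmonized against it);
        with this flag a single-site table round-trips unchanged, which is the
        expected degenerate behaviour in testing.

    Notes
    -----
    Preserved covariate effects are estimated jointly with site means, removed
    before standardization and added back after adjustment, so group differences
    encoded in ``design`` survive harmonization.
    """
    x = features.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("feature table contains missing entries")
    n_sub, n_feat = x.shape
    site = pd.Series(np.asarray(site), name="site")
    levels = list(pd.unique(site))
    counts = site.value_counts()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(
            f"singleton site(s) {bad}: cannot estimate site effects; "
            "exclude these subjects or sites"
        )
    if len(levels) < 2:
        if not allow_single_site:
            raise ValueError("need >= 2 sites to harmonize (allow_single_site=False)")
        zero = pd.DataFrame(
            np.zeros((1, n_feat)), index=levels, columns=features.columns
        )
        one = pd.DataFrame(np.ones((1, n_feat)), index=levels, columns=features.columns)
        return CombatResult(features.copy(), zero, one)

    batch = pd.get_dummies(site).astype(float)[levels].to_numpy()  # n_sub x n_batch
    n_batch = len(levels)
    if design is not None:
        cov = np.asarray(design, dtype=float)
        dmat = np.column_stack([batch, cov])
    else:
        dmat = batch
    if np.linalg.matrix_rank(dmat) < dmat.shape[1]:
        raise ValueError("design matrix (site + covariates) is rank deficient")

    # work features-as-rows from here on
    dat = x.T  # n_feat x n_sub
    beta = np.linalg.solve(dmat.T @ dmat, dmat.T @ dat.T)  # n_params x n_feat
    n_per = batch.sum(axis=0)
    grand_mean = (n_per / n_sub) @ beta[:n_batch, :]  # weighted mean of site intercepts
    resid = dat - (dmat @ beta).T
    var_pooled = (resid**2).mean(axis=1)  # 1/n convention of the reference model
    if np.any(var_pooled == 0):
        raise ValueError("constant feature (zero pooled variance); drop it first")

    stand_mean = np.tile(grand_mean[:, None], (1, n_sub))
    if design is not None:
        stand_mean = stand_mean + (cov @ beta[n_batch:, :]).T
    sdat = (dat - stand_mean) / np.sqrt(var_pooled)[:, None]

    # per-site location/scale estimates on the standardized scale
    gamma_hat = np.linalg.solve(batch.T @ batch, batch.T @ sdat.T)  # n_batch x n_feat
    delta_hat = np.vstack(
        [sdat[:, batch[:, i] == 1].var(axis=1, ddof=1) for i in range(n_batch)]
    )

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    for i in range(n_batch):
        g_bar = gamma_hat[i].mean()
        t2 = gamma_hat[i].var(ddof=1)
        a = _aprior(delta_hat[i])
        b = _bprior(delta_hat[i])
        g, d = _it_sol(
            sdat[:, batch[:, i] == 1], gamma_hat[i], delta_hat[i], g_bar, t2, a, b, conv
        )
        gamma_star[i], delta_star[i] = g, d

    bayes = sdat.copy()
    for i in range(n_batch):
        mask = batch[:, i] == 1
        bayes[:, mask] = (bayes[:, mask] - gamma_star[i][:, None]) / np.sqrt(
            delta_star[i]
        )[:, None]
    bayes = bayes * np.sqrt(var_pooled)[:, None] + stand_mean

    adjusted = pd.DataFrame(bayes.T, index=features.index, columns=features.columns)
    return CombatResult(
        adjusted,
        pd.DataFrame(gamma_star, index=levels, columns=features.columns),
        pd.DataFrame(delta_star, index=levels, columns=features.columns),
    )
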