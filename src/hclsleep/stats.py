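"""Cohort statistics: intraclass correlations, Spearman correlation
matrices with Benjamini-Hochberg FDR control, and the general linear model
relating mid-sleep time to its endogenous (intrinsic period) and exogenous
(biological effect of light) drivers.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class ICCResult:
    """Variance components of the random-intercept model
    y_ij = b0 + b_j + e_ij with b_j ~ N(0, sigma_b2), e_ij ~ N(0, sigma2);
    ICC = sigma_b2 / (sigma_b2 + sigma2)."""

    sigma_b2: float
    sigma2: float

    @property
    def icc(self) -> float:
        tot = self.sigma_b2 + self.sigma2
        return self.sigma_b2 / tot if tot > 0 else math.nan


def icc(values, groups) -> ICCResult:
    """Intraclass correlation of daily values grouped by participant.

    Fits the random-intercept mixed model by REML; if the fit fails to
    converge, falls back to one-way ANOVA method-of-moments estimates with
    negative between-participant components truncated at zero.
    """
    df = pd.DataFrame({"y": np.asarray(values, dtype=float),
                       "g": np.asarray(groups)}).dropna()
    counts = df.groupby("g").size()
    if len(counts) < 2 or (counts >= 2).sum() < 2:
        raise ValueError("ICC requires >= 2 participants with >= 2 days each")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm("y ~ 1", df, groups=df["g"])
            fit = model.fit(reml=True)
        sigma_b2 = float(fit.cov_re.iloc[0, 0])
        sigma2 = float(fit.scale)
        if not (math.isfinite(sigma_b2) and math.isfinite(sigma2)):
            raise ValueError("non-finite variance components")
    except (ValueError, np.linalg.LinAlgError):
        sigma_b2, sigma2 = _icc_moments(df)
    return ICCResult(sigma_b2=max(sigma_b2, 0.0), sigma2=sigma2)


def _icc_moments(df: pd.DataFrame) -> tuple[float, float]:
    """One-way ANOVA method-of-moments variance components (unbalanced)."""
    groups = [g["y"].to_numpy() for _, g in df.groupby("g")]
    k = len(groups)
    n_i = np.array([len(g) for g in groups], dtype=float)
    N = n_i.sum()
    grand = df["y"].mean()
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    ss_between = float((n_i * (np.array([g.mean() for g in groups])
                               - grand) ** 2).sum())
    ms_within = ss_within / (N - k)
    ms_between = ss_between / (k - 1)
    n0 = (N - (n_i ** 2).sum() / N) / (k - 1)
    sigma_b2 = max((ms_between - ms_within) / n0, 0.0)
    return sigma_b2, ms_within


# ---------------------------------------------------------------------------
# Spearman correlations with FDR control
# ---------------------------------------------------------------------------

def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided exact permutation p-value for Spearman's rho (small n)."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    n = len(rx)
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perm = ry[perms]
    rx_c = rx - rx.mean()
    ry_c = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    num = ry_c @ rx_c
    den = np.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum(axis=1))
    rhos = num / den
    return float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))


def spearman_bh(table: pd.DataFrame, pairs: list[tuple[str, str]],
                q: float = 0.05, min_pairs: int = 5) -> pd.DataFrame:
    """Spearman rank correlations for the given variable pairs, with
    Benjamini-Hochberg step-up control of the false discovery rate at
    level ``q`` across the tested family.

    P-values use the t approximation for n >= 10 and an exact permutation
    null below that.  Constant columns give undefined rho and are flagged
    rather than dropped silently.
    """
    rows = []
    for a, b in pairs:
        sub = table[[a, b]].dropna()
        n = len(sub)
        if n < min_pairs:
            raise ValueError(f"pair ({a}, {b}) has only {n} complete pairs")
        x, y = sub[a].to_numpy(float), sub[b].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append({"var1": a, "var2": b, "n": n, "rho": math.nan,
                         "p": math.nan, "defined": False})
            continue
        if n >= 10:
            rho, p = sps.spearmanr(x, y)
        else:
            rho, _ = sps.spearmanr(x, y)
            p = _spearman_exact_p(x, y, rho)
        rows.append({"var1": a, "var2": b, "n": n, "rho": float(rho),
                     "p": float(p), "defined": True})
    out = pd.DataFrame(rows)
    mask = out["defined"].to_numpy()
    sig = np.zeros(len(out), dtype=bool)
    if mask.any():
        reject, *_ = multipletests(out.loc[mask, "p"], alpha=q,
                                   method="fdr_bh")
        sig[mask] = reject
    out["significant"] = sig
    # the largest BH-passing p, reported in the style 'p <= threshold'
    passed = out.loc[out["significant"], "p"]
    out.attrs["bh_threshold"] = float(passed.max()) if len(passed) else 0.0
    return out


# ---------------------------------------------------------------------------
# General linear model for mid-sleep
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GLMResult:
    """OLS of mid-sleep time (noon-anchored decimal hours) on the
    biological effect of light (hours) and the fitted intrinsic period
    deviation (tauc - 24.2 h)."""

    intercept: float
    coef_Ltime: float
    coef_tauc: float
    r2: float
    adjusted_r2: float

    def predict(self, Ltime, tauc):
        return (self.intercept + self.coef_Ltime * np.asarray(Ltime)
                + self.coef_tauc * (np.asarray(tauc) - 24.2))


def glm_midsleep(table: pd.DataFrame, mid_col: str = "mid_sleep",
                 ltime_col: str = "bio_effect_hours",
                 tauc_col: str = "tauc") -> GLMResult:
    """Fit mid-sleep ~ L_time + (tauc - 24.2) by ordinary least squares."""
    sub = table[[mid_col, ltime_col, tauc_col]].dropna()
    X = np.column_stack([sub[ltime_col].to_numpy(float),
                         sub[tauc_col].to_numpy(float) - 24.2])
    Xd = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        raise np.linalg.LinAlgError("collinear predictors in mid-sleep GLM")
    fit = sm.OLS(sub[mid_col].to_numpy(float), Xd).fit()
    return GLMResult(intercept=float(fit.params[0]),
                     coef_Ltime=float(fit.params[1]),
                     coef_tauc=float(fit.params[2]),
                     r2=float(fit.rsquared),
                     adjusted_r2=float(fit.rsquared_adj))


def adjusted_r2_single(table: pd.DataFrame, response: str,
                       predictor: str) -> float:
    """Adjusted R^2 of a single-predictor OLS (for driver comparisons)."""
    sub = table[[response, predictor]].dropna()
    X = sm.add_constant(sub[predictor].to_numpy(float))
    return float(sm.OLS(sub[response].to_numpy(float), X).fit().rsquared_adj)
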