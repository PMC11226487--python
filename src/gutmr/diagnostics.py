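"""Heterogeneity, pleiotropy, outlier, and influence diagnostics.

* Cochran's Q over per-SNP Wald ratios (chi-square, J-1 df) drives the
  fixed- vs random-effects IVW choice downstream (heterogeneity at p < 0.05).
* MR-PRESSO: a resampling global test on the leave-one-out residual sum of
  squares, with per-SNP empirical outlier p-values (Bonferroni over J) and a
  descriptive distortion assessment.
* Leave-one-out IVW re-estimation with a qualitative stability flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import Z95, IVW, MREstimate, _arrays, _require

__all__ = [
    "cochran_q", "mr_presso", "leave_one_out", "PressoResult", "DiagnosticsReport",
]


def cochran_q(insts: pd.DataFrame):
    """Cochran's Q at the fixed-effects IVW estimate.

    Q = sum_j w_j (ratio_j - beta_ivw)^2 with w_j = 1/ratio_se_j^2; the
    p-value is the upper tail of chi-square with J-1 degrees of freedom.

    Returns (q_stat, q_df, q_pval).
    """
    _require(insts, 2, "cochran_q")
    *_, ratio, ratio_se = _arrays(insts)
    w = 1.0 / ratio_se ** 2
    beta = np.sum(w * ratio) / np.sum(w)
    q = float(np.sum(w * (ratio - beta) ** 2))
    df = len(ratio) - 1
    return q, df, float(stats.chi2.sf(q, df))


def _loo_slopes(bx, by, w):
    """Per-SNP leave-one-out weighted through-origin slopes, vectorized.

    bx/by may be 1-D (J,) or 2-D (n_sim, J); w is (J,)."""
    sxx = np.sum(w * bx * bx, axis=-1, keepdims=True)
    sxy = np.sum(w * bx * by, axis=-1, keepdims=True)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


@dataclass
class PressoResult:
    global_rss: float
    global_p: float
    per_snp_p: pd.Series
    outliers: list
    distortion_coef: float | None = None
    distortion_p: float | None = None


def mr_presso(insts: pd.DataFrame, n_sim: int = 1000, seed: int = 0,
              outlier_alpha: float = 0.05) -> PressoResult:
    """MR-PRESSO global and outlier tests.

    The observed statistic is RSS = sum_j w_j (beta_out_j - b_(-j) *
    beta_exp_j)^2 with w_j = 1/se_out_j^2 and b_(-j) the inverse-variance
    slope excluding SNP j. The null distribution comes from ``n_sim``
    parametric draws beta_out_j* ~ N(b_(-j) beta_exp_j, se_out_j) and
    beta_exp_j* ~ N(beta_exp_j, se_exp_j), recomputing the statistic on each
    draw. Empirical p-values use the (1 + k) / (1 + n_sim) estimator; SNP j
    is an outlier when its per-SNP empirical p, Bonferroni-adjusted over J,
    is below ``outlier_alpha``.

    When outliers are found, the distortion of the outlier-corrected slope is
    reported descriptively: its percent change from the all-SNP slope, with an
    empirical two-sided p against slopes from removing random subsets of the
    same size. Distortion never gates any decision.
    """
    _require(insts, 4, "mr_presso")
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    bx, sx, by, sy, *_ = _arrays(insts)
    snp_ids = list(insts["snp_id"]) if "snp_id" in insts.columns else list(range(len(bx)))
    w = 1.0 / sy ** 2
    rng = np.random.default_rng(seed)

    slopes_loo = _loo_slopes(bx, by, w)
    resid = by - slopes_loo * bx
    contrib = w * resid ** 2
    rss_obs = float(contrib.sum())

    bys = rng.normal(slopes_loo * bx, sy, size=(n_sim, len(bx)))
    bxs = rng.normal(bx, sx, size=(n_sim, len(bx)))
    slopes_s = _loo_slopes(bxs, bys, w)
    contrib_s = w * (bys - slopes_s * bxs) ** 2
    rss_s = contrib_s.sum(axis=1)

    global_p = float((1 + np.sum(rss_s >= rss_obs)) / (n_sim + 1))
    per_p = (1 + np.sum(contrib_s >= contrib, axis=0)) / (n_sim + 1)
    per_snp_p = pd.Series(per_p, index=snp_ids, name="presso_p")
    j = len(bx)
    outliers = [sid for sid, p in zip(snp_ids, per_p) if p * j < outlier_alpha]

    distortion_coef = distortion_p = None
    if outliers and len(outliers) < j:
        keep = ~np.isin(snp_ids, outliers)
        slope_all = float(np.sum(w * bx * by) / np.sum(w * bx * bx))
        slope_corr = float(np.sum((w * bx * by)[keep]) / np.sum((w * bx * bx)[keep]))
        if slope_all != 0:
            distortion_coef = 100.0 * (slope_corr - slope_all) / abs(slope_all)
        n_out = len(outliers)
        drops = np.array([rng.choice(j, size=n_out, replace=False) for _ in range(n_sim)])
        mask = np.ones((n_sim, j), dtype=bool)
        np.put_along_axis(mask, drops, False, axis=1)
        num = np.sum(np.where(mask, w * bx * by, 0.0), axis=1)
        den = np.sum(np.where(mask, w * bx * bx, 0.0), axis=1)
        sub_slopes = num / den
        k = np.sum(np.abs(sub_slopes - slope_all) >= abs(slope_corr - slope_all))
        distortion_p = float((1 + k) / (n_sim + 1))

    return PressoResult(global_rss=rss_obs, global_p=global_p, per_snp_p=per_snp_p,
                        outliers=outliers, distortion_coef=distortion_coef,
                        distortion_p=distortion_p)


def leave_one_out(insts: pd.DataFrame, effects_model: str = "fixed"):
    """IVW re-estimated once per left-out SNP, plus the full-set reference row.

    Returns (loo_table, stable) where the table has one row per left-out SNP
    labelled by snp_id and a final ``(all)`` reference row (columns: n_snp,
    beta, se, pval, ci_low, ci_high on the log-odds scale). ``stable`` is
    True when every leave-one-out CI overlaps the full-set CI and no
    nominally significant leave-one-out fit changes sign relative to the
    full-set estimate.
    """
    _require(insts, 3, "leave_one_out")
    full = IVW(effects_model=effects_model).fit(insts).estimate_
    rows = []
    for i in range(len(insts)):
        sub = insts.drop(insts.index[i])
        est = IVW(effects_model=effects_model).fit(sub).estimate_
        rows.append((insts["snp_id"].iloc[i], est))
    rows.append(("(all)", full))

    table = pd.DataFrame({
        "snp_id": [sid for sid, _ in rows],
        "n_snp": [e.n_snp for _, e in rows],
        "beta": [e.beta for _, e in rows],
        "se": [e.se for _, e in rows],
        "pval": [e.pval for _, e in rows],
        "ci_low": [e.beta - Z95 * e.se for _, e in rows],
        "ci_high": [e.beta + Z95 * e.se for _, e in rows],
    })
    full_lo, full_hi = full.beta - Z95 * full.se, full.beta + Z95 * full.se
    loo = table.iloc[:-1]
    overlaps = (loo["ci_low"] <= full_hi) & (loo["ci_high"] >= full_lo)
    signif = loo["pval"] < 0.05
    sign_ok = ~signif | (np.sign(loo["beta"]) == np.sign(full.beta))
    stable = bool(overlaps.all() and sign_ok.all())
    return table, stable


@dataclass
class DiagnosticsReport:
    """Per exposure-outcome diagnostics bundle; fields are None when the
    instrument count is below the diagnostic's minimum."""

    q_stat: float | None = None
    q_df: int | None = None
    q_pval: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    presso_global_rss: float | None = None
    presso_global_p: float | None = None
    presso_outliers: list = field(default_factory=list)
    presso_distortion_coef: float | None = None
    presso_distortion_p: float | None = None
    loo_table: pd.DataFrame | None = None
    loo_stable: bool | None = None
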