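"""Causal-effect estimators for summary-statistic Mendelian randomization.

Each estimator consumes a harmonized-instrument table (columns ``beta_exp``,
``se_exp``, ``beta_out``, ``se_out``; ``ratio``/``ratio_se`` are derived if
absent) and produces a causal log-odds slope with its standard error,
two-sided normal p-value, and odds ratio with 95% CI.

Estimators are scikit-learn style: ``fit(instruments)`` populates
trailing-underscore attributes (``beta_``, ``se_``, ``pval_``, ``or_``,
``ci_low_``, ``ci_high_``, ``n_snp_``) and ``estimate_`` bundles them into an
:class:`MREstimate`. Module-level functions (:func:`ivw`, :func:`mr_egger`,
...) are thin wrappers over the classes.

Conventions
-----------
* Per-SNP weights are inverse squared delta-method ratio SEs,
  w_j = 1 / ratio_se_j**2 = beta_exp_j**2 / se_out_j**2, which makes IVW
  identical to weighted least squares of beta_out on beta_exp through the
  origin with weights 1 / se_out**2.
* Random-effects IVW is multiplicative: the fixed-effects SE is inflated by
  max(1, sqrt(Q / (J - 1))) and never shrinks below it.
* MR-Egger internally orients every instrument so beta_exp > 0 (the slope is
  not orientation-invariant); its SEs carry the multiplicative
  overdispersion scale max(1, sqrt(RSS_w / (J - 2))).
* p-values are two-sided normal throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .exceptions import (
    CollinearityError,
    InsufficientInstrumentsError,
    UndefinedRatioError,
)

Z95 = float(stats.norm.ppf(0.975))


@dataclass
class MREstimate:
    """One method's causal estimate on the log-odds scale, with OR and CI."""

    method: str
    beta: float
    se: float
    pval: float
    or_: float
    ci_low: float
    ci_high: float
    n_snp: int

    @classmethod
    def from_beta_se(cls, method: str, beta: float, se: float, n_snp: int) -> "MREstimate":
        beta, se = float(beta), float(se)
        z = abs(beta) / se if se > 0 else np.inf
        pval = float(max(2.0 * stats.norm.sf(z), np.finfo(float).tiny))
        return cls(method=method, beta=beta, se=se, pval=pval,
                   or_=float(np.exp(beta)),
                   ci_low=float(np.exp(beta - Z95 * se)),
                   ci_high=float(np.exp(beta + Z95 * se)),
                   n_snp=int(n_snp))


@dataclass
class EggerFit:
    """MR-Egger slope plus the directional-pleiotropy intercept test."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_p: float


def _arrays(instruments: pd.DataFrame):
    bx = np.asarray(instruments["beta_exp"], dtype=float)
    sx = np.asarray(instruments["se_exp"], dtype=float)
    by = np.asarray(instruments["beta_out"], dtype=float)
    sy = np.asarray(instruments["se_out"], dtype=float)
    if "ratio" in instruments.columns:
        ratio = np.asarray(instruments["ratio"], dtype=float)
        ratio_se = np.asarray(instruments["ratio_se"], dtype=float)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = by / bx
            ratio_se = sy / np.abs(bx)
    return bx, sx, by, sy, ratio, ratio_se


def _require(instruments: pd.DataFrame, min_snp: int, method: str):
    if len(instruments) < min_snp:
        raise InsufficientInstrumentsError(
            f"{method} needs >= {min_snp} instruments, got {len(instruments)}")


class _MRBase(BaseEstimator):
    """Shared fit plumbing; subclasses implement ``_fit_arrays``."""

    method: str = ""
    _min_snp: int = 1

    def fit(self, instruments: pd.DataFrame, y=None):
        _require(instruments, self._min_snp, self.method)
        self.n_snp_ = len(instruments)
        beta, se = self._fit_arrays(*_arrays(instruments))
        est = MREstimate.from_beta_se(self.method, beta, se, self.n_snp_)
        self.beta_, self.se_, self.pval_ = est.beta, est.se, est.pval
        self.or_, self.ci_low_, self.ci_high_ = est.or_, est.ci_low, est.ci_high
        self.estimate_ = est
        return self


class WaldRatio(_MRBase):
    """Single-instrument causal estimate beta_out / beta_exp."""

    method = "wald_ratio"
    _min_snp = 1

    def _fit_arrays(self, bx, sx, by, sy, ratio, ratio_se):
        if bx[0] == 0:
            raise UndefinedRatioError("beta_exp is zero; Wald ratio undefined")
        return ratio[0], ratio_se[0]


def _ivw_point(ratio, w):
    return float(np.sum(w * ratio) / np.sum(w))


def _cochran_q(ratio, w, beta):
    return float(np.sum(w * (ratio - beta) ** 2))


class IVW(_MRBase):
    """Inverse-variance weighted estimator.

    Parameters
    ----------
    effects_model : {"fixed", "random"}
        "random" applies the multiplicative overdispersion inflation
        max(1, sqrt(Q / (J - 1))) to the fixed-effects SE.

    Fitted attributes include ``q_stat_`` (Cochran's Q at the fixed-effects
    estimate) in addition to the common set.
    """

    _min_snp = 2

    def __init__(self, effects_model: str = "fixed"):
        self.effects_model = effects_model

    @property
    def method(self):
        return f"ivw_{self.effects_model}"

    def _fit_arrays(self, bx, sx, by, sy, ratio, ratio_se):
        if self.effects_model not in ("fixed", "random"):
            raise ValueError(f"unknown effects_model {self.effects_model!r}")
        w = 1.0 / ratio_se ** 2
        beta = _ivw_point(ratio, w)
        se = float(np.sqrt(1.0 / np.sum(w)))
        self.q_stat_ = _cochran_q(ratio, w, beta)
        if self.effects_model == "random":
            se *= max(1.0, np.sqrt(self.q_stat_ / (len(ratio) - 1)))
        return beta, se


class EggerRegression(_MRBase):
    """MR-Egger: weighted regression of beta_out on beta_exp with intercept.

    A nonzero intercept indicates directional horizontal pleiotropy; the
    intercept test p-value (two-sided normal) feeds the pipeline's
    pleiotropy flag. Instruments are oriented internally so beta_exp > 0.
    """

    method = "egger"
    _min_snp = 3

    def fit(self, instruments: pd.DataFrame, y=None):
        _require(instruments, self._min_snp, self.method)
        bx, sx, by, sy, ratio, ratio_se = _arrays(instruments)
        sign = np.where(bx < 0, -1.0, 1.0)
        x, yv = bx * sign, by * sign
        if np.ptp(x) == 0:
            raise CollinearityError("beta_exp has zero variance; Egger slope undefined")
        w = 1.0 / sy ** 2
        res = sm.WLS(yv, sm.add_constant(x), weights=w).fit()
        # multiplicative overdispersion, floored at 1 (never below the
        # known-weights SE); res.scale is RSS_w/(J-2)
        infl = max(1.0, float(np.sqrt(res.scale)))
        inter, slope = res.params
        inter_se, slope_se = np.sqrt(np.diag(res.normalized_cov_params)) * infl

        self.n_snp_ = len(instruments)
        est = MREstimate.from_beta_se(self.method, slope, slope_se, self.n_snp_)
        self.beta_, self.se_, self.pval_ = est.beta, est.se, est.pval
        self.or_, self.ci_low_, self.ci_high_ = est.or_, est.ci_low, est.ci_high
        self.intercept_ = float(inter)
        self.intercept_se_ = float(inter_se)
        z = abs(inter) / inter_se if inter_se > 0 else np.inf
        self.intercept_pval_ = float(max(2.0 * stats.norm.sf(z), np.finfo(float).tiny))
        self.estimate_ = est
        self.egger_fit_ = EggerFit(slope=est, intercept=self.intercept_,
                                   intercept_se=self.intercept_se_,
                                   intercept_p=self.intercept_pval_)
        return self


def _weighted_median_rows(ratios: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-wise weighted median by interpolating the cumulative weight at 0.5.

    ``ratios`` and ``weights`` are (n_rows, J); returns (n_rows,).
    """
    order = np.argsort(ratios, axis=1)
    r = np.take_along_axis(ratios, order, axis=1)
    w = np.take_along_axis(weights, order, axis=1)
    wn = w / w.sum(axis=1, keepdims=True)
    s = np.cumsum(wn, axis=1) - wn / 2.0
    n = r.shape[1]
    k = (s < 0.5).sum(axis=1)  # first midpoint position >= 0.5
    lo = np.clip(k - 1, 0, n - 1)[:, None]
    hi = np.clip(k, 0, n - 1)[:, None]
    s0 = np.take_along_axis(s, lo, axis=1)[:, 0]
    s1 = np.take_along_axis(s, hi, axis=1)[:, 0]
    r0 = np.take_along_axis(r, lo, axis=1)[:, 0]
    r1 = np.take_along_axis(r, hi, axis=1)[:, 0]
    span = s1 - s0
    t = np.where(span > 0, (0.5 - s0) / np.where(span > 0, span, 1.0), 0.0)
    out = r0 + t * (r1 - r0)
    out = np.where(k == 0, r[:, 0], out)
    out = np.where(k == n, r[:, -1], out)
    return out


def _bootstrap_draws(bx, sx, by, sy, n_boot, rng):
    """Parametric resample of exposure/outcome betas; returns ratio and weight
    matrices of shape (n_boot, J)."""
    bxs = rng.normal(bx, sx, size=(n_boot, len(bx)))
    bys = rng.normal(by, sy, size=(n_boot, len(by)))
    ratios = bys / bxs
    weights = (bxs / sy) ** 2  # 1 / (sy/|bx*|)^2
    return ratios, weights


class WeightedMedian(_MRBase):
    """Weighted-median estimator (consistent when valid instruments carry
    more than half the weight). SE by seeded parametric bootstrap."""

    method = "weighted_median"
    _min_snp = 3

    def __init__(self, n_boot: int = 1000, seed: int = 0):
        self.n_boot = n_boot
        self.seed = seed

    def _fit_arrays(self, bx, sx, by, sy, ratio, ratio_se):
        w = 1.0 / ratio_se ** 2
        beta = float(_weighted_median_rows(ratio[None, :], w[None, :])[0])
        rng = np.random.default_rng(self.seed)
        ratios, weights = _bootstrap_draws(bx, sx, by, sy, self.n_boot, rng)
        boots = _weighted_median_rows(ratios, weights)
        return beta, float(np.std(boots, ddof=1))


def _mode_bandwidth(ratios: np.ndarray, phi: float) -> float:
    n = ratios.shape[-1]
    sd = np.std(ratios, ddof=1)
    iqr = np.subtract(*np.percentile(ratios, [75, 25]))
    spread = min(sd, iqr / 1.34)
    if spread <= 0:  # ties collapse the IQR; fall back to the sd
        spread = sd
    return phi * 0.9 * spread * n ** (-0.2)


def _kde_argmax_grid(ratios, weights, h, grid):
    """Weighted Gaussian KDE maximizer over an explicit grid (vectorized over
    leading row dimension). ratios/weights (R, J), h (R,), grid (G,)."""
    z = (grid[None, :, None] - ratios[:, None, :]) / h[:, None, None]
    dens = np.einsum("rj,rgj->rg", weights, np.exp(-0.5 * z ** 2))
    return grid[np.argmax(dens, axis=1)]


def _weighted_mode_point(ratio, w, phi, grid_size=2001, refine=True):
    h = _mode_bandwidth(ratio, phi)
    lo, hi = float(np.min(ratio)), float(np.max(ratio))
    if h <= 0 or lo == hi:
        return lo, 0.0
    grid = np.linspace(lo, hi, grid_size)
    best = float(_kde_argmax_grid(ratio[None, :], w[None, :], np.array([h]), grid)[0])
    if refine:
        step = (hi - lo) / (grid_size - 1)
        neg = lambda x: -np.sum(w * np.exp(-0.5 * ((x - ratio) / h) ** 2))
        res = optimize.minimize_scalar(
            neg, bounds=(best - step, best + step), method="bounded",
            options={"xatol": 1e-10})
        best = float(res.x)
    return best, h


class WeightedMode(_MRBase):
    """Weighted-mode estimator: the maximizer of a weighted Gaussian kernel
    density over the per-SNP ratios.

    Bandwidth = phi * 0.9 * min(sd, IQR/1.34) * J**(-1/5) on the ratios
    (Silverman-type rule). SE by seeded parametric bootstrap with a coarser
    density grid per draw.
    """

    method = "weighted_mode"
    _min_snp = 3

    def __init__(self, phi: float = 1.0, n_boot: int = 1000, seed: int = 0,
                 boot_grid: int = 256):
        self.phi = phi
        self.n_boot = n_boot
        self.seed = seed
        self.boot_grid = boot_grid

    def _fit_arrays(self, bx, sx, by, sy, ratio, ratio_se):
        w = 1.0 / ratio_se ** 2
        beta, _ = _weighted_mode_point(ratio, w, self.phi)
        rng = np.random.default_rng(self.seed)
        ratios, weights = _bootstrap_draws(bx, sx, by, sy, self.n_boot, rng)
        boots = _mode_rows(ratios, weights, self.phi, self.boot_grid)
        return beta, float(np.std(boots, ddof=1))


def _mode_rows(ratios, weights, phi, grid_size=256, chunk=200):
    """Row-wise weighted-mode point estimates on per-row grids."""
    n_rows, n = ratios.shape
    sd = np.std(ratios, axis=1, ddof=1)
    q75, q25 = np.percentile(ratios, [75, 25], axis=1)
    spread = np.minimum(sd, (q75 - q25) / 1.34)
    spread = np.where(spread > 0, spread, sd)
    h = phi * 0.9 * spread * n ** (-0.2)
    h = np.where(h > 0, h, 1.0)  # degenerate rows resolve to their min ratio
    lo = ratios.min(axis=1)
    hi = ratios.max(axis=1)
    frac = np.linspace(0.0, 1.0, grid_size)
    out = np.empty(n_rows)
    for start in range(0, n_rows, chunk):
        sl = slice(start, min(start + chunk, n_rows))
        grid = lo[sl, None] + (hi[sl] - lo[sl])[:, None] * frac[None, :]
        z = (grid[:, :, None] - ratios[sl][:, None, :]) / h[sl, None, None]
        dens = np.einsum("rj,rgj->rg", weights[sl], np.exp(-0.5 * z ** 2))
        out[sl] = np.take_along_axis(grid, np.argmax(dens, axis=1)[:, None], axis=1)[:, 0]
    return out


# ---------------------------------------------------------------------------
# function wrappers matching the operation signatures

def wald_ratio(inst: pd.DataFrame) -> MREstimate:
    """Wald ratio of the first (single) instrument row."""
    return WaldRatio().fit(inst.iloc[:1]).estimate_


def ivw(insts: pd.DataFrame, effects_model: str = "fixed") -> MREstimate:
    return IVW(effects_model=effects_model).fit(insts).estimate_


def mr_egger(insts: pd.DataFrame) -> EggerFit:
    return EggerRegression().fit(insts).egger_fit_


def weighted_median(insts: pd.DataFrame, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    return WeightedMedian(n_boot=n_boot, seed=seed).fit(insts).estimate_


def weighted_mode(insts: pd.DataFrame, phi: float = 1.0, n_boot: int = 1000,
                  seed: int = 0) -> MREstimate:
    return WeightedMode(phi=phi, n_boot=n_boot, seed=seed).fit(insts).estimate_
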