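"""MR estimators and sensitivity statistics for one harmonized pair.

All estimators consume a :class:`~mrchain.gwas_io.HarmonizedSet` whose betas
share an effect-allele convention.  Effects are on the log-odds scale for a
binary outcome (SD scale otherwise); :func:`beta_to_or` converts to the
odds-ratio reporting convention.

Estimators
----------
* IVW: precision-weighted combination of Wald ratios, i.e. weighted least
  squares of by on bx through the origin with weights 1/se_y^2.  The random
  flavor inflates SEs multiplicatively by sqrt(Q/(k-1)) when Cochran's Q
  exceeds its degrees of freedom.
* MR-Egger: the same regression with an intercept; a nonzero intercept
  signals directional horizontal pleiotropy.  Variants are oriented so
  bx >= 0 first (the estimate is invariant to joint re-orientation).
* Weighted median: consistent when instruments carrying >= 50% of the weight
  are valid; SE by parametric bootstrap.
* Weighted mode: kernel-density mode of the ratio estimates; consistent when
  the largest group of instruments shares the true ratio (ZEMPA); SE by the
  same bootstrap.
* Multivariable IVW: joint weighted regression on several exposures, used for
  direct effects in the mediation difference method.

p-values are two-sided normal throughout, the summary-data convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .errors import (CollinearityError, DataError, DegenerateInstrumentError,
                     InsufficientInstrumentsError)
from .gwas_io import HarmonizedSet

#: two-sided 95% normal quantile used for all confidence intervals
Z95 = 1.959964

METHODS = ("wald_ratio", "ivw_fixed", "ivw_random", "egger",
           "weighted_median", "weighted_mode", "mvmr_ivw")


@dataclass
class MREstimate:
    """One estimator's causal-effect estimate with OR-scale reporting."""

    method: str
    k: int
    beta: float
    se: float
    pval: float
    or_: float
    ci_low: float
    ci_high: float

    @classmethod
    def from_beta(cls, method: str, k: int, beta: float, se: float) -> "MREstimate":
        or_, lo, hi, p = beta_to_or(beta, se)
        return cls(method, k, beta, se, p, or_, lo, hi)


@dataclass
class QTest:
    """Cochran's Q heterogeneity test over per-variant ratio estimates."""

    Q: float
    df: int
    pval: float


@dataclass
class EggerIntercept:
    """MR-Egger intercept: average directional pleiotropic effect."""

    intercept: float
    se: float
    pval: float


def beta_to_or(beta: float, se: float):
    """(OR, CI low, CI high, two-sided p) from a log-scale effect and SE."""
    if se <= 0:
        raise DataError(f"se must be positive, got {se}")
    or_ = float(np.exp(beta))
    lo = float(np.exp(beta - Z95 * se))
    hi = float(np.exp(beta + Z95 * se))
    p = float(2.0 * stats.norm.sf(abs(beta) / se))
    return or_, lo, hi, max(p, np.finfo(float).tiny)


def wald_ratios(h: HarmonizedSet, second_order: bool = False):
    """Per-variant ratio estimates by/bx and their delta-method SEs.

    First-order SE is se_y/|bx| (exposure-side error ignored); with
    ``second_order`` the by^2*se_x^2/bx^4 term is added.
    """
    if np.any(h.bx == 0):
        bad = [v for v, b in zip(h.variant_ids, h.bx) if b == 0]
        raise DegenerateInstrumentError(
            f"zero exposure effect for variant(s) {bad[:5]}")
    ratio = h.by / h.bx
    var = h.se_y**2 / h.bx**2
    if second_order:
        var = var + h.by**2 * h.se_x**2 / h.bx**4
    return ratio, np.sqrt(var)


# ---------------------------------------------------------------------------
# IVW
# ---------------------------------------------------------------------------

def ivw(h: HarmonizedSet, mode: str = "random") -> tuple[MREstimate, QTest]:
    """Inverse-variance-weighted estimate with Cochran's Q.

    beta = sum(bx*by/se_y^2) / sum(bx^2/se_y^2); the fixed-effect SE is
    1/sqrt(sum(bx^2/se_y^2)).  ``random`` applies multiplicative
    overdispersion, inflating the SE by sqrt(Q/(k-1)) only when Q/(k-1) > 1.
    """
    if mode not in ("fixed", "random"):
        raise DataError(f"ivw mode must be 'fixed' or 'random', got {mode!r}")
    k = h.k
    if k == 0:
        raise DataError("ivw requires at least one variant")
    w = h.bx**2 / h.se_y**2
    beta = float(np.sum(h.bx * h.by / h.se_y**2) / np.sum(w))
    se_fixed = float(1.0 / np.sqrt(np.sum(w)))
    ratio, _ = wald_ratios(h)
    if k >= 2:
        Q = float(np.sum(w * (ratio - beta) ** 2))
        df = k - 1
        q_p = float(stats.chi2.sf(Q, df))
    else:
        Q, df, q_p = 0.0, 0, float("nan")
    se = se_fixed
    if mode == "random" and df > 0 and Q / df > 1:
        se = se_fixed * float(np.sqrt(Q / df))
    method = "ivw_fixed" if mode == "fixed" else "ivw_random"
    return MREstimate.from_beta(method, k, beta, se), QTest(Q, df, q_p)


# ---------------------------------------------------------------------------
# MR-Egger
# ---------------------------------------------------------------------------

def mr_egger(h: HarmonizedSet) -> tuple[MREstimate, EggerIntercept]:
    """MR-Egger regression: weighted fit of by on bx with an intercept.

    Variants are oriented to bx >= 0 first; SEs use multiplicative random
    effects, i.e. the model SE scaled by max(1, sqrt(RSS_w/(k-2))).
    """
    if h.k < 3:
        raise InsufficientInstrumentsError(
            f"MR-Egger requires k >= 3, got k = {h.k}")
    flip = np.where(h.bx < 0, -1.0, 1.0)
    bx, by = h.bx * flip, h.by * flip
    w = 1.0 / h.se_y**2
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=w).fit()
    sigma = float(np.sqrt(fit.scale))  # sqrt(RSS_w / (k-2))
    se = fit.bse / min(1.0, sigma)     # == base SE * max(1, sigma)
    slope = MREstimate.from_beta("egger", h.k, float(fit.params[1]),
                                 float(se[1]))
    ip = float(2.0 * stats.norm.sf(abs(fit.params[0]) / se[0]))
    intercept = EggerIntercept(float(fit.params[0]), float(se[0]), ip)
    return slope, intercept


# ---------------------------------------------------------------------------
# weighted median
# ---------------------------------------------------------------------------

def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order] / np.sum(weights)
    # cumulative midpoint of each variant's weight mass
    p = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, p, r))


def _bootstrap_se(h: HarmonizedSet, point_fn, n_boot: int, seed: int) -> float:
    """Parametric bootstrap: redraw (bx, by) from normals with the data SEs."""
    rng = np.random.default_rng(seed)
    est = np.empty(n_boot)
    for b in range(n_boot):
        bx = rng.normal(h.bx, h.se_x)
        by = rng.normal(h.by, h.se_y)
        bx = np.where(bx == 0, np.finfo(float).tiny, bx)
        ratios = by / bx
        ratio_se = h.se_y / np.abs(bx)
        est[b] = point_fn(ratios, 1.0 / ratio_se**2)
    return float(np.std(est, ddof=1))


def weighted_median(h: HarmonizedSet, n_boot: int = 1000,
                    seed: int = 0) -> MREstimate:
    """Weighted median of the Wald ratios with inverse-variance weights.

    The estimate interpolates the ratio at cumulative weight 0.5; the SE is a
    parametric bootstrap over ``n_boot`` redraws with the given seed.
    """
    if h.k < 3:
        raise InsufficientInstrumentsError(
            f"weighted median requires k >= 3, got k = {h.k}")
    if n_boot < 2:
        raise DataError("n_boot must be >= 2 for a bootstrap SE")
    ratios, ratio_se = wald_ratios(h)
    beta = _weighted_median_point(ratios, 1.0 / ratio_se**2)
    se = _bootstrap_se(h, _weighted_median_point, n_boot, seed)
    se = max(se, np.finfo(float).tiny)
    return MREstimate.from_beta("weighted_median", h.k, beta, se)


# ---------------------------------------------------------------------------
# weighted mode
# ---------------------------------------------------------------------------

_MODE_GRID = 512


def _mode_point(ratios: np.ndarray, weights: np.ndarray,
                phi: float = 1.0) -> float:
    lo, hi = float(np.min(ratios)), float(np.max(ratios))
    if lo == hi:
        return lo
    sd = float(np.std(ratios, ddof=1))
    mad = float(stats.median_abs_deviation(ratios, scale="normal"))
    s = min(sd, mad) if mad > 0 else sd
    bw = phi * 0.9 * s * len(ratios) ** (-0.2)
    if bw <= 0:
        return float(ratios[np.argmax(weights)])
    grid = np.linspace(lo, hi, _MODE_GRID)
    dens = np.sum(
        weights[:, None] * np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / bw) ** 2),
        axis=0)
    return float(grid[np.argmax(dens)])


def weighted_mode(h: HarmonizedSet, bandwidth_phi: float = 1.0,
                  n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Mode of the weighted kernel density of Wald ratios.

    Bandwidth is ``phi`` times a modified Silverman rule,
    0.9*min(sd, mad)*k^(-1/5), evaluated on a 512-point grid spanning the
    ratio range.  SE by the same parametric bootstrap as the median.
    """
    if h.k < 3:
        raise InsufficientInstrumentsError(
            f"weighted mode requires k >= 3, got k = {h.k}")
    if n_boot < 2:
        raise DataError("n_boot must be >= 2 for a bootstrap SE")
    ratios, ratio_se = wald_ratios(h)
    beta = _mode_point(ratios, 1.0 / ratio_se**2, bandwidth_phi)
    se = _bootstrap_se(
        h, lambda r, w: _mode_point(r, w, bandwidth_phi), n_boot, seed)
    se = max(se, np.finfo(float).tiny)
    return MREstimate.from_beta("weighted_mode", h.k, beta, se)


# ---------------------------------------------------------------------------
# multivariable IVW
# ---------------------------------------------------------------------------

def mvmr_ivw(bx_matrix: np.ndarray, se_x_matrix: np.ndarray,
             by: np.ndarray, se_y: np.ndarray) -> list[MREstimate]:
    """Multivariable IVW: joint weighted regression on m exposures.

    Weighted least squares of by on the exposure-effect columns without
    intercept, weights 1/se_y^2; per-exposure SEs use multiplicative random
    effects (scale max(1, sqrt(RSS_w/(k-m)))).  With m = 1 this reduces to
    univariable random-effects IVW.
    """
    bx = np.atleast_2d(np.asarray(bx_matrix, dtype=float))
    if bx.ndim != 2:
        raise DataError("bx_matrix must be 2-D (k x m)")
    by = np.asarray(by, dtype=float)
    se_y = np.asarray(se_y, dtype=float)
    k, m = bx.shape
    if m < 1 or k <= m:
        raise DataError(f"mvmr requires k > m >= 1, got k={k}, m={m}")
    if np.linalg.matrix_rank(bx) < m:
        raise CollinearityError("exposure-effect matrix is rank deficient")
    w = 1.0 / se_y**2
    fit = sm.WLS(by, bx, weights=w).fit()
    sigma = float(np.sqrt(fit.scale))  # sqrt(RSS_w / (k-m))
    se = fit.bse / min(1.0, sigma)
    return [MREstimate.from_beta("mvmr_ivw", k, float(fit.params[j]),
                                 float(se[j]))
            for j in range(m)]
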