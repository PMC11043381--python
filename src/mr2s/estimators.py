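"""Causal-effect estimators for two-sample summary-level MR.

All estimators operate on per-SNP Wald ratios theta_j = beta_out_j /
beta_exp_j with first-order standard errors se_out_j / |beta_exp_j| (the
exposure-side uncertainty is ignored, the conventional default at typical
GWAS instrument strengths; a second-order option is available).

* Wald ratio — one SNP, or the fixed-effect inverse-variance average of
  two;
* IVW — inverse-variance-weighted mean of the ratios, equivalent to
  weighted regression of beta_out on beta_exp through the origin, with a
  multiplicative random-effects standard error (inflation floored at 1);
* MR-Egger — the same regression with a free intercept; the intercept
  estimates average directional pleiotropy and inference uses a t
  distribution on n - 2 df;
* weighted median — consistent when at least half the weight comes from
  valid instruments; bootstrap standard error;
* weighted mode — the peak of a weighted Gaussian kernel density over the
  ratios; bootstrap standard error.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from scipy.stats import norm, t as t_dist

from .types import HarmonizedInstrument, MRResult, ValidationError

#: 95% two-sided normal quantile, kept at full precision for bit-level
#: reproducibility of interval bounds.
Z_95 = 1.959964

WALD_RATIO = "wald_ratio"
IVW_RE = "ivw_re"
EGGER = "egger"
WEIGHTED_MEDIAN = "weighted_median"
WEIGHTED_MODE = "weighted_mode"


def ratio_estimates(
    instruments: list[HarmonizedInstrument],
    second_order: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[HarmonizedInstrument]]:
    """Per-SNP Wald ratios, their SEs, and inverse-variance weights.

    SNPs with beta_exp exactly zero carry no instrument information and
    are dropped (returned list contains the survivors, aligned with the
    arrays).
    """
    kept = [h for h in instruments if h.beta_exp != 0.0]
    bx = np.array([h.beta_exp for h in kept])
    by = np.array([h.beta_out for h in kept])
    sx = np.array([h.se_exp for h in kept])
    sy = np.array([h.se_out for h in kept])
    theta = by / bx
    se = sy / np.abs(bx)
    if second_order:
        se = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    weight = 1.0 / se**2
    return theta, se, weight, kept


def _finish(method: str, beta_hat: float, se_hat: float, n_snps: int,
            pval: Optional[float] = None, **extra) -> MRResult:
    ci_low = beta_hat - Z_95 * se_hat
    ci_high = beta_hat + Z_95 * se_hat
    if pval is None:
        z = beta_hat / se_hat if se_hat > 0 else math.inf * np.sign(beta_hat)
        pval = 2.0 * norm.sf(abs(z)) if se_hat > 0 else 0.0
    return MRResult(
        method=method,
        beta_hat=beta_hat,
        se_hat=se_hat,
        ci_low=ci_low,
        ci_high=ci_high,
        or_point=math.exp(beta_hat),
        or_low=math.exp(ci_low),
        or_high=math.exp(ci_high),
        pval=max(min(pval, 1.0), 5e-324),
        n_snps=n_snps,
        **extra,
    )


def wald_ratio(instruments: list[HarmonizedInstrument]) -> MRResult:
    """Single-SNP Wald ratio, or the fixed-effect average of two.

    Applicable when one or two instruments survive selection; with more,
    the full method set (IVW/Egger/median/mode) is required.
    """
    if len(instruments) == 0:
        raise ValidationError("wald_ratio requires at least 1 SNP")
    if len(instruments) > 2:
        raise ValidationError("wald_ratio applies to at most 2 SNPs; use ivw_random_effects")
    theta, se, w, kept = ratio_estimates(instruments)
    if len(kept) == 0:
        raise ValidationError("all instruments have zero exposure effect")
    if len(kept) == 1:
        return _finish(WALD_RATIO, float(theta[0]), float(se[0]), 1)
    beta_hat = float(np.sum(w * theta) / np.sum(w))
    se_hat = float(1.0 / math.sqrt(np.sum(w)))
    return _finish(WALD_RATIO, beta_hat, se_hat, 2)


def ivw_random_effects(instruments: list[HarmonizedInstrument]) -> MRResult:
    """Inverse-variance-weighted estimate with multiplicative random effects.

    beta_hat is the weighted mean of the ratios; the fixed-effect standard
    error is inflated by sqrt(Q / (n - 1)) when the heterogeneity statistic
    Q exceeds its degrees of freedom (floored at no inflation).
    """
    if len(instruments) < 2:
        raise ValidationError("ivw_random_effects requires at least 2 SNPs")
    theta, se, w, kept = ratio_estimates(instruments)
    n = len(kept)
    if n < 2:
        raise ValidationError("fewer than 2 usable instruments after dropping null ones")
    sw = float(np.sum(w))
    beta_hat = float(np.sum(w * theta) / sw)
    q = float(np.sum(w * (theta - beta_hat) ** 2))
    inflation = max(1.0, math.sqrt(q / (n - 1)))
    se_hat = math.sqrt(1.0 / sw) * inflation
    return _finish(IVW_RE, beta_hat, se_hat, n)


def egger(instruments: list[HarmonizedInstrument]) -> MRResult:
    """MR-Egger: weighted regression of beta_out on beta_exp with intercept.

    Each SNP is first oriented so its exposure effect is positive (both
    betas flipped together — the effect allele is an arbitrary label, and
    the intercept is only interpretable in this orientation).  Weights are
    1/se_out^2; slope and intercept inference is ordinary weighted
    least squares with t on n - 2 df.
    """
    if len(instruments) < 3:
        raise ValidationError("egger requires at least 3 SNPs")
    bx = np.array([h.beta_exp for h in instruments])
    by = np.array([h.beta_out for h in instruments])
    sy = np.array([h.se_out for h in instruments])
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    w = 1.0 / sy**2
    n = len(bx)
    x_bar = np.sum(w * bx) / np.sum(w)
    y_bar = np.sum(w * by) / np.sum(w)
    sxx = float(np.sum(w * (bx - x_bar) ** 2))
    if sxx == 0.0:
        raise ValidationError("degenerate design: all exposure effects equal after orientation")
    sxy = float(np.sum(w * (bx - x_bar) * (by - y_bar)))
    slope = sxy / sxx
    intercept = float(y_bar - slope * x_bar)
    resid = by - intercept - slope * bx
    df = n - 2
    sigma2 = float(np.sum(w * resid**2)) / df
    se_slope = math.sqrt(sigma2 / sxx)
    se_intercept = math.sqrt(sigma2 * (1.0 / float(np.sum(w)) + x_bar**2 / sxx))
    p_slope = 2.0 * t_dist.sf(abs(slope / se_slope), df) if se_slope > 0 else 0.0
    p_intercept = (
        2.0 * t_dist.sf(abs(intercept / se_intercept), df) if se_intercept > 0 else 0.0
    )
    return _finish(
        EGGER,
        slope,
        se_slope,
        n,
        pval=p_slope,
        egger_intercept=intercept,
        egger_intercept_se=se_intercept,
        egger_intercept_p=max(min(p_intercept, 1.0), 5e-324),
    )


def _weighted_median(theta: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(theta)
    th = theta[order]
    wt = w[order]
    cum = (np.cumsum(wt) - 0.5 * wt) / np.sum(wt)
    if cum[0] >= 0.5:
        return float(th[0])
    below = int(np.max(np.where(cum < 0.5)[0]))
    if below == len(th) - 1:
        return float(th[-1])
    frac = (0.5 - cum[below]) / (cum[below + 1] - cum[below])
    return float(th[below] + (th[below + 1] - th[below]) * frac)


def weighted_median(
    instruments: list[HarmonizedInstrument],
    n_boot: int = 1000,
    seed: int = 0,
) -> MRResult:
    """Weighted median of the per-SNP ratios, bootstrap standard error.

    The point estimate interpolates the sorted ratios at cumulative weight
    one half; it is consistent whenever valid instruments carry a majority
    of the weight.  The SE is the standard deviation of the estimate over
    parametric-bootstrap replicates theta_j* ~ N(theta_j, se_j^2).
    """
    if len(instruments) < 3:
        raise ValidationError("weighted_median requires at least 3 SNPs")
    theta, se, w, kept = ratio_estimates(instruments)
    beta_hat = _weighted_median(theta, w)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        th_b = rng.normal(theta, se)
        boots[b] = _weighted_median(th_b, w)
    se_hat = float(np.std(boots, ddof=1))
    return _finish(WEIGHTED_MEDIAN, beta_hat, se_hat, len(kept))


def _silverman_bandwidth(theta: np.ndarray, factor: float) -> float:
    n = len(theta)
    sd = float(np.std(theta, ddof=1)) if n > 1 else 0.0
    mad = float(np.median(np.abs(theta - np.median(theta)))) * 1.4826
    s = 0.9 * min(sd, mad) * n ** (-1 / 5) if min(sd, mad) > 0 else 0.9 * max(sd, mad) * n ** (-1 / 5)
    return max(1e-8, s * factor)


def _weighted_mode(theta: np.ndarray, w: np.ndarray, factor: float) -> float:
    h = _silverman_bandwidth(theta, factor)
    lo, hi = theta.min() - 3 * h, theta.max() + 3 * h
    grid = np.linspace(lo, hi, 512)
    wn = w / np.sum(w)
    dens = np.sum(wn[None, :] * np.exp(-0.5 * ((grid[:, None] - theta[None, :]) / h) ** 2), axis=1)
    return float(grid[int(np.argmax(dens))])


def weighted_mode(
    instruments: list[HarmonizedInstrument],
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MRResult:
    """Mode of the weighted kernel density over the per-SNP ratios.

    Consistent when the largest cluster of instruments is valid (the
    "zero modal pleiotropy" assumption).  Bandwidth follows a modified
    Silverman rule on the ratio spread, scaled by ``bandwidth_factor``;
    the SE comes from the same parametric bootstrap as the median.
    """
    if len(instruments) < 3:
        raise ValidationError("weighted_mode requires at least 3 SNPs")
    if bandwidth_factor <= 0:
        raise ValidationError("bandwidth_factor must be positive")
    theta, se, w, kept = ratio_estimates(instruments)
    if np.ptp(theta) == 0.0:
        return _finish(WEIGHTED_MODE, float(theta[0]), float(1.0 / math.sqrt(np.sum(w))), len(kept))
    beta_hat = _weighted_mode(theta, w, bandwidth_factor)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        th_b = rng.normal(theta, se)
        boots[b] = _weighted_mode(th_b, w, bandwidth_factor)
    se_hat = float(np.std(boots, ddof=1))
    return _finish(WEIGHTED_MODE, beta_hat, se_hat, len(kept))


def to_odds_scale(beta_hat: float, se_hat: float) -> dict:
    """95% CI and odds-ratio transform of a log-odds estimate."""
    if se_hat <= 0:
        raise ValidationError("se_hat must be positive")
    ci_low = beta_hat - Z_95 * se_hat
    ci_high = beta_hat + Z_95 * se_hat
    pval = 2.0 * norm.sf(abs(beta_hat / se_hat))
    return {
        "ci_low": ci_low,
        "ci_high": ci_high,
        "or_point": math.exp(beta_hat),
        "or_low": math.exp(ci_low),
        "or_high": math.exp(ci_high),
        "pval": pval,
    }
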