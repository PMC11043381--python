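"""Heterogeneity, pleiotropy, outlier, influence, and power diagnostics.

* Cochran's Q over the per-SNP ratio estimates (chi-square, n - 1 df);
* a residual-sum-of-squares outlier test in the MR-PRESSO style: a
  simulation-based global heterogeneity p-value, per-SNP outlier p-values
  with Bonferroni adjustment, removal of flagged SNPs, and a distortion
  test comparing the estimate shift against random removals;
* the Egger intercept test for directional pleiotropy;
* leave-one-out re-estimation to flag single influential variants;
* an asymptotic power approximation for a binary outcome (the formula
  behind the mRnd-style calculators).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import chi2, norm

from .estimators import EGGER, ivw_random_effects, ratio_estimates
from .types import HarmonizedInstrument, MRResult, ValidationError


def cochran_q(instruments: list[HarmonizedInstrument]) -> tuple[float, int, float]:
    """Cochran's Q over per-SNP ratio estimates.

    Q = sum_j w_j (theta_j - theta_IVW)^2 on n - 1 degrees of freedom,
    with the usual inverse-variance weights; the p-value is the upper
    chi-square tail.
    """
    if len(instruments) < 2:
        raise ValidationError("cochran_q requires at least 2 SNPs")
    theta, _se, w, kept = ratio_estimates(instruments)
    if len(kept) < 2:
        raise ValidationError("fewer than 2 usable instruments")
    beta_ivw = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum(w * (theta - beta_ivw) ** 2))
    df = len(kept) - 1
    p = float(chi2.sf(q, df))
    return q, df, p


@dataclass
class PressoResult:
    """Output of the residual-sum-of-squares outlier test."""

    rss_obs: float
    global_p: float
    per_snp_p: dict[str, float]
    outlier_ids: list[str]
    distortion_p: Optional[float]
    beta_before: float
    beta_after: Optional[float]
    n_sim: int
    seed: int


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out weighted through-origin slopes for every SNP at once."""
    sxy = np.sum(w * bx * by)
    sxx = np.sum(w * bx * bx)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def mr_presso(
    instruments: list[HarmonizedInstrument],
    n_sim: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> PressoResult:
    """Simulation-based pleiotropy residual sum and outlier test.

    For each SNP the expected outcome effect under no pleiotropy is the
    leave-that-SNP-out through-origin slope times its exposure effect; the
    observed RSS is the weighted sum of squared departures.  ``n_sim``
    parametric simulations under the no-pleiotropy null calibrate both the
    global p-value and each SNP's outlier p-value (Bonferroni-adjusted
    across SNPs; adjusted p < ``alpha`` flags an outlier).  Monte-Carlo
    p-values use the add-one rule (1 + k) / (n_sim + 1), so they are never
    zero.  Flagged SNPs are removed, the IVW estimate recomputed, and a
    distortion p-value compares the estimate shift with the shifts from
    removing equally many random SNPs.
    """
    n = len(instruments)
    if n < 4:
        raise ValidationError("presso_insufficient_snps: need at least 4 SNPs")
    if n_sim < 100:
        raise ValidationError("n_sim must be at least 100")
    rng = np.random.default_rng(seed)
    bx = np.array([h.beta_exp for h in instruments])
    by = np.array([h.beta_out for h in instruments])
    sx = np.array([h.se_exp for h in instruments])
    sy = np.array([h.se_out for h in instruments])
    ids = [h.snp_id for h in instruments]
    w = 1.0 / sy**2

    theta_loo = _loo_slopes(bx, by, w)
    resid = by - theta_loo * bx
    wr2_obs = w * resid**2
    rss_obs = float(np.sum(wr2_obs))

    # parametric null simulations, vectorised over (n_sim, n)
    x_sim = rng.normal(bx, sx, size=(n_sim, n))
    y_sim = rng.normal(theta_loo * bx, sy, size=(n_sim, n))
    sxy = np.sum(w * x_sim * y_sim, axis=1, keepdims=True)
    sxx = np.sum(w * x_sim * x_sim, axis=1, keepdims=True)
    theta_loo_sim = (sxy - w * x_sim * y_sim) / (sxx - w * x_sim * x_sim)
    wr2_sim = w * (y_sim - theta_loo_sim * x_sim) ** 2
    rss_sim = np.sum(wr2_sim, axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    p_raw = (1 + np.sum(wr2_sim >= wr2_obs[None, :], axis=0)) / (n_sim + 1)
    p_adj = np.minimum(1.0, p_raw * n)
    per_snp_p = {ids[j]: float(p_adj[j]) for j in range(n)}
    flagged = [ids[j] for j in range(n) if p_adj[j] < alpha]
    if len(flagged) == n:
        raise ValidationError("all SNPs flagged as outliers; no valid instruments remain")

    beta_before = ivw_random_effects(instruments).beta_hat
    beta_after = None
    distortion_p = None
    if flagged:
        keep = [h for h in instruments if h.snp_id not in flagged]
        if len(keep) >= 2:
            beta_after = ivw_random_effects(keep).beta_hat
            d_obs = abs(beta_before - beta_after)
            k = len(flagged)
            n_draw = min(n_sim, 1000)
            d_sim = np.empty(n_draw)
            for b in range(n_draw):
                drop = rng.choice(n, size=k, replace=False)
                mask = np.ones(n, dtype=bool)
                mask[drop] = False
                beta_r = float(
                    np.sum(w[mask] * bx[mask] * by[mask]) / np.sum(w[mask] * bx[mask] ** 2)
                )
                d_sim[b] = abs(beta_before - beta_r)
            distortion_p = float((1 + np.sum(d_sim >= d_obs)) / (n_draw + 1))
    return PressoResult(
        rss_obs=rss_obs,
        global_p=global_p,
        per_snp_p=per_snp_p,
        outlier_ids=sorted(flagged),
        distortion_p=distortion_p,
        beta_before=beta_before,
        beta_after=beta_after,
        n_sim=n_sim,
        seed=seed,
    )


def egger_intercept_test(egger_result: MRResult) -> tuple[float, float, float, str]:
    """Directional-pleiotropy verdict from the Egger intercept.

    Returns (intercept, se, p, verdict): ``no_evidence`` iff p > 0.05,
    else ``pleiotropy_suspected`` (the boundary p = 0.05 counts as
    suspected).
    """
    if egger_result.method != EGGER:
        raise ValidationError("egger_intercept_test requires an MR-Egger result")
    p = egger_result.egger_intercept_p
    verdict = "no_evidence" if p > 0.05 else "pleiotropy_suspected"
    return (
        egger_result.egger_intercept,
        egger_result.egger_intercept_se,
        p,
        verdict,
    )


@dataclass
class LeaveOneOutTable:
    """Per-SNP-excluded IVW estimates plus the full-sample row."""

    rows: list[tuple[Optional[str], float, float, float]]  # (excluded, beta, se, p)
    influential_ids: list[str] = field(default_factory=list)


def leave_one_out(
    instruments: list[HarmonizedInstrument], alpha: float = 0.05
) -> LeaveOneOutTable:
    """IVW with each SNP excluded in turn.

    A SNP is influential when its exclusion moves the IVW p-value across
    ``alpha`` in either direction or flips the sign of the estimate —
    i.e. the full-sample conclusion hinges on that single variant.
    """
    n = len(instruments)
    if n < 3:
        raise ValidationError("leave_one_out requires at least 3 SNPs")
    full = ivw_random_effects(instruments)
    rows: list[tuple[Optional[str], float, float, float]] = [
        (None, full.beta_hat, full.se_hat, full.pval)
    ]
    influential = []
    for j in range(n):
        sub = instruments[:j] + instruments[j + 1 :]
        res = ivw_random_effects(sub)
        rows.append((instruments[j].snp_id, res.beta_hat, res.se_hat, res.pval))
        crossed = (full.pval < alpha) != (res.pval < alpha)
        flipped = full.beta_hat * res.beta_hat < 0
        if crossed or flipped:
            influential.append(instruments[j].snp_id)
    return LeaveOneOutTable(rows=rows, influential_ids=influential)


def mr_power(
    n_outcome: float,
    case_fraction: float,
    pve_total: float,
    beta_causal: float,
    alpha: float = 0.05,
) -> float:
    """Asymptotic power of the IVW test for a binary outcome.

    The noncentrality is |beta| * sqrt(N * PVE * K * (1 - K)) with K the
    case fraction and PVE the summed variance explained by the
    instruments; power is the two-tailed normal rejection probability at
    level ``alpha``.
    """
    if not (0.0 < case_fraction < 1.0):
        raise ValidationError("case_fraction must be in (0, 1)")
    if pve_total <= 0:
        raise ValidationError("pve_total must be positive")
    z_crit = norm.ppf(1.0 - alpha / 2.0)
    z = abs(beta_causal) * math.sqrt(
        n_outcome * pve_total * case_fraction * (1.0 - case_fraction)
    )
    return float(norm.cdf(z - z_crit) + norm.cdf(-z - z_crit))
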