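"""Synthetic two-sample GWAS summary statistics with known causal truth.

The generative model is the standard summary-level instrumental-variable
decomposition: SNP j has true exposure effect gamma_j and direct
(pleiotropic) outcome effect alpha_j, so its true outcome effect is
``beta_causal * gamma_j + alpha_j``.  Observed effects are the truth plus
Gaussian estimation error whose standard deviation follows the usual
allele-frequency approximation

    se = 1 / sqrt(2 * maf * (1 - maf) * N)

with an extra ``1 / sqrt(K * (1 - K))`` factor for a binary outcome with
case fraction K.  Participant overlap between the exposure and outcome
GWAS is realised as correlation (equal to the overlap rate) between the
two errors of each SNP — the ``r`` of the overlap-bias formula
``bias = beta * r / F``.

The generator also plants the nuisances a real harmonization step must
survive: palindromic (A/T, C/G) variants and outcome records written on
the opposite strand.  LD is block-diagonal with a constant within-block
r-squared, enough to exercise greedy clumping without a reference panel.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .types import (
    COMPLEMENT,
    SummaryStatRecord,
    SyntheticStudy,
    TruthParameters,
    ValidationError,
)

_NONPALINDROMIC = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "A")]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


def make_truth(
    m_snps: int,
    beta_causal: float,
    n_exp: int = 100_000,
    n_out: int = 100_000,
    gamma_mean: float = 0.06,
    gamma_sd: float = 0.02,
    alpha_mean: float = 0.0,
    alpha_sd: float = 0.0,
    inside_corr: float = 0.0,
    randomize_signs: bool = False,
    seed: int = 0,
    **kwargs,
) -> TruthParameters:
    """Draw per-SNP true effects and assemble a :class:`TruthParameters`.

    gamma_j are |N(gamma_mean, gamma_sd^2)| — effect alleles are taken as
    exposure-increasing, the usual convention, so directional pleiotropy
    (nonzero ``alpha_mean``) is directional in the analysis frame too;
    ``randomize_signs`` relaxes this.  alpha_j ~ N(alpha_mean,
    alpha_sd^2), correlated with |gamma_j| at ``inside_corr`` so a nonzero
    value violates the InSIDE condition.
    """
    rng = np.random.default_rng(seed)
    gamma = np.abs(rng.normal(gamma_mean, gamma_sd, m_snps))
    if randomize_signs:
        gamma = gamma * rng.choice([-1.0, 1.0], m_snps)
    if alpha_sd > 0:
        z = rng.standard_normal(m_snps)
        g_std = (np.abs(gamma) - np.mean(np.abs(gamma))) / (np.std(np.abs(gamma)) + 1e-12)
        alpha = alpha_mean + alpha_sd * (inside_corr * g_std + math.sqrt(max(0.0, 1 - inside_corr**2)) * z)
    else:
        alpha = np.full(m_snps, alpha_mean)
    truth = TruthParameters(
        beta_causal=beta_causal,
        m_snps=m_snps,
        gamma=list(gamma),
        alpha=list(alpha),
        n_exp=n_exp,
        n_out=n_out,
        alpha_mean=alpha_mean,
        alpha_sd=alpha_sd,
        inside_corr=inside_corr,
        seed=seed,
        **kwargs,
    )
    truth.validate()
    return truth


def generate_study(truth: TruthParameters) -> SyntheticStudy:
    """Realise one pair of exposure/outcome summary-statistic tables.

    Deterministic for a fixed ``truth.seed``.  Every exposure SNP gets a
    same-ID outcome record; strand-flipped outcome records are re-labelled
    on the complementary strand (the association itself is unchanged, so a
    correct harmonization step must recover identical estimates).
    """
    truth.validate()
    if truth.m_snps == 0:
        raise ValidationError("m_snps must be positive")
    m = truth.m_snps
    rng = np.random.default_rng(truth.seed)
    gamma = np.asarray(truth.gamma)
    alpha = np.asarray(truth.alpha)

    lo, hi = truth.maf_range
    maf = rng.uniform(lo, hi, m)
    n_pal = int(round(truth.frac_palindromic * m))
    pal_idx = rng.choice(m, size=n_pal, replace=False)
    is_pal = np.zeros(m, dtype=bool)
    is_pal[pal_idx] = True
    if not truth.ambiguous_palindromes:
        # keep palindromic frequencies resolvable by eaf concordance
        maf[is_pal] = np.clip(maf[is_pal], None, 0.35)
        maf[is_pal] = np.maximum(maf[is_pal], max(lo, 0.05))
    else:
        maf[is_pal] = 0.5

    se_x = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * truth.n_exp)
    se_y = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * truth.n_out)
    if truth.outcome_binary:
        k = truth.case_fraction
        se_y = se_y / math.sqrt(k * (1.0 - k))

    r = truth.overlap_rate
    e_x = rng.standard_normal(m)
    e_shared = rng.standard_normal(m)
    e_y = r * e_x + math.sqrt(max(0.0, 1.0 - r * r)) * e_shared

    beta_x = gamma + se_x * e_x
    beta_y = truth.beta_causal * gamma + alpha + se_y * e_y
    p_x = 2.0 * norm.sf(np.abs(beta_x) / se_x)
    p_y = 2.0 * norm.sf(np.abs(beta_y) / se_y)

    # genomic layout: LD blocks first (adjacent SNPs, one block per run),
    # remaining SNPs spaced far apart so clumping never links them.
    chrom = np.empty(m, dtype=object)
    pos = np.empty(m, dtype=np.int64)
    block_of = np.full(m, -1, dtype=int)
    i = 0
    for b, (size, _r2) in enumerate(truth.ld_blocks):
        for j in range(size):
            if i >= m:
                break
            chrom[i] = str(1 + b % 22)
            pos[i] = 1_000_000 + (b // 22) * 200_000_000 + j * 5_000
            block_of[i] = b
            i += 1
    while i < m:
        chrom[i] = str(1 + i % 22)
        pos[i] = 50_000_000 + (i // 22) * 30_000_000
        i += 1

    # allele assignment
    alleles = []
    for j in range(m):
        if is_pal[j]:
            alleles.append(_PALINDROMIC[int(rng.integers(len(_PALINDROMIC)))])
        else:
            alleles.append(_NONPALINDROMIC[int(rng.integers(len(_NONPALINDROMIC)))])
    eaf = np.where(rng.random(m) < 0.5, maf, 1.0 - maf)
    if truth.ambiguous_palindromes:
        eaf[is_pal] = 0.5

    n_flip = int(round(truth.frac_strand_flipped * m))
    flip_idx = set(rng.choice(m, size=n_flip, replace=False).tolist())

    exposure_records = []
    outcome_records = []
    for j in range(m):
        ea, oa = alleles[j]
        # seed-scoped IDs so independent synthetic studies never collide
        snp = f"rs{truth.seed % 10_000}{j + 1:04d}"
        exposure_records.append(
            SummaryStatRecord(
                snp_id=snp,
                chrom=str(chrom[j]),
                pos=int(pos[j]),
                effect_allele=ea,
                other_allele=oa,
                eaf=float(eaf[j]),
                beta=float(beta_x[j]),
                se=float(se_x[j]),
                pval=float(max(p_x[j], 5e-324)),
                n=float(truth.n_exp),
            )
        )
        oea, ooa = ea, oa
        if j in flip_idx:
            oea, ooa = COMPLEMENT[ea], COMPLEMENT[oa]
        outcome_records.append(
            SummaryStatRecord(
                snp_id=snp,
                chrom=str(chrom[j]),
                pos=int(pos[j]),
                effect_allele=oea,
                other_allele=ooa,
                eaf=float(eaf[j]),
                beta=float(beta_y[j]),
                se=float(se_y[j]),
                pval=float(max(p_y[j], 5e-324)),
                n=float(truth.n_out),
            )
        )

    ids = [r.snp_id for r in exposure_records]
    ld = np.eye(m)
    for b, (_size, r2) in enumerate(truth.ld_blocks):
        members = np.where(block_of == b)[0]
        for a in members:
            for c in members:
                if a != c:
                    ld[a, c] = r2
    ld_df = pd.DataFrame(ld, index=ids, columns=ids)

    return SyntheticStudy(
        exposure_records=exposure_records,
        outcome_records=outcome_records,
        ld_matrix=ld_df,
        truth=truth,
    )


def plant_outliers(study: SyntheticStudy, k: int, shift: float, seed: int | None = None) -> SyntheticStudy:
    """Add ``shift`` to the outcome beta of k randomly chosen SNPs.

    The chosen IDs are recorded in the returned study's truth so tests can
    check that outlier detection recovers exactly them.  ``k = 0`` returns
    an identical copy.
    """
    m = study.truth.m_snps
    if k >= m:
        raise ValidationError("k must be smaller than the number of SNPs")
    new = copy.deepcopy(study)
    if k == 0:
        return new
    rng = np.random.default_rng(study.truth.seed + 7_919 if seed is None else seed)
    idx = rng.choice(m, size=k, replace=False)
    ids = []
    for j in idx:
        rec = new.outcome_records[j]
        new.outcome_records[j] = replace(rec, beta=rec.beta + shift)
        ids.append(rec.snp_id)
    new.truth.planted_outlier_ids = sorted(ids)
    return new


def plant_dominant_instrument(
    study: SyntheticStudy,
    weight_share: float,
    outcome_shift: float = 0.0,
    seed: int | None = None,
) -> SyntheticStudy:
    """Rescale one SNP so it carries at least ``weight_share`` of IVW weight.

    Emulates a single variant of outsized effect and precision (the
    ALDH2-locus phenomenon in East Asian alcohol GWAS): one SNP's exposure
    beta is inflated until its inverse-variance weight dominates.  An
    optional ``outcome_shift`` adds a direct outcome effect to the same
    SNP, making it the sole driver of an otherwise null signal.  The SNP's
    ID is recorded in the truth record.
    """
    if not (0.0 < weight_share < 1.0):
        raise ValidationError("weight_share must be in (0, 1)")
    new = copy.deepcopy(study)
    rng = np.random.default_rng(study.truth.seed + 104_729 if seed is None else seed)
    j = int(rng.integers(study.truth.m_snps))
    exp = new.exposure_records[j]
    out = new.outcome_records[j]
    w = np.array(
        [e.beta**2 / o.se**2 for e, o in zip(new.exposure_records, new.outcome_records)]
    )
    w_others = float(w.sum() - w[j])
    # nudge above the requested share so the bound survives float rounding
    target_w = weight_share / (1.0 - weight_share) * w_others * (1.0 + 1e-9)
    scale = math.sqrt(max(target_w, w[j]) / w[j]) if w[j] > 0 else 1.0
    new.exposure_records[j] = replace(exp, beta=exp.beta * scale)
    if outcome_shift:
        new.outcome_records[j] = replace(out, beta=out.beta + outcome_shift)
    new.truth.dominant_id = exp.snp_id
    return new


def write_truth(truth: TruthParameters, path) -> None:
    """Serialise the ground truth as JSON for test harnesses."""
    payload = {
        "beta_causal": truth.beta_causal,
        "m_snps": truth.m_snps,
        "gamma": list(map(float, truth.gamma)),
        "alpha": list(map(float, truth.alpha)),
        "n_exp": truth.n_exp,
        "n_out": truth.n_out,
        "overlap_rate": truth.overlap_rate,
        "seed": truth.seed,
        "planted_outlier_ids": truth.planted_outlier_ids,
        "dominant_id": truth.dominant_id,
    }
    Path(path).write_text(json.dumps(payload, indent=2))
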