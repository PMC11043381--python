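"""Instrument selection and strength grading.

The selection cascade is: genome-wide significance (P < 5e-8), minor
allele frequency (MAF >= 0.01), greedy LD clumping (r^2 < 0.001 within a
±10,000 kb window), and instrument strength (F > 10).  Strength is graded
by the proportion of exposure variance a SNP explains,

    PVE = 2 * MAF * (1 - MAF) * beta^2
    F   = PVE * (N - 2) / (1 - PVE)

falling back to ``F = beta^2 / se^2`` when the allele frequency is not
reported.  All comparisons are strict in the direction stated above;
boundary behaviour is pinned by tests.
"""

from __future__ import annotations

from typing import Optional

import pandas as pd

from .audit import AuditLog
from .types import InstrumentRecord, SummaryStatRecord, ValidationError

P_THRESHOLD_DEFAULT = 5e-8
MAF_MIN_DEFAULT = 0.01
CLUMP_R2_DEFAULT = 0.001
CLUMP_KB_DEFAULT = 10_000
F_MIN_DEFAULT = 10.0


def select_significant(
    records: list[SummaryStatRecord],
    p_threshold: float = P_THRESHOLD_DEFAULT,
    audit: Optional[AuditLog] = None,
) -> list[SummaryStatRecord]:
    """Keep records with pval strictly below the genome-wide threshold."""
    if not (0.0 < p_threshold <= 1.0):
        raise ValidationError("p_threshold must be in (0, 1]")
    kept = []
    for r in records:
        if r.pval < p_threshold:
            kept.append(r)
        elif audit is not None:
            audit.record(r.snp_id, "select_significant", "drop", "not_genome_wide_significant")
    return kept


def filter_maf(
    records: list[SummaryStatRecord],
    maf_min: float = MAF_MIN_DEFAULT,
    audit: Optional[AuditLog] = None,
) -> list[SummaryStatRecord]:
    """Drop rare variants (MAF < maf_min); keep records with unknown eaf.

    A missing frequency cannot be evaluated, so those SNPs pass with a
    logged note and take the beta/se F-statistic path downstream.
    """
    kept = []
    for r in records:
        if r.maf is None:
            if audit is not None:
                audit.record(r.snp_id, "filter_maf", "warn", "maf_unknown")
            kept.append(r)
        elif r.maf >= maf_min:
            kept.append(r)
        elif audit is not None:
            audit.record(r.snp_id, "filter_maf", "drop", "rare_variant")
    return kept


def ld_clump(
    records: list[SummaryStatRecord],
    ld: pd.DataFrame,
    r2_max: float = CLUMP_R2_DEFAULT,
    window_kb: float = CLUMP_KB_DEFAULT,
    audit: Optional[AuditLog] = None,
) -> list[SummaryStatRecord]:
    """Greedy LD clumping: lowest p first, prune linked neighbours.

    Repeatedly keep the remaining SNP with the smallest p-value (ties
    broken by chromosome then position), then discard every remaining SNP
    on the same chromosome within ``window_kb`` whose r^2 with the index
    SNP is >= ``r2_max``.  The kept set is therefore pairwise either below
    the r^2 threshold or beyond the window.

    ``ld`` must cover every same-chromosome pair within the window;
    a missing pair is a hard error naming it.
    """
    window_bp = window_kb * 1_000
    order = sorted(records, key=lambda r: (r.pval, r.chrom, r.pos))
    alive = {r.snp_id for r in records}
    kept: list[SummaryStatRecord] = []
    by_id = {r.snp_id: r for r in records}
    for idx_rec in order:
        if idx_rec.snp_id not in alive:
            continue
        kept.append(idx_rec)
        alive.discard(idx_rec.snp_id)
        for other_id in list(alive):
            other = by_id[other_id]
            if other.chrom != idx_rec.chrom:
                continue
            if abs(other.pos - idx_rec.pos) > window_bp:
                continue
            try:
                r2 = float(ld.loc[idx_rec.snp_id, other_id])
            except KeyError:
                raise ValidationError(
                    f"LD matrix lacks pair ({idx_rec.snp_id}, {other_id}) "
                    f"on chromosome {idx_rec.chrom} within the clumping window"
                ) from None
            if r2 >= r2_max:
                alive.discard(other_id)
                if audit is not None:
                    audit.record(
                        other_id, "ld_clump", "drop", f"clumped_with:{idx_rec.snp_id}"
                    )
    # restore the input order of kept SNPs
    kept_ids = {r.snp_id for r in kept}
    return [r for r in records if r.snp_id in kept_ids]


def compute_pve(eaf: Optional[float], beta: float) -> Optional[float]:
    """Proportion of variance explained: 2 * MAF * (1 - MAF) * beta^2.

    Returns None when eaf is missing, signalling the beta/se fallback.
    """
    if eaf is None:
        return None
    maf = min(eaf, 1.0 - eaf)
    return 2.0 * maf * (1.0 - maf) * beta * beta


def f_statistic(
    pve: Optional[float], n: float, beta: float, se: float
) -> tuple[float, str]:
    """Instrument strength F with the formula actually applicable.

    With a known PVE: ``F = PVE * (N - 2) / (1 - PVE)``; without one
    (frequency unreported): ``F = beta^2 / se^2``.
    """
    if se <= 0:
        raise ValidationError("se must be positive")
    if pve is not None:
        if n <= 2:
            raise ValidationError("PVE-based F-statistic requires n > 2")
        return pve * (n - 2.0) / (1.0 - pve), "from_pve"
    return (beta / se) ** 2, "from_beta_se"


def grade_instruments(records: list[SummaryStatRecord]) -> list[InstrumentRecord]:
    """Attach PVE and F to each record."""
    out = []
    for r in records:
        pve = compute_pve(r.eaf, r.beta)
        f, method = f_statistic(pve, r.n, r.beta, r.se)
        out.append(InstrumentRecord(base=r, pve=pve, f_stat=f, f_method=method))
    return out


def filter_weak(
    instruments: list[InstrumentRecord],
    f_min: float = F_MIN_DEFAULT,
    audit: Optional[AuditLog] = None,
) -> list[InstrumentRecord]:
    """Keep instruments with F strictly greater than f_min."""
    kept = []
    for inst in instruments:
        if inst.f_stat > f_min:
            kept.append(inst)
        elif audit is not None:
            audit.record(inst.base.snp_id, "filter_weak", "drop", "weak_instrument")
    return kept


def overlap_bias(beta_mr: float, overlap_rate: float, f_mean: float) -> float:
    """Bias from participant overlap: beta * r / F.

    ``overlap_rate`` is the fraction of participants shared between the
    exposure and outcome GWAS; ``f_mean`` the mean F across instruments.
    """
    if f_mean <= 0:
        raise ValidationError("mean F must be positive")
    if not (0.0 <= overlap_rate <= 1.0):
        raise ValidationError("overlap_rate must be in [0, 1]")
    return beta_mr * overlap_rate / f_mean


def exclude_snps(
    instruments: list[InstrumentRecord],
    exclusion_list: dict[str, str],
    audit: Optional[AuditLog] = None,
) -> list[InstrumentRecord]:
    """Remove explicitly listed SNPs (e.g. confounder-associated variants).

    ``exclusion_list`` maps SNP IDs to a human-readable reason (a local
    stand-in for an online confounder-lookup service).  IDs not present in
    the instrument set are logged as no-ops.
    """
    present = {i.base.snp_id for i in instruments}
    for snp_id, reason in exclusion_list.items():
        if audit is not None:
            if snp_id in present:
                audit.record(snp_id, "exclude_snps", "drop", reason or "user_excluded")
            else:
                audit.record(snp_id, "exclude_snps", "note", "not_found")
    return [i for i in instruments if i.base.snp_id not in exclusion_list]
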