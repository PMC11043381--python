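"""Aligning exposure and outcome effects onto a common effect allele.

Each exposure instrument is matched to the same-ID outcome record and the
outcome association is rewritten in the exposure's orientation:

* identical allele pair — nothing to do;
* swapped alleles — the outcome beta changes sign and its frequency is
  mirrored;
* complementary-strand pair (non-palindromic) — relabel via A<->T / C<->G,
  then treat as identical or swapped;
* palindromic pair (A/T or C/G) — the strand is unknowable from alleles,
  so orientation is inferred from allele-frequency concordance: both
  frequencies must lie on the same side of 0.5 and be at least
  ``palindromic_eaf_limit`` away from it, otherwise the SNP is dropped as
  ambiguous.

Effect sizes are never rescaled — only signs and labels change.
"""

from __future__ import annotations

from typing import Optional

from .audit import AuditLog
from .types import (
    COMPLEMENT,
    HarmonizedInstrument,
    SummaryStatRecord,
    ValidationError,
)

PALINDROMIC_EAF_LIMIT_DEFAULT = 0.08


def _build(exposure: SummaryStatRecord, outcome: SummaryStatRecord,
           beta_out: float, eaf_out: Optional[float], action: str) -> HarmonizedInstrument:
    h = HarmonizedInstrument(
        snp_id=exposure.snp_id,
        effect_allele=exposure.effect_allele,
        other_allele=exposure.other_allele,
        beta_exp=exposure.beta,
        se_exp=exposure.se,
        beta_out=beta_out,
        se_out=outcome.se,
        eaf_exp=exposure.eaf,
        eaf_out=eaf_out,
        action=action,
        palindromic=exposure.is_palindromic,
    )
    h.validate()
    return h


def harmonize_pair(
    exposure: SummaryStatRecord,
    outcome: SummaryStatRecord,
    palindromic_eaf_limit: float = PALINDROMIC_EAF_LIMIT_DEFAULT,
    audit: Optional[AuditLog] = None,
) -> Optional[HarmonizedInstrument]:
    """Harmonize one SNP; returns None when the SNP must be dropped.

    Drop reasons (logged to the audit trail): ``palindromic_ambiguous``
    when frequency cannot resolve an A/T or C/G variant, and
    ``allele_mismatch`` when the two allele pairs are irreconcilable.
    """
    if exposure.snp_id != outcome.snp_id:
        raise ValidationError(
            f"cannot harmonize different SNPs ({exposure.snp_id} vs {outcome.snp_id})"
        )
    ea, oa = exposure.effect_allele, exposure.other_allele
    oea, ooa = outcome.effect_allele, outcome.other_allele

    if exposure.is_palindromic:
        if (oea, ooa) not in ((ea, oa), (oa, ea)):
            return _drop(exposure, "allele_mismatch", audit)
        return _resolve_palindromic(exposure, outcome, palindromic_eaf_limit, audit)

    if (oea, ooa) == (ea, oa):
        return _log_keep(_build(exposure, outcome, outcome.beta, outcome.eaf, "none"), audit)
    if (oea, ooa) == (oa, ea):
        eaf_out = None if outcome.eaf is None else 1.0 - outcome.eaf
        return _log_keep(_build(exposure, outcome, -outcome.beta, eaf_out, "swap"), audit)

    cea, coa = COMPLEMENT[oea], COMPLEMENT[ooa]
    if (cea, coa) == (ea, oa):
        return _log_keep(
            _build(exposure, outcome, outcome.beta, outcome.eaf, "strand_flip"), audit
        )
    if (cea, coa) == (oa, ea):
        eaf_out = None if outcome.eaf is None else 1.0 - outcome.eaf
        return _log_keep(
            _build(exposure, outcome, -outcome.beta, eaf_out, "strand_flip_swap"), audit
        )
    return _drop(exposure, "allele_mismatch", audit)


def _resolve_palindromic(
    exposure: SummaryStatRecord,
    outcome: SummaryStatRecord,
    limit: float,
    audit: Optional[AuditLog],
) -> Optional[HarmonizedInstrument]:
    # same or swapped labels are indistinguishable from a strand flip for
    # palindromic alleles; only allele frequency carries orientation.
    if exposure.eaf is None or outcome.eaf is None:
        return _drop(exposure, "palindromic_ambiguous", audit)
    d_exp = exposure.eaf - 0.5
    swapped = (outcome.effect_allele, outcome.other_allele) == (
        exposure.other_allele,
        exposure.effect_allele,
    )
    # express the outcome frequency on the exposure's effect-allele label
    eaf_out_label = 1.0 - outcome.eaf if swapped else outcome.eaf
    d_out = eaf_out_label - 0.5
    if abs(d_exp) < limit or abs(d_out) < limit:
        return _drop(exposure, "palindromic_ambiguous", audit)
    if d_exp * d_out > 0:
        # frequencies agree: the labelled allele is the same physical allele
        beta_out = -outcome.beta if swapped else outcome.beta
        action = "swap" if swapped else "none"
        eaf_out = eaf_out_label
    else:
        # frequencies disagree: the outcome is on the opposite strand, so
        # the label actually refers to the complementary (other) allele
        beta_out = outcome.beta if swapped else -outcome.beta
        action = "strand_flip" if swapped else "strand_flip_swap"
        eaf_out = 1.0 - eaf_out_label
    return _log_keep(_build(exposure, outcome, beta_out, eaf_out, action), audit)


def _drop(exposure: SummaryStatRecord, reason: str, audit: Optional[AuditLog]):
    if audit is not None:
        audit.record(exposure.snp_id, "harmonize", "drop", reason)
    return None


def _log_keep(h: HarmonizedInstrument, audit: Optional[AuditLog]) -> HarmonizedInstrument:
    if audit is not None:
        audit.record(h.snp_id, "harmonize", "keep", h.action)
    return h


def harmonize_all(
    exposure_set: list[SummaryStatRecord],
    outcome_records: list[SummaryStatRecord],
    palindromic_eaf_limit: float = PALINDROMIC_EAF_LIMIT_DEFAULT,
    audit: Optional[AuditLog] = None,
) -> list[HarmonizedInstrument]:
    """Harmonize every exposure instrument against the outcome table.

    Exposure SNPs with no same-ID outcome record are dropped with reason
    ``missing_in_outcome``.  Duplicate IDs within either input are a hard
    error — a summary-statistic table is keyed by SNP.
    """
    exp_ids = [r.snp_id for r in exposure_set]
    if len(set(exp_ids)) != len(exp_ids):
        raise ValidationError("duplicate snp_id in exposure set")
    out_ids = [r.snp_id for r in outcome_records]
    if len(set(out_ids)) != len(out_ids):
        raise ValidationError("duplicate snp_id in outcome records")
    outcome_by_id = {r.snp_id: r for r in outcome_records}
    harmonized = []
    for exp in exposure_set:
        out = outcome_by_id.get(exp.snp_id)
        if out is None:
            _drop(exp, "missing_in_outcome", audit)
            continue
        h = harmonize_pair(exp, out, palindromic_eaf_limit, audit)
        if h is not None:
            harmonized.append(h)
    return harmonized


def harmonization_report(audit: AuditLog):
    """Harmonization rows of the audit trail as a DataFrame."""
    df = audit.to_frame()
    df = df[df["stage"] == "harmonize"].copy()
    df["dropped"] = df["action"] == "drop"
    return df[["snp_id", "action", "dropped", "reason"]]
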