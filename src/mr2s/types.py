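"""Core record types shared across the pipeline.

The unit of data is one SNP's association with one trait
(:class:`SummaryStatRecord`).  After instrument selection each SNP carries
strength metadata (:class:`InstrumentRecord`); after allele alignment the
exposure and outcome associations live side by side in a
:class:`HarmonizedInstrument`, which is what every causal estimator
consumes.  Estimator output is an :class:`MRResult`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

VALID_BASES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
#: A/T and C/G pairs look identical on both strands, so strand cannot be
#: inferred from the alleles alone.
PALINDROMIC_PAIRS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})


class ValidationError(ValueError):
    """A record or file violates a hard invariant."""


@dataclass(frozen=True)
class SummaryStatRecord:
    """One SNP-trait association from a GWAS summary-statistic table.

    ``beta`` is the per-allele effect of ``effect_allele``: SD units for a
    quantitative trait, log-odds for a binary trait.  ``eaf`` (effect-allele
    frequency) may be missing (``None``); downstream code then falls back to
    the beta/se form of the F-statistic and drops palindromic SNPs during
    harmonization.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: Optional[float]
    beta: float
    se: float
    pval: float
    n: float

    def validate(self) -> None:
        if self.effect_allele not in VALID_BASES or self.other_allele not in VALID_BASES:
            raise ValidationError(
                f"{self.snp_id}: alleles must be single bases A/C/G/T, "
                f"got {self.effect_allele}/{self.other_allele}"
            )
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.snp_id}: degenerate alleles")
        if not (self.se > 0):
            raise ValidationError(f"{self.snp_id}: nonpositive se")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValidationError(f"{self.snp_id}: eaf outside [0,1]")
        if not (0.0 < self.pval <= 1.0):
            raise ValidationError(f"{self.snp_id}: pval outside (0,1]")
        if not (self.n > 0):
            raise ValidationError(f"{self.snp_id}: nonpositive n")

    @property
    def maf(self) -> Optional[float]:
        if self.eaf is None:
            return None
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def is_palindromic(self) -> bool:
        return (self.effect_allele, self.other_allele) in PALINDROMIC_PAIRS

    def pval_consistent(self, rtol: float = 0.5) -> bool:
        """Check p against the two-sided normal implied by beta/se.

        Published GWAS round p-values aggressively, so this is advisory
        (warn-only): it flags gross mismatches, not rounding.
        """
        from scipy.stats import norm

        implied = 2.0 * norm.sf(abs(self.beta) / self.se)
        if implied == 0.0:
            return self.pval < 1e-300 or self.pval < rtol
        return abs(math.log(max(self.pval, 1e-300)) - math.log(implied)) <= abs(
            math.log(implied)
        ) * rtol + math.log(10.0)


@dataclass(frozen=True)
class StudyMeta:
    """Trait-level metadata for one GWAS."""

    trait_name: str
    trait_type: str  # "quantitative" | "binary"
    n_total: int
    n_cases: Optional[int] = None
    n_controls: Optional[int] = None
    source_label: str = ""

    def validate(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise ValidationError(
                f"{self.trait_name}: trait_type must be quantitative or binary"
            )
        if self.n_total < 2:
            raise ValidationError(f"{self.trait_name}: n_total must be >= 2")
        if self.trait_type == "binary":
            if self.n_cases is None or self.n_controls is None:
                raise ValidationError(
                    f"{self.trait_name}: binary trait needs n_cases and n_controls"
                )
            if self.n_cases + self.n_controls != self.n_total:
                raise ValidationError(
                    f"{self.trait_name}: n_cases + n_controls != n_total"
                )

    @property
    def case_fraction(self) -> Optional[float]:
        if self.trait_type == "binary" and self.n_cases is not None:
            return self.n_cases / self.n_total
        return None


@dataclass
class StudyManifest:
    """Exposure and outcome studies plus the pair grid to analyse."""

    exposures: list[tuple[StudyMeta, str]]
    outcomes: list[tuple[StudyMeta, str]]
    pairs: list[tuple[str, str]]
    n_exposure_traits: int

    def validate(self) -> None:
        if self.n_exposure_traits < 1:
            raise ValidationError("n_exposure_traits must be >= 1")


@dataclass(frozen=True)
class InstrumentRecord:
    """A selected instrument with its strength grade.

    ``f_method`` records which F-statistic formula applied: ``from_pve``
    when the allele frequency (hence PVE) was available, ``from_beta_se``
    otherwise.
    """

    base: SummaryStatRecord
    pve: Optional[float]
    f_stat: float
    f_method: str  # "from_pve" | "from_beta_se"
    clump_kept: bool = True
    drop_reason: Optional[str] = None


@dataclass(frozen=True)
class HarmonizedInstrument:
    """Exposure and outcome effects aligned to one effect allele.

    Orientation is the exposure file's; ``action`` records what was done to
    the outcome record to reach it.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: Optional[float]
    eaf_out: Optional[float]
    action: str  # none | swap | strand_flip | strand_flip_swap
    palindromic: bool

    def validate(self) -> None:
        if not (self.se_exp > 0 and self.se_out > 0):
            raise ValidationError(f"{self.snp_id}: nonpositive se after harmonization")


@dataclass(frozen=True)
class MRResult:
    """A causal estimate on the log-odds (or SD-outcome) scale.

    ``or_point`` and its bounds are the exponentiated estimate: the odds
    ratio per SD of a quantitative exposure, or per log-odds unit of a
    binary exposure.
    """

    method: str
    beta_hat: float
    se_hat: float
    ci_low: float
    ci_high: float
    or_point: float
    or_low: float
    or_high: float
    pval: float
    n_snps: int
    egger_intercept: Optional[float] = None
    egger_intercept_se: Optional[float] = None
    egger_intercept_p: Optional[float] = None


@dataclass
class TruthParameters:
    """Ground truth for the synthetic generator.

    gamma are the true per-SNP exposure effects, alpha the direct
    (pleiotropic) outcome effects; the true outcome effect of SNP j is
    ``beta_causal * gamma[j] + alpha[j]``.  ``inside_corr`` correlates gamma
    and alpha, violating the InSIDE condition when nonzero.
    ``overlap_rate`` is the fraction of participants shared between the two
    GWAS, realised as correlation between the two estimation errors.
    """

    beta_causal: float
    m_snps: int
    gamma: "list[float]"
    alpha: "list[float]"
    n_exp: int
    n_out: int
    alpha_mean: float = 0.0
    alpha_sd: float = 0.0
    inside_corr: float = 0.0
    overlap_rate: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    frac_palindromic: float = 0.0
    frac_strand_flipped: float = 0.0
    ld_blocks: list[tuple[int, float]] = field(default_factory=list)
    outcome_binary: bool = True
    case_fraction: float = 0.1
    ambiguous_palindromes: bool = False
    seed: int = 0
    # filled in by plant_* operations
    planted_outlier_ids: list[str] = field(default_factory=list)
    dominant_id: Optional[str] = None

    def validate(self) -> None:
        if self.m_snps < 1:
            raise ValidationError("m_snps must be >= 1")
        if len(self.gamma) != self.m_snps or len(self.alpha) != self.m_snps:
            raise ValidationError("gamma and alpha must have length m_snps")
        for name in ("overlap_rate", "frac_palindromic", "frac_strand_flipped"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0,1]")
        lo, hi = self.maf_range
        if not (0.01 <= lo <= hi <= 0.5):
            raise ValidationError("maf_range must lie within [0.01, 0.5]")


@dataclass
class SyntheticStudy:
    """A paired exposure/outcome dataset with known truth."""

    exposure_records: list[SummaryStatRecord]
    outcome_records: list[SummaryStatRecord]
    ld_matrix: "object"  # pandas DataFrame, SNP IDs as index/columns
    truth: TruthParameters


def flip_record(rec: SummaryStatRecord) -> SummaryStatRecord:
    """Rewrite a record with alleles exchanged, beta negated, eaf mirrored.

    This is a pure re-labelling: the association it describes is unchanged,
    which is the basis of the orientation-invariance property of
    harmonization.
    """
    return replace(
        rec,
        effect_allele=rec.other_allele,
        other_allele=rec.effect_allele,
        beta=-rec.beta,
        eaf=None if rec.eaf is None else 1.0 - rec.eaf,
    )


def complement_record(rec: SummaryStatRecord) -> SummaryStatRecord:
    """Rewrite a record on the opposite strand (A<->T, C<->G)."""
    return replace(
        rec,
        effect_allele=COMPLEMENT[rec.effect_allele],
        other_allele=COMPLEMENT[rec.other_allele],
    )
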