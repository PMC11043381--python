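"""Reference metadata for the six digestive-system cancer outcome GWAS.

Case/control counts and IEU OpenGWAS identifiers of the Biobank Japan
digestive-system cancer GWAS commonly used as outcomes in East Asian
two-sample MR.  These are study-level metadata only — no summary
statistics are bundled; users supply their own downloaded tables.
"""

from __future__ import annotations

from .types import StudyMeta

DSC_OUTCOMES: dict[str, StudyMeta] = {
    "esophageal_cancer": StudyMeta(
        "esophageal_cancer", "binary", 197_045, 1_300, 195_745, "bbj-a-117"
    ),
    "gastric_cancer": StudyMeta(
        "gastric_cancer", "binary", 202_308, 6_563, 195_745, "bbj-a-119"
    ),
    "colorectal_cancer": StudyMeta(
        "colorectal_cancer", "binary", 202_807, 7_062, 195_745, "bbj-a-107"
    ),
    "hepatocellular_carcinoma": StudyMeta(
        "hepatocellular_carcinoma", "binary", 197_611, 1_866, 195_745, "bbj-a-158"
    ),
    "biliary_tract_cancer": StudyMeta(
        "biliary_tract_cancer", "binary", 196_084, 339, 195_745, "bbj-a-92"
    ),
    "pancreatic_cancer": StudyMeta(
        "pancreatic_cancer", "binary", 196_187, 442, 195_745, "bbj-a-140"
    ),
}

#: Number of exposure traits in the canonical risk-factor screen, the
#: denominator of the Bonferroni correction.
N_EXPOSURE_TRAITS = 19


def total_cases() -> int:
    """Summed case count across the six outcome GWAS."""
    return sum(m.n_cases for m in DSC_OUTCOMES.values())
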