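"""A small exposure-by-outcome study grid with Bonferroni classification.

Builds a 2-exposure x 2-outcome manifest from synthetic studies (one pair
carries a real effect, the rest are null), runs every pair, and prints
the classification grid.  In a full risk-factor screen the Bonferroni
denominator is the number of exposure traits, e.g. 0.05/19 = 2.63e-3.
"""

import tempfile
from pathlib import Path

import yaml

from mr2s import (
    MRConfig,
    generate_study,
    load_manifest,
    make_truth,
    run_study,
    summary_grid,
    write_ld_matrix,
    write_sumstats,
)

tmp = Path(tempfile.mkdtemp())
cfg = {"exposures": [], "outcomes": []}
studies = {
    "adiposity": generate_study(make_truth(m_snps=40, beta_causal=0.35, seed=1)),
    "urate": generate_study(make_truth(m_snps=40, beta_causal=0.0, seed=2)),
}
for name, study in studies.items():
    write_sumstats(study.exposure_records, tmp / f"{name}.tsv")
    write_ld_matrix(study.ld_matrix, tmp / f"{name}.ld.tsv")
    cfg["exposures"].append(
        {"name": name, "type": "quantitative", "n_total": 100_000, "file": f"{name}.tsv"}
    )
for out_name, src in [("cancer_a", "adiposity"), ("cancer_b", "urate")]:
    write_sumstats(studies[src].outcome_records, tmp / f"{out_name}.tsv")
    cfg["outcomes"].append(
        {"name": out_name, "type": "binary", "n_total": 100_000,
         "n_cases": 10_000, "n_controls": 90_000, "file": f"{out_name}.tsv"}
    )
(tmp / "manifest.yaml").write_text(yaml.safe_dump(cfg))

report = run_study(load_manifest(tmp / "manifest.yaml"), MRConfig(seed=3), out_dir=tmp / "out")
print(f"Bonferroni threshold (alpha 0.05, {report['n_tests']} exposures): "
      f"{report['bonferroni_threshold']:.3g}\n")
print(summary_grid(report["analyses"]))
print(
    "\n'strong' = primary-method p below the corrected threshold, "
    "'suggestive' = below 0.05, 'null' otherwise.  Only the adiposity "
    "pair built on the same underlying study carries a true effect; "
    "cross pairs share no SNP overlap and fall out at harmonization.  "
    f"Full tables were written to {tmp/'out'}."
)
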