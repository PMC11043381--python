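"""A single dominant variant driving an apparent causal signal.

East Asian alcohol GWAS are dominated by the ALDH2-locus variant rs671,
whose huge effect and precision can single-handedly create MR
associations.  This script reproduces the phenomenon synthetically: the
true causal effect is zero, but one planted variant carries ~90% of the
IVW weight plus a direct outcome effect.  Leave-one-out analysis exposes
it.
"""

from mr2s import (
    generate_study,
    harmonize_all,
    ivw_random_effects,
    leave_one_out,
    make_truth,
    plant_dominant_instrument,
)

study = generate_study(make_truth(m_snps=20, beta_causal=0.0, seed=5))
dominated = plant_dominant_instrument(study, weight_share=0.9, outcome_shift=0.15, seed=6)

h = harmonize_all(dominated.exposure_records, dominated.outcome_records)
full = ivw_random_effects(h)
table = leave_one_out(h)
dom = dominated.truth.dominant_id

print(f"true causal effect: 0.0; dominant variant: {dom}")
print(f"full-sample IVW: beta = {full.beta_hat:.3f}, p = {full.pval:.2e}")
for excluded, beta, _se, p in table.rows[1:]:
    marker = "  <-- dominant" if excluded == dom else ""
    if excluded == dom or p >= 0.05:
        print(f"  excluding {excluded}: beta = {beta:.3f}, p = {p:.3f}{marker}")
print(f"influential variants flagged: {table.influential_ids}")
print(
    "\nThe association is significant with all variants but vanishes the "
    "moment the dominant one is excluded — the leave-one-out table flags "
    "exactly that variant, so the 'causal' signal rests on a single SNP."
)
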