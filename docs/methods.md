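# Methods

## The model

`mr2s` implements two-sample Mendelian randomization (MR) from GWAS
summary statistics.  For SNP j, let γ_j be its true effect on the
exposure and α_j its direct (pleiotropic) effect on the outcome.  Under
the instrumental-variable assumptions (relevance, independence from
confounders, exclusion restriction) the true SNP-outcome effect is

    Γ_j = β γ_j + α_j

with β the causal effect of interest — per SD of a quantitative
exposure, per log-odds unit of a binary one; on a binary outcome β is a
log odds ratio.  The observed summary statistics are the (γ̂_j, Γ̂_j)
pairs with their standard errors, from two non-overlapping (or partially
overlapping) samples.

Per-SNP Wald ratios θ̂_j = Γ̂_j / γ̂_j with first-order standard errors
se(Γ̂_j)/|γ̂_j| feed five estimators:

* **Wald ratio** — a single θ̂_j, or the fixed-effect inverse-variance
  average when exactly two instruments survive.  (How two surviving
  ratios should be combined is genuinely underdetermined in common
  usage; fixed-effect averaging is the natural degenerate case of IVW
  and is what we do.)
* **IVW (multiplicative random effects)** — the inverse-variance-weighted
  mean of the θ̂_j, algebraically identical to weighted regression of
  Γ̂ on γ̂ through the origin.  The fixed-effect SE is inflated by
  √(Q/(n−1)) when Cochran's Q exceeds its degrees of freedom, and never
  deflated (inflation floored at 1).
* **MR-Egger** — the same weighted regression with a free intercept,
  each SNP first oriented so γ̂_j > 0.  The intercept estimates the mean
  directional pleiotropy; the slope is consistent for β under InSIDE
  (instrument strength independent of direct effects).  Inference is
  ordinary WLS with t on n−2 df, with no variance floor: an exact fit
  legitimately yields zero residual variance, which is what makes the
  collinear worked example detect its offset.
* **Weighted median** — interpolates the weight-ordered ratios at
  cumulative weight ½ (each SNP contributing its weight centred on its
  position); consistent when valid instruments carry a majority of the
  weight.  SE by parametric bootstrap, θ̂*_j ~ N(θ̂_j, se_j²).
* **Weighted mode** — the argmax of a weighted Gaussian kernel density
  over the ratios, bandwidth 0.9·min(sd, mad)·n^(−1/5) scaled by a user
  factor (default 1), evaluated on a 512-point grid spanning the ratios
  ±3 bandwidths; same bootstrap SE.

95% intervals use z = 1.959964 throughout (kept at this precision for
bit-reproducibility); odds ratios are the exponentiated estimate and
bounds.  Egger keeps its t-based p-value through the odds transform.

## Instrument selection

The QC cascade applies, in order, with strict inequalities:

| step | rule | default |
|---|---|---|
| significance | p < threshold | 5×10⁻⁸ |
| frequency | MAF = min(eaf, 1−eaf) ≥ minimum | 0.01 |
| LD clumping | greedy lowest-p-first, discard r² ≥ cutoff within window | r² 0.001, ±10,000 kb |
| strength | F > minimum | 10 |

Strength uses PVE = 2·MAF·(1−MAF)·β² and F = PVE·(N−2)/(1−PVE); when
the frequency is unreported the record passes the MAF filter (it cannot
be evaluated; logged) and F falls back to β²/se².  Under the standard
se ≈ 1/√(2·MAF·(1−MAF)·N) approximation the two formulas agree to
within a factor (1−PVE), which the tests bound at 10%.

Clumping is greedy on p-value (ties broken by chromosome, then
position) — the de facto standard; the window is interpreted as
±window around the index SNP on the same chromosome, and a
same-chromosome in-window pair absent from the LD matrix is a hard
error rather than an assumption of independence.

Participant overlap between the two GWAS biases the estimate by
approximately β·r/F̄ (overlap rate r, mean instrument F̄), which the
runner reports when an overlap rate is supplied.

Confounder screening against an online variant database is represented
by a user-supplied exclusion list (ID → reason): listed SNPs are removed
and the analysis re-run, with the original always reported alongside.

## Harmonization

Outcome records are rewritten in the exposure's allele orientation:
identical pair → unchanged; swapped pair → sign flip and mirrored
frequency; complementary-strand pair → relabel then proceed.
Palindromic variants (A/T, C/G) carry no strand information in their
alleles, so orientation is inferred from allele frequency: both
frequencies must lie on the same side of 0.5 and at least 0.08 away
from it (the widely used default; configurable — setting the limit to
0.5 forces the drop path), otherwise the SNP is dropped as ambiguous.
Missing frequency on either side drops a palindromic SNP and leaves a
non-palindromic one to allele identity.  Effect sizes are never
rescaled; harmonization is idempotent and all causal estimates are
invariant to any relabelling of input records (both properties are
tested to 1e-12).

## Diagnostics

* **Cochran's Q** over the ratio estimates, χ² on n−1 df.
* **Outlier screen** (MR-PRESSO-style): each SNP's expected outcome
  effect under no pleiotropy is its leave-one-out through-origin slope
  times its exposure effect; the observed weighted residual sum of
  squares is compared with parametric simulations under that null
  (default 1000).  Monte-Carlo p-values use the add-one rule
  (1+k)/(n_sim+1), so they are valid and never zero.  Per-SNP outlier
  p-values are Bonferroni-adjusted across instruments; flagged SNPs are
  removed and the estimate recomputed (a config switch reports the
  global test only), and a distortion p compares the resulting shift
  against removing equally many random SNPs.  Requires ≥ 4 instruments;
  with the default 1000 simulations the smallest attainable adjusted
  p is n/1001, so per-SNP detection is possible for n ≲ 50.
* **Egger intercept test**: p > 0.05 (strict) reads "no evidence of
  directional pleiotropy", otherwise "pleiotropy suspected".
* **Leave-one-out**: IVW with each SNP excluded; a variant is
  influential when its exclusion moves the p-value across 0.05 in
  either direction or flips the estimate's sign.  This is the check
  that exposes single-variant-driven associations such as the
  ALDH2-locus variant rs671 dominating East Asian alcohol instruments.
* **Power**: two-sided normal approximation for a binary outcome with
  noncentrality |β|·√(N·PVE·K(1−K)), K the case fraction — the formula
  family behind the mRnd-style calculators.

## Study grid

`run_study` analyses every exposure×outcome pair of a manifest.
Associations are classified on the primary method's p-value only (IVW,
or Wald ratio when ≤ 2 SNPs survive): *strong* below α/n_exposures
(0.05/19 = 2.63×10⁻³ in a 19-trait screen — the denominator is exposure
traits, not pairs), *suggestive* below 0.05, *null* otherwise.  One
pair's failure is recorded and does not stop the grid.

## Synthetic generator

The generator realises the model above directly: γ̂_j = γ_j + se_x·e_x,
Γ̂_j = βγ_j + α_j + se_y·e_y, with se = 1/√(2·MAF(1−MAF)N) and a
1/√(K(1−K)) inflation for binary outcomes; corr(e_x, e_y) equals the
participant-overlap rate.  γ_j are |N(0.06, 0.02²)| by default — GWAS
top hits explain a fraction of a percent of variance each, so 25–100
such instruments give summed PVE around 1–4% and F-statistics in the
hundreds, typical of the strong-instrument regime this design targets;
effect alleles are taken as exposure-increasing (sign randomisation is
an option, but then "directional" pleiotropy in the label frame is
balanced in the analysis frame).  α_j ~ N(α_mean, α_sd²), correlated
with instrument strength only when an InSIDE violation is requested.
Default sample sizes are 100,000 per GWAS with a 10% outcome case
fraction, matching the biobank-scale studies this workflow is designed
for.

Nuisances are planted on demand: palindromic alleles (frequency kept ≤
0.35 so concordance can resolve them, or forced to 0.5 to exercise the
drop path), strand-flipped outcome records, block-diagonal LD with
constant within-block r², outcome-beta outliers, and a dominant
instrument whose exposure effect is rescaled until it carries a target
share of IVW weight.

What the generator does *not* emulate: realistic LD maps (blocks are
constant-r²), winner's curse in instrument discovery, allele-frequency
differences between the two samples, covariate-adjusted or mixed-model
GWAS, and case-control ascertainment beyond the K(1−K) variance
inflation.  Passing tests therefore demonstrate correctness of the
estimators and the plumbing under the stated model, not robustness to
every pathology of real GWAS.

## Numerical choices and edge cases

* Ratio SEs are first-order by default (exposure noise ignored), the
  common convention at F ≫ 10; a second-order option exists.
* SNPs with γ̂_j = 0 exactly are dropped from ratio-based estimators
  with a logged reason (they carry no information and break division).
* Degenerate Egger designs (all γ̂ equal after orientation) are a hard
  error rather than a silent infinite-variance fit.
* The weighted-mode bandwidth falls back to the larger of sd/mad when
  the smaller is zero; identical ratios short-circuit to that value.
* p-values are clamped to (0, 1]; Monte-Carlo p-values cannot be 0 by
  construction.
* The dominant-instrument rescaling overshoots its weight-share target
  by one part in 10⁹ so the requested share holds under float rounding.

## Problem sizes in the validation suite

The simulation-backed checks run at 50 instruments and 100k/100k
samples with 500 replicates for recovery/coverage, 1000 replicates for
null calibration, and 50–60 replicates for the detection-rate checks —
sizes at which Monte-Carlo error is comfortably inside the asserted
bands while the whole suite stays fast on a single core.

## Known limitations

* No multivariable MR, Steiger filtering, Radial-MR, or colocalization.
* No reference-panel LD estimation: the LD matrix is an input (or the
  identity when absent, appropriate only for pre-clumped instruments).
* The outlier screen removes flagged SNPs; it does not re-estimate
  corrected per-SNP effects.
* Proxy-SNP substitution for instruments missing in the outcome is not
  attempted; such SNPs are dropped and logged.
* Egger inference is plain WLS; with very homogeneous instruments its
  SE can be anti-conservative relative to a floored variant.
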