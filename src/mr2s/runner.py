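"""Orchestration of the full exposure-by-outcome study grid.

Per pair, the workflow is: instrument QC (significance, MAF, clumping,
strength) -> allele harmonization -> outlier screen (when at least four
instruments remain) -> Egger intercept pleiotropy test (three or more) ->
optional user exclusion list with a re-run -> Cochran's Q -> estimation
(Wald ratio when two or fewer SNPs survive, otherwise IVW / Egger /
weighted median / weighted mode) -> leave-one-out -> power.  Associations
are classified as strong below the Bonferroni threshold (family alpha
over the number of exposure traits), suggestive between that and 0.05,
null otherwise, always on the primary method's p-value (IVW, or Wald
ratio when it applies).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import diagnostics as dx
from . import estimators as est
from . import harmonize as hz
from . import qc
from .audit import AuditLog
from .io import read_ld_matrix, read_sumstats
from .types import (
    HarmonizedInstrument,
    MRResult,
    StudyManifest,
    StudyMeta,
    SummaryStatRecord,
    ValidationError,
)


@dataclass
class MRConfig:
    """Tunable thresholds of the pipeline, with field-standard defaults."""

    p_threshold: float = qc.P_THRESHOLD_DEFAULT
    maf_min: float = qc.MAF_MIN_DEFAULT
    clump_r2: float = qc.CLUMP_R2_DEFAULT
    clump_kb: float = qc.CLUMP_KB_DEFAULT
    f_min: float = qc.F_MIN_DEFAULT
    palindromic_eaf_limit: float = hz.PALINDROMIC_EAF_LIMIT_DEFAULT
    presso_n_sim: int = 1000
    presso_alpha: float = 0.05
    n_boot: int = 1000
    family_alpha: float = 0.05
    alpha: float = 0.05
    seed: int = 0
    exclusion_list: dict[str, str] = field(default_factory=dict)
    #: "remove_outliers" reruns estimation without flagged SNPs;
    #: "global_gate" only reports the global heterogeneity p.
    presso_mode: str = "remove_outliers"


@dataclass
class DiagnosticsReport:
    q: Optional[float] = None
    q_df: Optional[int] = None
    q_p: Optional[float] = None
    egger_intercept: Optional[float] = None
    egger_intercept_p: Optional[float] = None
    egger_verdict: Optional[str] = None
    presso: Optional[dx.PressoResult] = None
    loo: Optional[dx.LeaveOneOutTable] = None
    power: Optional[float] = None
    mean_f: Optional[float] = None
    overlap_bias: Optional[float] = None


@dataclass
class PairAnalysis:
    exposure: str
    outcome: str
    n_snps_initial: int
    n_snps_final: int
    results: dict[str, MRResult]
    diagnostics: DiagnosticsReport
    classification: str
    primary_method: Optional[str]
    status: str = "ok"  # ok | no_instruments
    instruments: list[HarmonizedInstrument] = field(default_factory=list)
    audit: Optional[AuditLog] = None
    rerun_after_exclusion: Optional["PairAnalysis"] = None


def bonferroni_threshold(n_tests: int, family_alpha: float = 0.05) -> float:
    """Family-wise threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValidationError("n_tests must be at least 1")
    return family_alpha / n_tests


def classify(pval: float, bonferroni: float, nominal: float = 0.05) -> str:
    """strong below the corrected threshold, suggestive below nominal."""
    if pval < bonferroni:
        return "strong"
    if pval < nominal:
        return "suggestive"
    return "null"


def _estimate(
    instruments: list[HarmonizedInstrument], config: MRConfig
) -> tuple[dict[str, MRResult], Optional[str]]:
    results: dict[str, MRResult] = {}
    n = len(instruments)
    if n == 0:
        return results, None
    if n <= 2:
        results[est.WALD_RATIO] = est.wald_ratio(instruments)
        return results, est.WALD_RATIO
    results[est.IVW_RE] = est.ivw_random_effects(instruments)
    results[est.EGGER] = est.egger(instruments)
    results[est.WEIGHTED_MEDIAN] = est.weighted_median(
        instruments, n_boot=config.n_boot, seed=config.seed
    )
    results[est.WEIGHTED_MODE] = est.weighted_mode(
        instruments, n_boot=config.n_boot, seed=config.seed
    )
    return results, est.IVW_RE


def run_pair(
    exposure_stats: list[SummaryStatRecord],
    outcome_stats: list[SummaryStatRecord],
    ld: pd.DataFrame,
    config: Optional[MRConfig] = None,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
    outcome_meta: Optional[StudyMeta] = None,
    n_tests: int = 1,
    overlap_rate: float = 0.0,
    _apply_exclusions: bool = True,
) -> PairAnalysis:
    """Run the complete single-pair analysis.

    Returns a PairAnalysis; a pair whose QC removes every SNP is marked
    ``no_instruments`` rather than raising.  When ``config.exclusion_list``
    intersects the instruments, the analysis is repeated without them and
    attached as ``rerun_after_exclusion`` (the original is always kept).
    """
    config = config or MRConfig()
    audit = AuditLog()
    n_initial = len(exposure_stats)

    sig = qc.select_significant(exposure_stats, config.p_threshold, audit)
    common = qc.filter_maf(sig, config.maf_min, audit)
    clumped = qc.ld_clump(common, ld, config.clump_r2, config.clump_kb, audit)
    graded = qc.grade_instruments(clumped)
    strong = qc.filter_weak(graded, config.f_min, audit)

    mean_f = (
        sum(i.f_stat for i in strong) / len(strong) if strong else None
    )

    harmonized = hz.harmonize_all(
        [i.base for i in strong],
        outcome_stats,
        config.palindromic_eaf_limit,
        audit,
    )

    diag = DiagnosticsReport(mean_f=mean_f)
    instruments = harmonized
    if len(instruments) >= 4:
        presso = dx.mr_presso(
            instruments,
            n_sim=config.presso_n_sim,
            alpha=config.presso_alpha,
            seed=config.seed,
        )
        diag.presso = presso
        if config.presso_mode == "remove_outliers" and presso.outlier_ids:
            flagged = set(presso.outlier_ids)
            for snp in presso.outlier_ids:
                audit.record(snp, "mr_presso", "drop", "pleiotropic_outlier")
            instruments = [h for h in instruments if h.snp_id not in flagged]

    if len(instruments) == 0:
        return PairAnalysis(
            exposure=exposure_name,
            outcome=outcome_name,
            n_snps_initial=n_initial,
            n_snps_final=0,
            results={},
            diagnostics=diag,
            classification="null",
            primary_method=None,
            status="no_instruments",
            audit=audit,
        )

    results, primary = _estimate(instruments, config)
    if est.EGGER in results:
        intercept, ise, ip, verdict = dx.egger_intercept_test(results[est.EGGER])
        diag.egger_intercept = intercept
        diag.egger_intercept_p = ip
        diag.egger_verdict = verdict
    if len(instruments) >= 2:
        diag.q, diag.q_df, diag.q_p = dx.cochran_q(instruments)
    if len(instruments) >= 3:
        diag.loo = dx.leave_one_out(instruments, alpha=config.alpha)
    if outcome_meta is not None and outcome_meta.case_fraction is not None and primary:
        pve_total = sum(
            p for p in (qc.compute_pve(h.eaf_exp, h.beta_exp) for h in instruments) if p
        )
        if pve_total > 0:
            diag.power = dx.mr_power(
                n_outcome=outcome_meta.n_total,
                case_fraction=outcome_meta.case_fraction,
                pve_total=pve_total,
                beta_causal=results[primary].beta_hat,
                alpha=config.alpha,
            )
    if overlap_rate > 0 and mean_f and primary:
        diag.overlap_bias = qc.overlap_bias(
            results[primary].beta_hat, overlap_rate, mean_f
        )

    threshold = bonferroni_threshold(n_tests, config.family_alpha)
    classification = (
        classify(results[primary].pval, threshold) if primary else "null"
    )
    analysis = PairAnalysis(
        exposure=exposure_name,
        outcome=outcome_name,
        n_snps_initial=n_initial,
        n_snps_final=len(instruments),
        results=results,
        diagnostics=diag,
        classification=classification,
        primary_method=primary,
        instruments=instruments,
        audit=audit,
    )

    if _apply_exclusions and config.exclusion_list:
        present = {h.snp_id for h in instruments} & set(config.exclusion_list)
        if present:
            retained = [
                r for r in exposure_stats if r.snp_id not in config.exclusion_list
            ]
            analysis.rerun_after_exclusion = run_pair(
                retained,
                outcome_stats,
                ld,
                config,
                exposure_name=exposure_name,
                outcome_name=outcome_name,
                outcome_meta=outcome_meta,
                n_tests=n_tests,
                overlap_rate=overlap_rate,
                _apply_exclusions=False,
            )
    return analysis


def results_table(analyses: list[PairAnalysis]) -> pd.DataFrame:
    rows = []
    for a in analyses:
        for method, r in a.results.items():
            rows.append(
                {
                    "exposure": a.exposure,
                    "outcome": a.outcome,
                    "method": method,
                    "n_snps": r.n_snps,
                    "beta": r.beta_hat,
                    "se": r.se_hat,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "or": r.or_point,
                    "or_low": r.or_low,
                    "or_high": r.or_high,
                    "pval": r.pval,
                    "egger_intercept": r.egger_intercept,
                    "egger_intercept_p": r.egger_intercept_p,
                    "classification": a.classification
                    if method == a.primary_method
                    else "",
                }
            )
    return pd.DataFrame(rows)


def summary_grid(analyses: list[PairAnalysis]) -> pd.DataFrame:
    """Exposure x outcome grid of classifications."""
    df = pd.DataFrame(
        [(a.exposure, a.outcome, a.classification) for a in analyses],
        columns=["exposure", "outcome", "classification"],
    )
    return df.pivot(index="exposure", columns="outcome", values="classification")


def run_study(
    manifest: StudyManifest,
    config: Optional[MRConfig] = None,
    out_dir: Optional[str] = None,
) -> dict:
    """Analyse every pair in the manifest and assemble the study report.

    A hard error in one pair is recorded in that pair's slot; the other
    pairs still run.  With ``out_dir`` set, writes results, diagnostics,
    summary-grid and audit TSVs plus a JSON run record.
    """
    config = config or MRConfig()
    exp_by_name = {m.trait_name: (m, f) for m, f in manifest.exposures}
    out_by_name = {m.trait_name: (m, f) for m, f in manifest.outcomes}
    n_tests = manifest.n_exposure_traits
    analyses: list[PairAnalysis] = []
    errors: dict[str, str] = {}
    cache: dict[str, list[SummaryStatRecord]] = {}
    ld_cache: dict[str, pd.DataFrame] = {}

    def _load(path: str) -> list[SummaryStatRecord]:
        if path not in cache:
            cache[path] = read_sumstats(path)
        return cache[path]

    for exp_name, out_name in manifest.pairs:
        try:
            exp_meta, exp_path = exp_by_name[exp_name]
            out_meta, out_path = out_by_name[out_name]
            ld_path = str(Path(exp_path).with_suffix(".ld.tsv"))
            if ld_path not in ld_cache:
                if Path(ld_path).exists():
                    ld_cache[ld_path] = read_ld_matrix(ld_path)
                else:
                    recs = _load(exp_path)
                    ids = [r.snp_id for r in recs]
                    import numpy as np

                    ld_cache[ld_path] = pd.DataFrame(
                        np.eye(len(ids)), index=ids, columns=ids
                    )
            analyses.append(
                run_pair(
                    _load(exp_path),
                    _load(out_path),
                    ld_cache[ld_path],
                    config,
                    exposure_name=exp_name,
                    outcome_name=out_name,
                    outcome_meta=out_meta,
                    n_tests=n_tests,
                )
            )
        except Exception as exc:  # noqa: BLE001 - one pair must not sink the grid
            errors[f"{exp_name}|{out_name}"] = str(exc)

    report = {
        "analyses": analyses,
        "errors": errors,
        "bonferroni_threshold": bonferroni_threshold(n_tests, config.family_alpha),
        "n_tests": n_tests,
        "config": dataclasses.asdict(config),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        results_table(analyses).to_csv(out / "results.tsv", sep="\t", index=False)
        summary_grid(analyses).to_csv(out / "summary_grid.tsv", sep="\t")
        diag_rows = []
        for a in analyses:
            d = a.diagnostics
            diag_rows.append(
                {
                    "exposure": a.exposure,
                    "outcome": a.outcome,
                    "n_snps_final": a.n_snps_final,
                    "Q": d.q,
                    "Q_df": d.q_df,
                    "Q_p": d.q_p,
                    "egger_intercept_p": d.egger_intercept_p,
                    "presso_global_p": d.presso.global_p if d.presso else None,
                    "presso_outliers": ",".join(d.presso.outlier_ids)
                    if d.presso
                    else "",
                    "distortion_p": d.presso.distortion_p if d.presso else None,
                    "power": d.power,
                    "mean_f": d.mean_f,
                }
            )
        pd.DataFrame(diag_rows).to_csv(out / "diagnostics.tsv", sep="\t", index=False)
        audit_frames = [
            a.audit.to_frame().assign(exposure=a.exposure, outcome=a.outcome)
            for a in analyses
            if a.audit is not None
        ]
        if audit_frames:
            pd.concat(audit_frames).to_csv(out / "audit.tsv", sep="\t", index=False)
        run_record = {
            "bonferroni_threshold": report["bonferroni_threshold"],
            "n_tests": n_tests,
            "config": dataclasses.asdict(config),
            "errors": errors,
        }
        (out / "run_record.json").write_text(json.dumps(run_record, indent=2))
    return report
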