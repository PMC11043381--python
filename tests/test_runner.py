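import yaml
import pytest

from mr2s import (
    MRConfig,
    ValidationError,
    bonferroni_threshold,
    classify,
    generate_study,
    load_manifest,
    make_truth,
    run_pair,
    run_study,
    write_ld_matrix,
    write_sumstats,
)
from mr2s.runner import summary_grid
from mr2s.studies import DSC_OUTCOMES


class TestBonferroni:
    def test_nineteen_exposures(self):
        assert bonferroni_threshold(19, 0.05) == pytest.approx(0.05 / 19)
        assert f"{bonferroni_threshold(19, 0.05):.2e}" == "2.63e-03"

    @pytest.mark.parametrize("n, expected", [(1, 0.05), (20, 0.0025)])
    def test_direct_division(self, n, expected):
        assert bonferroni_threshold(n, 0.05) == pytest.approx(expected)

    def test_zero_tests_is_hard_error(self):
        with pytest.raises(ValidationError):
            bonferroni_threshold(0)


class TestClassify:
    @pytest.mark.parametrize(
        "pval, expected",
        [
            (1e-4, "strong"),
            (0.01, "suggestive"),
            (0.2, "null"),
            (0.05, "null"),          # nominal bound is strict
            (0.05 / 19, "suggestive"),  # corrected bound is strict
        ],
    )
    def test_bands(self, pval, expected):
        assert classify(pval, bonferroni_threshold(19)) == expected


def small_config(**kw):
    defaults = dict(presso_n_sim=300, n_boot=100, seed=0)
    defaults.update(kw)
    return MRConfig(**defaults)


class TestRunPair:
    def test_strong_effect_all_four_methods_same_sign(self):
        study = generate_study(make_truth(m_snps=50, beta_causal=0.3, seed=1))
        analysis = run_pair(
            study.exposure_records,
            study.outcome_records,
            study.ld_matrix,
            small_config(),
        )
        assert analysis.status == "ok"
        assert set(analysis.results) == {
            "ivw_re", "egger", "weighted_median", "weighted_mode"
        }
        signs = {r.beta_hat > 0 for r in analysis.results.values()}
        assert signs == {True}
        assert analysis.primary_method == "ivw_re"
        assert analysis.n_snps_final <= analysis.n_snps_initial

    def test_two_or_fewer_snps_use_wald_ratio_only(self):
        study = generate_study(make_truth(m_snps=2, beta_causal=0.3, seed=2))
        analysis = run_pair(
            study.exposure_records, study.outcome_records, study.ld_matrix,
            small_config(),
        )
        assert list(analysis.results) == ["wald_ratio"]
        assert analysis.primary_method == "wald_ratio"

    def test_all_snps_filtered_marks_no_instruments(self):
        study = generate_study(make_truth(m_snps=5, beta_causal=0.3, seed=3))
        analysis = run_pair(
            study.exposure_records, study.outcome_records, study.ld_matrix,
            small_config(p_threshold=1e-300),
        )
        assert analysis.status == "no_instruments"
        assert analysis.results == {}
        assert analysis.classification == "null"

    def test_attrition_accounting(self):
        study = generate_study(
            make_truth(m_snps=60, beta_causal=0.2, maf_range=(0.01, 0.5),
                       ld_blocks=[(6, 0.9)], frac_palindromic=0.15,
                       ambiguous_palindromes=True, seed=4)
        )
        analysis = run_pair(
            study.exposure_records, study.outcome_records, study.ld_matrix,
            small_config(),
        )
        drops = len(analysis.audit.drops())
        assert analysis.n_snps_initial == analysis.n_snps_final + drops

    def test_exclusion_list_triggers_rerun_keeping_original(self):
        study = generate_study(make_truth(m_snps=30, beta_causal=0.3, seed=5))
        target = study.exposure_records[0].snp_id
        analysis = run_pair(
            study.exposure_records, study.outcome_records, study.ld_matrix,
            small_config(exclusion_list={target: "smoking_associated"}),
        )
        rerun = analysis.rerun_after_exclusion
        assert rerun is not None
        assert target in {h.snp_id for h in analysis.instruments}
        assert target not in {h.snp_id for h in rerun.instruments}
        assert rerun.rerun_after_exclusion is None

    def test_power_reported_for_binary_outcome(self):
        study = generate_study(make_truth(m_snps=30, beta_causal=0.3, seed=6))
        analysis = run_pair(
            study.exposure_records, study.outcome_records, study.ld_matrix,
            small_config(),
            outcome_meta=DSC_OUTCOMES["gastric_cancer"],
        )
        assert analysis.diagnostics.power is not None
        assert 0.0 <= analysis.diagnostics.power <= 1.0


def write_manifest(tmp_path, specs):
    """specs: list of (kind, name, beta_causal, seed, m)."""
    cfg = {"exposures": [], "outcomes": []}
    for kind, name, beta, seed, m in specs:
        study = generate_study(make_truth(m_snps=m, beta_causal=beta, seed=seed))
        recs = study.exposure_records if kind == "exposures" else study.outcome_records
        path = tmp_path / f"{name}.tsv"
        write_sumstats(recs, path)
        if kind == "exposures":
            write_ld_matrix(study.ld_matrix, tmp_path / f"{name}.ld.tsv")
            cfg["exposures"].append(
                {"name": name, "type": "quantitative", "n_total": 100_000, "file": path.name}
            )
        else:
            cfg["outcomes"].append(
                {"name": name, "type": "binary", "n_total": 100_000,
                 "n_cases": 10_000, "n_controls": 90_000, "file": path.name}
            )
    mp = tmp_path / "manifest.yaml"
    mp.write_text(yaml.safe_dump(cfg))
    return mp


class TestRunStudy:
    def test_two_by_two_grid(self, tmp_path):
        # exposure/outcome pairs generated from one truth each so SNP IDs align
        study_a = generate_study(make_truth(m_snps=20, beta_causal=0.3, seed=11))
        study_b = generate_study(make_truth(m_snps=20, beta_causal=0.0, seed=12))
        cfg = {"exposures": [], "outcomes": []}
        for name, study in [("expA", study_a), ("expB", study_b)]:
            p = tmp_path / f"{name}.tsv"
            write_sumstats(study.exposure_records, p)
            write_ld_matrix(study.ld_matrix, tmp_path / f"{name}.ld.tsv")
            cfg["exposures"].append(
                {"name": name, "type": "quantitative", "n_total": 100_000, "file": p.name}
            )
        for name, study in [("outA", study_a), ("outB", study_b)]:
            p = tmp_path / f"{name}.tsv"
            write_sumstats(study.outcome_records, p)
            cfg["outcomes"].append(
                {"name": name, "type": "binary", "n_total": 100_000,
                 "n_cases": 10_000, "n_controls": 90_000, "file": p.name}
            )
        mp = tmp_path / "manifest.yaml"
        mp.write_text(yaml.safe_dump(cfg))
        report = run_study(load_manifest(mp), small_config(), out_dir=tmp_path / "out")
        assert len(report["analyses"]) == 4
        grid = summary_grid(report["analyses"])
        assert grid.shape == (2, 2)
        assert (tmp_path / "out" / "results.tsv").exists()
        assert (tmp_path / "out" / "run_record.json").exists()
        assert (tmp_path / "out" / "audit.tsv").exists()

    def test_report_carries_bonferroni_threshold(self, tmp_path):
        mp = write_manifest(tmp_path, [
            ("exposures", "e1", 0.2, 21, 10),
            ("outcomes", "o1", 0.2, 21, 10),
        ])
        manifest = load_manifest(mp)
        manifest.n_exposure_traits = 19
        report = run_study(manifest, small_config())
        assert report["bonferroni_threshold"] == pytest.approx(0.05 / 19)

    def test_determinism_of_rerun(self, tmp_path):
        mp = write_manifest(tmp_path, [
            ("exposures", "e1", 0.2, 31, 15),
            ("outcomes", "o1", 0.2, 31, 15),
        ])
        manifest = load_manifest(mp)
        r1 = run_study(manifest, small_config(), out_dir=tmp_path / "o1")
        r2 = run_study(manifest, small_config(), out_dir=tmp_path / "o2")
        assert (tmp_path / "o1" / "results.tsv").read_bytes() == (
            tmp_path / "o2" / "results.tsv"
        ).read_bytes()
        assert len(r1["analyses"]) == len(r2["analyses"]) == 1


class TestEndToEndRecovery:
    def test_true_effect_classified_strong_and_nulls_null(self):
        """A 3-exposure x 2-outcome grid with one true effect and five
        nulls: the effect comes out strong, nearly all nulls null."""
        successes = 0
        for seed in range(10):
            base = 1000 * seed
            truths = {
                ("e1", "o1"): 0.3,  # the one true effect
                ("e1", "o2"): 0.0, ("e2", "o1"): 0.0, ("e2", "o2"): 0.0,
                ("e3", "o1"): 0.0, ("e3", "o2"): 0.0,
            }
            classes = {}
            for i, ((e, o), beta) in enumerate(truths.items()):
                study = generate_study(
                    make_truth(m_snps=40, beta_causal=beta, seed=base + i)
                )
                a = run_pair(
                    study.exposure_records, study.outcome_records, study.ld_matrix,
                    small_config(seed=base + i), n_tests=3,
                )
                classes[(e, o)] = a.classification
            nulls_ok = sum(
                classes[k] == "null" for k, b in truths.items() if b == 0.0
            )
            if classes[("e1", "o1")] == "strong" and nulls_ok >= 4:
                successes += 1
        assert successes >= 9
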