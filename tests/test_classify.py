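"""Mechanistic locus classification: rules, invariances, recovery."""

import numpy as np
import pytest

from zwscan import (
    ArtifactSpec,
    ClassifyThresholds,
    SimConfig,
    classify_locus,
    scan_report,
    sex_genotype_profile,
    simulate_cohort,
    simulate_depth,
)


def _profile(calls_m, calls_f, chrom="5", pos=100, depth_m=None, depth_f=None):
    calls = np.array(calls_m + calls_f, dtype=np.int8)
    sexes = ["M"] * len(calls_m) + ["F"] * len(calls_f)
    depth = None
    if depth_m is not None:
        depth = np.array(depth_m + depth_f, dtype=float)
    return sex_genotype_profile(calls, sexes, "locus", chrom, pos, depth=depth)


class TestProfile:
    def test_split_artifact_profile(self):
        prof = _profile([0] * 30, [2] * 30)
        assert prof.counts_m == (30, 0, 0)
        assert prof.counts_f == (0, 0, 30)
        assert prof.theta_mf == 1.0

    def test_het_artifact_profile(self):
        prof = _profile([0] * 30, [1] * 30)
        assert prof.het_f == 1.0
        assert prof.het_m == 0.0
        assert prof.theta_mf == pytest.approx(0.5, abs=1e-12)

    def test_insufficient_data_untestable(self):
        prof = _profile([0] * 3, [1] * 30)
        assert not prof.testable

    def test_coverage_ratio(self):
        prof = _profile([0] * 10, [2] * 10, depth_m=[20.0] * 10, depth_f=[120.0] * 10)
        assert prof.coverage_ratio == pytest.approx(6.0)


class TestRules:
    def test_fixed_difference_category(self):
        call = classify_locus(_profile([0] * 30, [2] * 30))
        assert call.category == "fixed_between_sex_paralog"
        assert call.action == "exclude_and_validate"

    def test_sex_limited_het_category(self):
        call = classify_locus(_profile([0] * 30, [1] * 30))
        assert call.category == "sex_limited_het_paralog"
        assert call.action == "exclude_and_validate"

    def test_z_dosage_category(self):
        # polymorphic Z locus: males het-rich, females homozygous only
        calls_m = [0, 1, 1, 2, 1, 0, 1, 2, 1, 1]
        calls_f = [0, 2, 0, 2, 2, 0, 0, 2, 0, 2]
        call = classify_locus(_profile(calls_m, calls_f, chrom="Z"), z_chrom="Z")
        assert call.category == "z_linked_dosage"
        assert call.action == "analyze_by_sex"

    def test_neutral_profile_kept(self):
        rng = np.random.default_rng(1)
        g = rng.binomial(2, 0.4, size=60).tolist()
        call = classify_locus(_profile(g[:30], g[30:]))
        assert call.category == "unremarkable"
        assert call.action == "keep"

    def test_allele_swap_invariance(self):
        prof = _profile([0] * 30, [2] * 30)
        swapped = _profile([2] * 30, [0] * 30)
        assert classify_locus(prof).category == classify_locus(swapped).category
        prof_het = _profile([2] * 30, [1] * 30)
        assert classify_locus(prof_het).category == "sex_limited_het_paralog"

    def test_noisy_real_data_pattern_still_classified(self):
        """theta ~ 0.96 with a few discordant calls, as in real chip data."""
        prof = _profile([0] * 29 + [2], [2] * 29 + [0])
        assert classify_locus(prof).category == "fixed_between_sex_paralog"

    def test_depth_changes_evidence_not_category(self):
        bare = classify_locus(_profile([0] * 30, [2] * 30))
        with_depth = classify_locus(
            _profile([0] * 30, [2] * 30, depth_m=[20.0] * 30, depth_f=[110.0] * 30)
        )
        assert bare.category == with_depth.category
        assert any("coverage" in e for e in with_depth.evidence)
        assert not any("coverage" in e for e in bare.evidence)


@pytest.fixture(scope="module")
def big_cohort():
    cfg = SimConfig(
            populations=[("P", 25, 25)],
            L_auto=5000,
            L_z=200,
            artifact_loci=[
                ArtifactSpec("5", 1001, "split_call"),
                ArtifactSpec("5", 2002, "het_call"),
            ],
        seed=5,
    )
    matrix, samples, truth = simulate_cohort(cfg)
    depth = simulate_depth(truth, samples, 20.0, seed=55)
    return matrix, samples, truth, depth


class TestScanReport:
    def test_sensitivity_and_false_positive_rate(self, big_cohort):
        """Both planted artifacts recovered with the right category; no
        autosomal background locus among 5000 is called a paralog."""
        matrix, samples, truth, depth = big_cohort
        report = scan_report(matrix, samples["sex"], depth=depth, z_chrom="Z")
        by_id = report.set_index("ID")
        assert by_id.loc["artifact_5_1001", "CATEGORY"] == "fixed_between_sex_paralog"
        assert by_id.loc["artifact_5_2002", "CATEGORY"] == "sex_limited_het_paralog"
        neutral = report[report["ID"].str.startswith("auto")]
        paralog_fp = neutral["CATEGORY"].isin(
            ["fixed_between_sex_paralog", "sex_limited_het_paralog"]
        )
        assert paralog_fp.sum() <= 0.001 * 5000

    def test_impossible_threshold_empty(self, big_cohort):
        matrix, samples, _, _ = big_cohort
        report = scan_report(matrix, samples["sex"], report_threshold=1.1)
        assert report.empty

    def test_report_has_coverage_evidence(self, big_cohort):
        matrix, samples, _, depth = big_cohort
        report = scan_report(matrix, samples["sex"], depth=depth).set_index("ID")
        assert "coverage" in report.loc["artifact_5_1001", "EVIDENCE"]
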