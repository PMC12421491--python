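"""Weir-Cockerham estimator: fixed points, oracle equivalence, filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zwscan import (
    GenotypeMatrix,
    VariantFilter,
    allele_stats,
    filter_variants,
    fst_scan,
    wc_components,
    weighted_fst,
)


def wc_oracle(n, p, h):
    """Independent scalar evaluation of the 1984 variance components.

    Deliberately written as plain per-group loops against the published
    component definitions, sharing no code with the vectorized
    implementation it cross-checks.
    """
    r = len(n)
    nbar = sum(n) / r
    nc = (r * nbar - sum(ni**2 for ni in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    denom = a + b + c
    theta = a / denom if denom != 0 else float("nan")
    return a, b, c, theta


def _stats_from_counts(counts_per_group):
    """GroupAlleleStats from per-group (nAA, nAa, naa) genotype counts."""
    calls = []
    groups = []
    offset = 0
    for n_aa, n_ab, n_bb in counts_per_group:
        g = [0] * n_aa + [1] * n_ab + [2] * n_bb
        calls.extend(g)
        groups.append(np.arange(offset, offset + len(g)))
        offset += len(g)
    return allele_stats(np.array(calls, dtype=np.int8), groups)


class TestFixedPoints:
    def test_fixed_difference_gives_theta_one(self):
        rec = wc_components(_stats_from_counts([(54, 0, 0), (0, 0, 54)]))
        assert (rec.a, rec.b, rec.c) == (0.5, 0.0, 0.0)
        assert rec.theta == 1.0

    def test_homozygous_vs_heterozygous_gives_half(self):
        rec = wc_components(_stats_from_counts([(54, 0, 0), (0, 54, 0)]))
        assert rec.a == pytest.approx(0.125, abs=1e-12)
        assert rec.b == pytest.approx(-0.125, abs=1e-12)
        assert rec.c == pytest.approx(0.25, abs=1e-12)
        assert rec.theta == pytest.approx(0.5, abs=1e-12)

    def test_identical_heterozygous_groups_give_zero(self):
        rec = wc_components(_stats_from_counts([(0, 12, 0), (0, 12, 0)]))
        assert rec.a == 0.0
        assert rec.theta == 0.0

    def test_monomorphic_everywhere_is_nan(self):
        rec = wc_components(_stats_from_counts([(10, 0, 0), (10, 0, 0)]))
        assert np.isnan(rec.theta)


genotype_counts = st.tuples(
    st.integers(0, 8), st.integers(0, 8), st.integers(0, 8)
).filter(lambda t: sum(t) >= 2)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(st.lists(genotype_counts, min_size=2, max_size=4))
def test_components_match_independent_oracle(groups):
    """Random small instances (r <= 4, n_i <= 24) agree with the scalar
    oracle to 1e-12 on every component."""
    stats = _stats_from_counts(groups)
    rec = wc_components(stats)
    a, b, c, theta = wc_oracle(stats.n.tolist(), stats.p.tolist(), stats.h.tolist())
    assert rec.a == pytest.approx(a, abs=1e-12)
    assert rec.b == pytest.approx(b, abs=1e-12)
    assert rec.c == pytest.approx(c, abs=1e-12)
    if np.isnan(theta):
        assert np.isnan(rec.theta)
    else:
        assert rec.theta == pytest.approx(theta, abs=1e-12)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(genotype_counts, min_size=2, max_size=4))
def test_theta_invariant_under_allele_swap_and_group_relabeling(groups):
    rec = wc_components(_stats_from_counts(groups))
    swapped = wc_components(_stats_from_counts([(bb, ab, aa) for aa, ab, bb in groups]))
    relabeled = wc_components(_stats_from_counts(groups[::-1]))
    for other in (swapped, relabeled):
        if np.isnan(rec.theta):
            assert np.isnan(other.theta)
        else:
            assert other.theta == pytest.approx(rec.theta, abs=1e-12)


class TestAlleleStats:
    def test_counting_with_missing(self):
        calls = np.array([0, 0, 0, -1, 1, 1], dtype=np.int8)
        stats = allele_stats(calls, [np.arange(4), np.arange(4, 6)])
        assert stats.n.tolist() == [3, 2]
        assert stats.p.tolist() == [0.0, 0.5]
        assert stats.h.tolist() == [0.0, 1.0]

    def test_all_missing_group_rejected(self):
        calls = np.array([0, 1, -1, -1], dtype=np.int8)
        with pytest.raises(ValueError):
            allele_stats(calls, [np.arange(2), np.arange(2, 4)])


def _matrix(calls, chroms=None):
    calls = np.asarray(calls, dtype=np.int8)
    L = calls.shape[1]
    loci = pd.DataFrame(
        {
            "chrom": chroms or ["1"] * L,
            "pos": np.arange(1, L + 1) * 10,
            "id": [f"snp{i}" for i in range(L)],
            "ref": "A",
            "alt": "G",
        }
    )
    return GenotypeMatrix(calls, loci, [f"s{i}" for i in range(calls.shape[0])])


class TestFilters:
    def test_maf_and_geno_filters(self):
        # locus 0: MAF 0.005 (1 alt allele in 100); locus 1: 85% missing;
        # locus 2: monomorphic; locus 3: fine
        calls = np.zeros((100, 4), dtype=np.int8)
        calls[0, 0] = 1
        calls[:85, 1] = -1
        calls[:50, 3] = 1
        kept = filter_variants(_matrix(calls), VariantFilter())
        assert kept.loci["id"].tolist() == ["snp3"]

    def test_maf_computed_on_retained_individuals(self):
        # 50% missing passes geno 0.8; MAF among retained = 0.25
        calls = np.full((20, 1), -1, dtype=np.int8)
        calls[:10, 0] = [1, 0, 0, 0, 1, 0, 0, 0, 1, 2]
        kept = filter_variants(_matrix(calls), VariantFilter(maf_min=0.2))
        assert kept.n_loci == 1


class TestScan:
    def test_scan_orders_and_symmetry(self, six_pop_cohort):
        cfg, matrix, samples, truth = six_pop_cohort
        males = samples.loc[samples["sex"] == "M", "id"].tolist()
        females = samples.loc[samples["sex"] == "F", "id"].tolist()
        scan = fst_scan(matrix, males, females)
        assert (scan.groupby("CHROM")["POS"].apply(lambda s: s.is_monotonic_increasing)).all()
        permuted = fst_scan(matrix, males[::-1], females[::-1])
        pd.testing.assert_frame_equal(scan, permuted)

    def test_planted_artifacts_are_the_only_theta_peaks(self, six_pop_cohort):
        """54 males vs 54 females: split artifact at theta 1, het artifact at
        0.5, every background locus well below the 0.2 peak threshold."""
        cfg, matrix, samples, truth = six_pop_cohort
        males = samples.loc[samples["sex"] == "M", "id"].tolist()
        females = samples.loc[samples["sex"] == "F", "id"].tolist()
        scan = fst_scan(matrix, males, females).set_index("ID")
        assert scan.loc["artifact_5_10662578", "THETA"] == 1.0
        assert scan.loc["artifact_5_10700000", "THETA"] == pytest.approx(0.5, abs=1e-12)
        autosomal = scan[scan.index.str.startswith("auto")]
        assert (autosomal["THETA"] < 0.2).all()

    def test_overlapping_groups_rejected(self, six_pop_cohort):
        _, matrix, samples, _ = six_pop_cohort
        ids = samples["id"].tolist()
        with pytest.raises(ValueError, match="overlap"):
            fst_scan(matrix, ids[:10], ids[5:15])

    def test_all_loci_failing_filters_gives_empty_table(self):
        calls = np.zeros((10, 3), dtype=np.int8)  # all monomorphic
        scan = fst_scan(_matrix(calls), [f"s{i}" for i in range(5)],
                        [f"s{i}" for i in range(5, 10)])
        assert scan.empty

    def test_balding_nichols_recovers_generating_fst(self):
        """Genome-wide WC estimate over 5000 loci recovers F_bg = 0.2
        within Monte-Carlo error (50 diploids per population)."""
        from zwscan import SimConfig, simulate_cohort

        cfg = SimConfig(populations=[("A", 25, 25), ("B", 25, 25)],
                        L_auto=5000, L_z=0, F_bg=0.2, seed=11)
        matrix, samples, _ = simulate_cohort(cfg)
        ga = samples.loc[samples["population"] == "A", "id"].tolist()
        gb = samples.loc[samples["population"] == "B", "id"].tolist()
        scan = fst_scan(matrix, ga, gb, vfilter=False)
        assert weighted_fst(scan) == pytest.approx(0.2, abs=0.02)
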