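import itertools

import numpy as np
import pytest

from popstruct import qc
from popstruct.cohort import MISSING

from conftest import make_cohort


class TestAlleleFrequency:
    def test_simple_arithmetic(self):
        cohort = make_cohort([[0], [1], [2]])
        freqs = qc.allele_frequency(cohort)
        assert freqs["alt_freq"].iloc[0] == 0.5
        assert freqs["maf"].iloc[0] == 0.5

    def test_missing_excluded_from_denominator(self):
        cohort = make_cohort([[2], [2], [MISSING]])
        freqs = qc.allele_frequency(cohort)
        assert freqs["alt_freq"].iloc[0] == 1.0
        assert freqs["maf"].iloc[0] == 0.0

    def test_all_missing_gives_nan(self):
        cohort = make_cohort([[MISSING], [MISSING]])
        assert np.isnan(qc.allele_frequency(cohort)["alt_freq"].iloc[0])

    def test_matches_brute_force_count(self, rng):
        calls = rng.choice([-1, 0, 1, 2], size=(30, 15))
        cohort = make_cohort(calls)
        freqs = qc.allele_frequency(cohort)
        for j in range(15):
            col = calls[:, j]
            obs = col[col >= 0]
            expected = obs.sum() / (2 * len(obs)) if len(obs) else np.nan
            if np.isnan(expected):
                assert np.isnan(freqs["alt_freq"].iloc[j])
            else:
                assert freqs["alt_freq"].iloc[j] == pytest.approx(expected)

    def test_sample_subset(self):
        cohort = make_cohort([[0], [2], [2]])
        freqs = qc.allele_frequency(cohort, sample_subset=["s2", "s3"])
        assert freqs["alt_freq"].iloc[0] == 1.0


class TestExcludeRegions:
    def test_boundaries_inclusive(self):
        cohort = make_cohort(
            np.zeros((1, 3), dtype=np.int8), pos=[100, 200, 300]
        )
        out = qc.exclude_regions(cohort, [("1", 100, 200)])
        assert out.variants["pos"].tolist() == [300]

    def test_empty_region_list_is_identity(self, toy_cohort):
        assert qc.exclude_regions(toy_cohort, []) is toy_cohort

    def test_hand_counted_removal(self):
        cohort = make_cohort(
            np.zeros((1, 10), dtype=np.int8),
            pos=[i * 100 for i in range(1, 11)],
        )
        out = qc.exclude_regions(cohort, [("1", 250, 550)])  # removes 300,400,500
        assert out.n_variants == 7

    def test_chromosome_must_match(self):
        cohort = make_cohort(np.zeros((1, 2), dtype=np.int8), chrom=["1", "2"],
                             pos=[100, 100])
        out = qc.exclude_regions(cohort, [("2", 1, 1000)])
        assert out.variants["chrom"].tolist() == ["1"]

    def test_bed_reader_converts_coordinates(self, tmp_path):
        bed = tmp_path / "regions.bed"
        bed.write_text("chr1\t99\t200\n# comment\n1\t0\t50\n")
        regions = qc.read_regions_bed(bed)
        assert regions == [("chr1", 100, 200), ("1", 1, 50)]


class TestLdR2:
    def test_self_correlation_is_one(self, rng):
        g = rng.integers(0, 3, size=50)
        assert qc.ld_r2(g, g) == pytest.approx(1.0)

    def test_perfect_negative_correlation(self, rng):
        g = rng.integers(0, 3, size=50)
        g[0], g[1] = 0, 2  # ensure non-constant
        assert qc.ld_r2(g, 2 - g) == pytest.approx(1.0)

    def test_constant_vector_returns_zero(self):
        assert qc.ld_r2(np.ones(10), np.arange(10) % 3) == 0.0

    def test_independent_vectors_near_null(self, rng):
        n = 10000
        g1 = rng.binomial(2, 0.5, size=n)
        g2 = rng.binomial(2, 0.5, size=n)
        assert qc.ld_r2(g1, g2) < 0.003  # null expectation ~ 1/n

    def test_too_few_complete_pairs(self):
        with pytest.raises(ValueError, match="complete"):
            qc.ld_r2(np.array([0, -1, -1]), np.array([-1, 1, 1]))


def brute_force_prune(calls, pos, maf, window_bp, threshold):
    """Exhaustive oracle: repeatedly drop the lower-MAF member of the
    worst in-window violating pair until no violation remains."""
    kept = list(range(calls.shape[1]))
    while True:
        violations = []
        for i, j in itertools.combinations(kept, 2):
            if abs(pos[j] - pos[i]) <= window_bp:
                r2 = qc.ld_r2(calls[:, i], calls[:, j])
                if r2 > threshold:
                    violations.append((i, j))
        if not violations:
            return kept
        i, j = violations[0]
        # same removal rule as the implementation
        if (maf[i], -pos[i]) < (maf[j], -pos[j]):
            kept.remove(i)
        else:
            kept.remove(j)


class TestLdPrune:
    def test_duplicate_snp_one_retained(self, rng):
        g = rng.binomial(2, 0.4, size=60).astype(np.int8)
        cohort = make_cohort(np.column_stack([g, g]), pos=[1000, 2000])
        kept = qc.ld_prune(cohort, qc.PruneParams())
        assert len(kept) == 1

    def test_independent_snps_all_retained(self, rng):
        calls = rng.binomial(2, 0.5, size=(500, 10)).astype(np.int8)
        cohort = make_cohort(calls, pos=[j * 1000 for j in range(1, 11)])
        kept = qc.ld_prune(cohort, qc.PruneParams(r2_threshold=0.05))
        assert len(kept) == 10

    def test_unsorted_input_rejected(self, rng):
        cohort = make_cohort(
            rng.integers(0, 3, size=(5, 2)).astype(np.int8), pos=[2000, 1000]
        )
        with pytest.raises(ValueError, match="sorted"):
            qc.ld_prune(cohort, qc.PruneParams())

    def test_matches_exhaustive_oracle(self, rng):
        # 20 SNPs with planted correlation blocks inside one window
        base = rng.binomial(2, 0.5, size=(200, 7)).astype(np.int8)
        cols = [base[:, i % 7].copy() for i in range(20)]
        for i in range(7, 20):  # noisy copies -> high r2 with their base
            flip = rng.random(200) < 0.05
            cols[i] = np.where(flip, 2 - cols[i], cols[i]).astype(np.int8)
        calls = np.column_stack(cols)
        pos = [1000 * (j + 1) for j in range(20)]
        cohort = make_cohort(calls, pos=pos)
        params = qc.PruneParams(window_kb=50, step_kb=10, r2_threshold=0.2)
        kept = qc.ld_prune(cohort, params)
        maf = qc.allele_frequency(cohort)["maf"].to_numpy()
        oracle = brute_force_prune(calls, np.array(pos), maf, 50_000, 0.2)
        assert sorted(kept) == sorted(np.array(cohort.variant_ids)[oracle])

    def test_post_prune_certificate(self, rng):
        base = rng.binomial(2, 0.5, size=(150, 30)).astype(np.int8)
        for j in range(1, 30, 3):
            base[:, j] = base[:, j - 1]
        cohort = make_cohort(base, pos=[500 * (j + 1) for j in range(30)])
        params = qc.PruneParams(r2_threshold=0.1)
        kept = qc.ld_prune(cohort, params)
        assert qc.prune_certificate(cohort, kept, params) <= 0.1 + 1e-12

    def test_idempotent(self, rng):
        calls = rng.binomial(2, 0.3, size=(100, 25)).astype(np.int8)
        calls[:, 5] = calls[:, 4]
        calls[:, 12] = calls[:, 11]
        cohort = make_cohort(calls, pos=[800 * (j + 1) for j in range(25)])
        params = qc.PruneParams(r2_threshold=0.1)
        kept = qc.ld_prune(cohort, params)
        again = qc.ld_prune(cohort.subset_variants(kept), params)
        assert again == kept

    def test_reference_subset_governs_r2(self, rng):
        # SNP pair correlated only within the reference samples
        g = rng.binomial(2, 0.5, size=100).astype(np.int8)
        noise = rng.binomial(2, 0.5, size=100).astype(np.int8)
        col2 = np.concatenate([g[:50], noise[50:]]).astype(np.int8)
        cohort = make_cohort(np.column_stack([g, col2]), pos=[1000, 2000])
        ref_ids = [f"s{i + 1}" for i in range(50)]
        kept_ref = qc.ld_prune(
            cohort, qc.PruneParams(r2_threshold=0.5, reference_sample_ids=ref_ids)
        )
        assert len(kept_ref) == 1
        kept_all = qc.ld_prune(cohort, qc.PruneParams(r2_threshold=0.5))
        assert len(kept_all) == 2

    def test_snp_count_window_mode(self, rng):
        g = rng.binomial(2, 0.4, size=80).astype(np.int8)
        # duplicates 100 kb apart: outside any kb window, inside SNP window
        cohort = make_cohort(np.column_stack([g, g]), pos=[1000, 101_000])
        kept_kb = qc.ld_prune(cohort, qc.PruneParams())
        assert len(kept_kb) == 2
        kept_ct = qc.ld_prune(
            cohort, qc.PruneParams(window_kb=5, step_kb=2, window_units="snps")
        )
        assert len(kept_ct) == 1

    def test_param_validation(self):
        with pytest.raises(ValueError, match="window_kb"):
            qc.PruneParams(window_kb=5, step_kb=10)
        with pytest.raises(ValueError, match="r2_threshold"):
            qc.PruneParams(r2_threshold=1.5)


def test_keep_list_round_trip(tmp_path):
    ids = ["rs1", "rs9", "rs4"]
    path = qc.write_keep_list(ids, tmp_path / "keep.txt")
    assert qc.read_keep_list(path) == ids


def test_bundled_high_ld_fixture_parses():
    from popstruct import example_fixture

    regions = qc.read_regions_bed(example_fixture("high_ld_regions_example.bed"))
    assert len(regions) == 10
    assert regions[0] == ("1", 48000001, 52000000)
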