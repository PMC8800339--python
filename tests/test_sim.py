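import numpy as np
import pytest

from popstruct import sim
from popstruct.fst import hudson_fst_from_freqs
from popstruct.relatedness import grm

BIG_N = 1e12  # effectively infinite diploids: kills the finite-sample correction


def spec_one_pop(n=10, n_snps=100, fs=0.0, fc=0.0, seed=0, **kw):
    return sim.PopulationSpec(
        continents=[sim.ContinentSpec("C1", fc, [sim.SubpopSpec("P1", fs, n)])],
        n_snps=n_snps,
        seed=seed,
        **kw,
    )


class TestFrequencyDraw:
    def test_zero_divergence_copies_ancestral_exactly(self):
        spec = spec_one_pop(fs=0.0, fc=0.0, n_snps=50, seed=1)
        freqs = sim.draw_hierarchical_frequencies(spec)
        assert np.array_equal(freqs.continent["C1"], freqs.ancestral)
        assert np.array_equal(freqs.subpop[("C1", "P1")], freqs.ancestral)

    def test_degenerate_maf_range_pins_ancestral(self):
        spec = spec_one_pop(n_snps=40, maf_range=(0.3, 0.3), seed=2)
        freqs = sim.draw_hierarchical_frequencies(spec)
        assert np.allclose(freqs.ancestral, 0.3)

    def test_divergence_one_rejected(self):
        spec = spec_one_pop(seed=3)
        spec.continents[0].fc = 1.0
        with pytest.raises(ValueError, match="F"):
            spec.validate()

    def test_latent_fst_matches_generating_f(self):
        # analytic: E[(p1-p2)^2] / E[p1(1-p2)+p2(1-p1)] = F for two
        # populations each at divergence F from a shared ancestor
        spec = sim.PopulationSpec(
            continents=[
                sim.ContinentSpec("A", 0.05, [sim.SubpopSpec("A1", 0.0, 2)]),
                sim.ContinentSpec("B", 0.05, [sim.SubpopSpec("B1", 0.0, 2)]),
            ],
            n_snps=20000,
            seed=4,
        )
        freqs = sim.draw_hierarchical_frequencies(spec)
        est = hudson_fst_from_freqs(
            freqs.continent["A"], BIG_N, freqs.continent["B"], BIG_N
        )
        assert abs(est - 0.05) < 0.01

    def test_frequencies_clamped(self):
        spec = spec_one_pop(fc=0.5, n_snps=5000, maf_range=(0.05, 0.5), seed=5)
        freqs = sim.draw_hierarchical_frequencies(spec)
        pc = freqs.continent["C1"]
        assert pc.min() >= 1e-6 and pc.max() <= 1 - 1e-6


class TestGenotypeSimulation:
    def test_sample_frequency_within_binomial_envelope(self):
        n, p = 5000, 0.25
        spec = spec_one_pop(n=n, n_snps=1, maf_range=(p, p), seed=6)
        cohort = sim.simulate_genotypes(sim.draw_hierarchical_frequencies(spec), spec)
        obs = cohort.genotypes.calls[:, 0].mean() / 2
        se = np.sqrt(p * (1 - p) / (2 * n))
        assert abs(obs - p) < 3 * se

    def test_pure_admixture_matches_single_population(self):
        # q = (1, 0): the mixture collapses onto continent 1's frequencies
        spec = sim.PopulationSpec(
            continents=[
                sim.ContinentSpec("A", 0.2, [sim.SubpopSpec("A1", 0.0, 0)]),
                sim.ContinentSpec("B", 0.2, [sim.SubpopSpec("B1", 0.0, 0)]),
            ],
            n_snps=2000,
            admixed_blocks=[sim.AdmixedBlock(n=300, alpha=[1e6, 1e-6])],
            seed=7,
        )
        freqs = sim.draw_hierarchical_frequencies(spec)
        cohort = sim.simulate_genotypes(freqs, spec)
        obs = cohort.genotypes.calls.mean(axis=0) / 2
        resid = obs - freqs.continent["A"]
        se = np.sqrt(freqs.continent["A"] * (1 - freqs.continent["A"]) / 600)
        assert (np.abs(resid) < 4 * se).mean() > 0.99

    def test_determinism_under_seed(self):
        spec = spec_one_pop(n=20, n_snps=200, fs=0.01, seed=8,
                            relative_pairs=3, label_concordance=0.8)
        a = sim.simulate(spec)
        b = sim.simulate(spec)
        assert a.genotypes.equals(b.genotypes)
        assert a.truth.equals(b.truth)
        assert a.relative_pairs == b.relative_pairs

    def test_truth_q_rows_sum_to_one(self):
        spec = sim.PopulationSpec(
            continents=[
                sim.ContinentSpec("A", 0.1, [sim.SubpopSpec("A1", 0.0, 10)]),
                sim.ContinentSpec("B", 0.1, [sim.SubpopSpec("B1", 0.0, 10)]),
            ],
            n_snps=50,
            admixed_blocks=[sim.AdmixedBlock(n=20, alpha=[0.5, 0.5])],
            relative_pairs=2,
            seed=9,
        )
        cohort = sim.simulate(spec)
        assert np.allclose(cohort.truth_q.sum(axis=1), 1.0, atol=1e-12)
        assert cohort.truth["id"].is_unique

    def test_realized_subpop_frequency_envelope(self):
        spec = spec_one_pop(n=400, n_snps=500, fs=0.02, seed=10)
        freqs = sim.draw_hierarchical_frequencies(spec)
        cohort = sim.simulate_genotypes(freqs, spec)
        pf = freqs.subpop[("C1", "P1")]
        obs = cohort.genotypes.calls.mean(axis=0) / 2
        se = np.sqrt(pf * (1 - pf) / 800)
        assert (np.abs(obs - pf) < 3 * se).mean() > 0.98

    def test_subpop_fst_recovers_generating_f(self):
        # module headline property: genotype-level Hudson Fst between
        # simulated subpopulations matches the latent-frequency oracle
        from popstruct.fst import pairwise_fst

        spec = sim.PopulationSpec(
            continents=[
                sim.ContinentSpec(
                    "C",
                    0.0,
                    [sim.SubpopSpec("P1", 0.05, 100), sim.SubpopSpec("P2", 0.05, 100)],
                )
            ],
            n_snps=20000,
            maf_range=(0.1, 0.5),
            seed=11,
        )
        freqs = sim.draw_hierarchical_frequencies(spec)
        cohort = sim.simulate_genotypes(freqs, spec)
        oracle = hudson_fst_from_freqs(
            freqs.subpop[("C", "P1")], BIG_N, freqs.subpop[("C", "P2")], BIG_N
        )
        group_of = {
            s: str(sp)
            for s, sp in zip(cohort.truth["id"], cohort.truth["subpop"])
        }
        est = pairwise_fst(cohort.genotypes, group_of).values[0, 1]
        assert abs(est - oracle) < 0.01
        # pairwise Fst of two pops each at F from the common ancestor is F
        assert abs(est - 0.05) < 0.01


@pytest.fixture(scope="module")
def trio_cohort():
    spec = spec_one_pop(n=100, n_snps=20000, maf_range=(0.1, 0.5), seed=12)
    cohort = sim.simulate_genotypes(sim.draw_hierarchical_frequencies(spec), spec)
    return sim.add_relatives(cohort, 4, np.random.default_rng(13))


class TestRelatives:

    def test_parent_offspring_grm_near_half(self, trio_cohort):
        matrix = grm(trio_cohort.genotypes, maf_floor=0.05)
        idx = {s: i for i, s in enumerate(trio_cohort.genotypes.sample_ids)}
        vals = [
            matrix.values[idx[a], idx[b]] for a, b in trio_cohort.relative_pairs
        ]
        assert abs(np.mean(vals) - 0.5) < 0.05

    def test_mendelian_constraint_hom_ref_parents(self, trio_cohort):
        calls = trio_cohort.genotypes.calls
        idx = {s: i for i, s in enumerate(trio_cohort.genotypes.sample_ids)}
        # pair entries arrive as (parent1, child), (parent2, child)
        pairs = trio_cohort.relative_pairs
        for k in range(0, len(pairs), 2):
            p1, child = pairs[k]
            p2, _ = pairs[k + 1]
            both_ref = (calls[idx[p1]] == 0) & (calls[idx[p2]] == 0)
            assert (calls[idx[child]][both_ref] == 0).all()
            both_alt = (calls[idx[p1]] == 2) & (calls[idx[p2]] == 2)
            assert (calls[idx[child]][both_alt] == 2).all()

    def test_zero_pairs_is_identity(self):
        spec = spec_one_pop(n=5, n_snps=20, seed=14)
        cohort = sim.simulate_genotypes(
            sim.draw_hierarchical_frequencies(spec), spec
        )
        out = sim.add_relatives(cohort, 0)
        assert out is cohort

    def test_insufficient_founders_rejected(self):
        spec = spec_one_pop(n=2, n_snps=10, seed=15)
        cohort = sim.simulate_genotypes(
            sim.draw_hierarchical_frequencies(spec), spec
        )
        with pytest.raises(ValueError, match="founders"):
            sim.add_relatives(cohort, 5, np.random.default_rng(0))


class TestBirthLabels:
    def two_pop_spec(self, concordance, missing=0.0, n=100, seed=16):
        return sim.PopulationSpec(
            continents=[
                sim.ContinentSpec(
                    "C",
                    0.0,
                    [
                        sim.SubpopSpec("P1", 0.0, n, region="R1", countries={"c1": 1}),
                        sim.SubpopSpec("P2", 0.0, n, region="R2", countries={"c2": 1}),
                    ],
                )
            ],
            n_snps=10,
            label_concordance=concordance,
            missing_label_fraction=missing,
            seed=seed,
        )

    def test_full_concordance_is_block_diagonal(self):
        cohort = sim.simulate(self.two_pop_spec(1.0))
        t = cohort.truth
        for sp, region in (("P1", "R1"), ("P2", "R2")):
            assert (t.loc[t["subpop"] == sp, "region"] == region).all()

    def test_partial_concordance_within_binomial_envelope(self):
        spec = self.two_pop_spec(0.8, n=500, seed=17)
        cohort = sim.simulate(spec)
        t = cohort.truth
        own = {"P1": "R1", "P2": "R2"}
        match = [
            own[sp] == r for sp, r in zip(t["subpop"], t["region"])
        ]
        obs = np.mean(match)
        se = np.sqrt(0.8 * 0.2 / len(match))
        assert abs(obs - 0.8) < 3 * se

    def test_all_missing_labels_refused_downstream(self):
        from popstruct.ca import build_contingency

        cohort = sim.simulate(self.two_pop_spec(1.0, missing=1.0, n=20, seed=18))
        assert cohort.truth["region"].isna().all()
        with pytest.raises(ValueError):
            build_contingency(
                cohort.truth["subpop"], cohort.truth["region"], min_count=1
            )


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        text = """
continents:
  - name: A
    fc: 0.1
    subpops:
      - {name: A1, fs: 0.005, n: 10, region: R1, countries: {x: 0.5, y: 0.5}}
      - {name: A_REF, fs: 0.001, n: 5, is_reference: true}
  - name: B
    fc: 0.1
    subpops:
      - {name: B1, fs: 0.01, n: 10, region: R2}
n_snps: 100
maf_range: [0.1, 0.5]
admixed_blocks:
  - {n: 4, alpha: [0.3, 0.3]}
relative_pairs: 1
label_concordance: 0.9
seed: 42
"""
        path = tmp_path / "spec.yaml"
        path.write_text(text)
        spec = sim.PopulationSpec.from_yaml(path)
        assert spec.continent_names == ["A", "B"]
        assert spec.continents[0].subpops[1].is_reference
        assert spec.admixed_blocks[0].alpha == [0.3, 0.3]
        cohort = sim.simulate(spec)
        assert cohort.genotypes.n_samples == 30

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="maf_range"):
            spec_one_pop(maf_range=(0.0, 0.5)).validate()
        with pytest.raises(ValueError, match="label_concordance"):
            spec_one_pop(label_concordance=1.5).validate()
        bad = spec_one_pop()
        bad.admixed_blocks = [sim.AdmixedBlock(n=1, alpha=[0.5, 0.5])]
        with pytest.raises(ValueError, match="alpha"):
            bad.validate()


def test_ld_block_mode_creates_correlated_duplicates():
    from popstruct.qc import ld_r2

    spec = spec_one_pop(
        n=200, n_snps=50, seed=19, ld_block=sim.LDBlockSpec(n_tagged=50, eps=0.01)
    )
    cohort = sim.simulate(spec)
    gm = cohort.genotypes
    assert gm.n_variants == 100
    vids = gm.variant_ids
    for base in ["rs1", "rs20"]:
        j0, j1 = vids.index(base), vids.index(f"{base}_tag")
        assert ld_r2(gm.calls[:, j0], gm.calls[:, j1]) > 0.9
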