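import numpy as np
import pytest

from popstruct import pca, sim

from conftest import make_cohort


def two_pop_cohort(fs=0.01, n=100, n_snps=5000, seed=40, extra=None):
    subpops = [sim.SubpopSpec("P1", fs, n), sim.SubpopSpec("P2", fs, n)]
    if extra:
        subpops.append(extra)
    spec = sim.PopulationSpec(
        continents=[sim.ContinentSpec("C", 0.0, subpops)],
        n_snps=n_snps,
        maf_range=(0.1, 0.5),
        seed=seed,
    )
    return sim.simulate_genotypes(sim.draw_hierarchical_frequencies(spec), spec)


class TestPattersonNormalize:
    def test_hand_normalized_toy_matrix(self):
        # 4 samples x 3 variants normalized by hand:
        # col means mu = (1, 0.5, 1.5); p = mu/2; scale = sqrt(p(1-p))
        calls = [[0, 0, 2], [1, 1, 1], [2, 0, 2], [1, 1, 1]]
        cohort = make_cohort(calls)
        x, norm = pca.patterson_normalize(cohort)
        mu = np.array([1.0, 0.5, 1.5])
        scale = np.sqrt((mu / 2) * (1 - mu / 2))
        expected = (np.array(calls, float) - mu) / scale
        assert np.allclose(x, expected)
        assert np.allclose(norm.mean, mu)

    def test_monomorphic_dropped(self):
        cohort = make_cohort([[0, 1], [0, 1], [0, 2]])
        x, norm = pca.patterson_normalize(cohort)
        assert x.shape[1] == 1
        assert norm.variant_ids == ["rs2"]

    def test_fit_columns_centered(self, rng):
        calls = rng.choice([0, 1, 2], size=(30, 50)).astype(np.int8)
        cohort = make_cohort(calls)
        x, _ = pca.patterson_normalize(cohort)
        assert np.allclose(x.mean(axis=0), 0.0, atol=1e-12)

    def test_missing_becomes_zero_after_centering(self):
        cohort = make_cohort([[0], [2], [-1]])
        x, _ = pca.patterson_normalize(cohort)
        assert x[2, 0] == 0.0

    def test_all_monomorphic_rejected(self):
        cohort = make_cohort([[1, 1], [1, 1]])
        # constant-het columns have mu=1 -> p=0.5: polymorphic by the rule;
        # truly fixed columns must fail
        cohort2 = make_cohort([[0, 2], [0, 2]])
        with pytest.raises(ValueError, match="monomorphic"):
            pca.patterson_normalize(cohort2)


class TestFitPcs:
    def test_two_population_structure_detected(self):
        cohort = two_pop_cohort(fs=0.005, n=100, n_snps=5000)
        model = pca.fit_pcs(cohort.genotypes, n_pcs=5)
        ind = np.array(
            [1.0 if s.startswith("P1") else 0.0 for s in model.fit_sample_ids]
        )
        assert abs(np.corrcoef(model.fit_scores[:, 0], ind)[0, 1]) > 0.9

    def test_eigenvalues_match_score_variance(self):
        cohort = two_pop_cohort(n=50, n_snps=800, seed=41)
        model = pca.fit_pcs(cohort.genotypes, n_pcs=10)
        assert np.allclose(
            model.fit_scores.var(axis=0, ddof=1), model.eigenvalues, rtol=1e-8
        )

    def test_loadings_orthonormal_scores_orthogonal(self):
        cohort = two_pop_cohort(n=40, n_snps=600, seed=42)
        model = pca.fit_pcs(cohort.genotypes, n_pcs=8)
        gram = model.loadings.T @ model.loadings
        assert np.allclose(gram, np.eye(8), atol=1e-8)
        cross = model.fit_scores.T @ model.fit_scores
        off = cross - np.diag(np.diag(cross))
        assert np.abs(off).max() < 1e-6 * np.abs(np.diag(cross)).max()

    def test_eigenvalues_descending_nonnegative(self):
        cohort = two_pop_cohort(n=30, n_snps=400, seed=43)
        model = pca.fit_pcs(cohort.genotypes, n_pcs=6)
        assert (np.diff(model.eigenvalues) <= 1e-12).all()
        assert (model.eigenvalues >= 0).all()

    def test_rank_deficient_warns_and_truncates(self, rng):
        calls = rng.choice([0, 1, 2], size=(4, 100)).astype(np.int8)
        cohort = make_cohort(calls)
        with pytest.warns(UserWarning, match="rank"):
            model = pca.fit_pcs(cohort, n_pcs=10)
        assert len(model.eigenvalues) == 3

    def test_deterministic_sign_convention(self):
        cohort = two_pop_cohort(n=30, n_snps=400, seed=44)
        m1 = pca.fit_pcs(cohort.genotypes, n_pcs=4)
        m2 = pca.fit_pcs(cohort.genotypes, n_pcs=4)
        assert np.array_equal(m1.fit_scores, m2.fit_scores)
        for p in range(4):
            col = m1.loadings[:, p]
            assert col[np.abs(col).argmax()] > 0

    def test_leading_eigenvalue_grows_with_fst(self):
        seps = []
        for fs in (0.0, 0.005, 0.02):
            cohort = two_pop_cohort(fs=fs, n=60, n_snps=3000, seed=45)
            model = pca.fit_pcs(cohort.genotypes, n_pcs=10)
            seps.append(model.eigenvalues[0] / model.eigenvalues[1:].mean())
        assert seps[0] < seps[1] < seps[2]


class TestProject:
    def test_projecting_fit_sample_reproduces_score(self):
        cohort = two_pop_cohort(n=40, n_snps=600, seed=46)
        model = pca.fit_pcs(cohort.genotypes, n_pcs=5)
        scores = pca.project(cohort.genotypes, model, model.fit_sample_ids[:3])
        assert np.allclose(scores, model.fit_scores[:3], atol=1e-8)

    def test_mean_genotype_projects_to_origin(self):
        cohort = two_pop_cohort(n=30, n_snps=400, seed=47)
        model = pca.fit_pcs(cohort.genotypes, n_pcs=4)
        # a synthetic sample whose normalized row is exactly zero:
        # missing everywhere -> centered to 0 -> score 0
        from popstruct.cohort import GenotypeMatrix
        import pandas as pd

        gm = cohort.genotypes
        blank = GenotypeMatrix(
            samples=pd.DataFrame({"id": ["blank"]}),
            variants=gm.variants,
            calls=np.full((1, gm.n_variants), -1, dtype=np.int8),
        )
        scores = pca.project(blank, model)
        assert np.allclose(scores, 0.0)

    def test_cognate_group_lands_in_cluster(self):
        # hold out 30 P1 samples; they must project onto the P1 cluster
        cohort = two_pop_cohort(fs=0.01, n=130, n_snps=5000, seed=48)
        gm = cohort.genotypes
        p1_ids = [s for s in gm.sample_ids if s.startswith("P1")]
        held_out = p1_ids[100:]
        fit_ids = [s for s in gm.sample_ids if s not in set(held_out)]
        model = pca.fit_pcs(gm, fit_sample_ids=fit_ids, n_pcs=2)
        proj = pca.project(gm, model, held_out)
        p1 = np.array([s.startswith("P1") for s in model.fit_sample_ids])
        centroid = model.fit_scores[p1, 0].mean()
        spread = model.fit_scores[p1, 0].std(ddof=1)
        # projection shrinkage pulls scores toward 0, so allow 2 SD around
        # the segment between origin-side and the cognate centroid
        assert abs(proj[:, 0].mean()) < abs(centroid) + 2 * spread
        assert np.sign(proj[:, 0].mean()) == np.sign(centroid)
        other = model.fit_scores[~p1, 0].mean()
        assert abs(proj[:, 0].mean() - centroid) < abs(proj[:, 0].mean() - other)


class TestRemoveOutliers:
    def test_homogeneous_cohort_no_outliers(self):
        cohort = two_pop_cohort(fs=0.0, n=100, n_snps=2000, seed=49)
        model = pca.remove_outliers(cohort.genotypes, n_pcs=15)
        assert model.outliers == []
        assert len(model.outliers_per_iteration) == 0

    def test_planted_outliers_flagged(self):
        spec = sim.PopulationSpec(
            continents=[
                sim.ContinentSpec("C", 0.0, [sim.SubpopSpec("MAIN", 0.0, 300)]),
                sim.ContinentSpec("O", 0.3, [sim.SubpopSpec("OUT", 0.0, 5)]),
            ],
            n_snps=3000,
            maf_range=(0.1, 0.5),
            seed=50,
        )
        cohort = sim.simulate_genotypes(sim.draw_hierarchical_frequencies(spec), spec)
        model = pca.remove_outliers(cohort.genotypes, n_pcs=15)
        assert sorted(model.outliers) == sorted(
            s for s in cohort.genotypes.sample_ids if s.startswith("OUT")
        )
        assert len(model.outliers_per_iteration) <= 2

    def test_infinite_sigma_is_identity(self):
        cohort = two_pop_cohort(n=30, n_snps=500, seed=51)
        model = pca.remove_outliers(cohort.genotypes, sigma=np.inf, n_pcs=5)
        assert model.outliers == []
        assert len(model.fit_sample_ids) == cohort.genotypes.n_samples

    def test_fixed_point_on_clean_data(self):
        cohort = two_pop_cohort(fs=0.0, n=80, n_snps=1000, seed=52)
        model = pca.remove_outliers(cohort.genotypes, n_pcs=10)
        again = pca.remove_outliers(
            cohort.genotypes, fit_sample_ids=model.fit_sample_ids, n_pcs=10
        )
        assert again.outliers == []


class TestVarianceExplained:
    def test_fractions_sum_to_one(self):
        cohort = two_pop_cohort(n=30, n_snps=400, seed=53)
        model = pca.fit_pcs(cohort.genotypes, n_pcs=6)
        assert pca.variance_explained(model).sum() == pytest.approx(1.0)

    def test_toy_spectrum(self):
        model = pca.PCAModel(
            eigenvalues=np.array([4.0, 3.0, 2.0, 1.0]),
            loadings=np.eye(4),
            fit_sample_ids=[],
            fit_scores=np.empty((0, 4)),
            normalization=None,
        )
        assert np.allclose(pca.variance_explained(model), [0.4, 0.3, 0.2, 0.1])


class TestSelectTopPcs:
    def test_second_difference_elbow(self):
        assert pca.select_top_pcs([0.5, 0.3, 0.05, 0.05, 0.05, 0.05]) == 2

    def test_flat_spectrum_defaults_to_two_with_warning(self):
        with pytest.warns(UserWarning, match="flat"):
            assert pca.select_top_pcs([0.25, 0.25, 0.25, 0.25]) == 2

    def test_override_wins(self):
        assert pca.select_top_pcs([0.5, 0.3, 0.05, 0.05, 0.05], override=4) == 4

    def test_too_few_pcs_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            pca.select_top_pcs([0.6, 0.4])


def test_scores_and_eigenvalue_output(tmp_path):
    cohort = two_pop_cohort(n=20, n_snps=300, seed=54)
    model = pca.fit_pcs(cohort.genotypes, n_pcs=3)
    pca.attach_projection(cohort.genotypes, model, model.fit_sample_ids[:2])
    spath = pca.write_scores(model, tmp_path / "scores.tsv")
    import pandas as pd

    df = pd.read_csv(spath, sep="\t")
    assert list(df.columns) == ["id", "PC1", "PC2", "PC3", "label"]
    assert (df["label"] == "projected").sum() == 2
    epath = pca.write_eigenvalues(model, tmp_path / "eval.txt")
    vals = [float(x) for x in epath.read_text().split()]
    assert np.allclose(vals, model.eigenvalues)
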