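"""PCA assignment: reference fitting, projection/assignment, frequency-matrix PCA."""

import numpy as np
import pandas as pd
import pytest

from bgakit import (
    SimConfig,
    apply_frequency_floor,
    fit_reference_pca,
    population_frequency_pca,
    project_and_assign,
    simulate_individuals,
    simulate_panel,
)
from bgakit.zscore import genotype_codes


@pytest.fixture(scope="module")
def two_pop_model():
    panel, _ = simulate_panel(SimConfig(seed=14, fst=0.2, n_populations=2))
    panel = apply_frequency_floor(panel)
    rows, labels = [], []
    for k, pop in enumerate(panel.population_names):
        for g in simulate_individuals(panel, pop, 60, seed=20 + k):
            rows.append(genotype_codes(g, panel, panel.locus_ids))
            labels.append(panel.metapopulation_of(pop))
    X = np.vstack(rows)
    model = fit_reference_pca(X, labels, loci=panel.locus_ids)
    return panel, X, labels, model


class TestFit:
    def test_pc1_separates_populations(self, two_pop_model):
        _, _, _, model = two_pop_model
        (c1, cov1), (c2, cov2) = model.clusters.values()
        gap = abs(c1[0] - c2[0])
        spread = max(np.sqrt(cov1[0, 0]), np.sqrt(cov2[0, 0]))
        assert gap > 3 * spread

    def test_training_self_consistency(self, two_pop_model):
        _, X, labels, model = two_pop_model
        correct = 0
        for row, lab in zip(X, labels):
            r = project_and_assign(model, row)
            if r.decision.status == "predicted" and r.decision.label == lab:
                correct += 1
        assert correct / len(labels) > 0.8

    def test_duplicate_individuals_identical_projection(self, two_pop_model):
        _, X, _, model = two_pop_model
        a = model.transform(X[0])
        b = model.transform(X[0].copy())
        np.testing.assert_array_equal(a, b)

    def test_needs_multiple_clusters(self):
        X = np.random.default_rng(0).integers(0, 3, (10, 5)).astype(float)
        with pytest.raises(ValueError, match="clusters"):
            fit_reference_pca(X, ["A"] * 10)

    def test_loadings_orthonormal(self, two_pop_model):
        _, _, _, model = two_pop_model
        G = model.loadings @ model.loadings.T
        np.testing.assert_allclose(G, np.eye(2), atol=1e-10)


class TestAssign:
    def test_cluster_mean_is_centroid_distance_zero(self, two_pop_model):
        """The mean code vector of a cluster projects exactly onto its centroid."""
        _, X, labels, model = two_pop_model
        lab = labels[0]
        members = X[np.array(labels) == lab]
        mean_codes = members.mean(axis=0)
        r = project_and_assign(model, mean_codes)
        assert r.mahalanobis_sq[lab] == pytest.approx(0.0, abs=1e-16)
        assert r.decision.status == "predicted" and r.decision.label == lab

    def test_unknown_from_source_population_assigned(self, two_pop_model):
        panel, _, _, model = two_pop_model
        profs = simulate_individuals(panel, "POP1", 40, seed=31)
        hits = 0
        for g in profs:
            r = project_and_assign(model, g, panel=panel)
            if r.decision.status == "predicted" and r.decision.label == "META1":
                hits += 1
        assert hits > 30

    def test_admixed_unknowns_mostly_inconclusive(self, two_pop_model):
        panel, _, _, model = two_pop_model
        adm = simulate_individuals(panel, "POP1", 40, seed=32,
                                   admixed_pair=("POP1", "POP2"))
        inconclusive = sum(
            project_and_assign(model, g, panel=panel).decision.status == "inconclusive"
            for g in adm
        )
        assert inconclusive > 20

    def test_admixed_reference_cluster_never_predicted(self, two_pop_model):
        _, X, labels, model = two_pop_model
        lab = labels[0]
        model2 = fit_reference_pca(X, labels, loci=model.loci, admixed_labels=[lab])
        members = X[np.array(labels) == lab]
        r = project_and_assign(model2, members.mean(axis=0))
        assert r.decision.status == "inconclusive"

    def test_fully_missing_profile_errors_and_lands_at_origin(self, two_pop_model):
        _, _, _, model = two_pop_model
        empty = np.full(len(model.loci), np.nan)
        with pytest.raises(ValueError, match="missing"):
            project_and_assign(model, empty)
        # mean imputation of an all-missing row is the global centroid (origin)
        np.testing.assert_allclose(model.transform(empty)[0], [0.0, 0.0], atol=1e-12)

    def test_locus_permutation_invariance(self, two_pop_model):
        """Refitting on column-permuted training data projects unknowns identically."""
        panel, X, labels, model = two_pop_model
        perm = np.random.default_rng(1).permutation(X.shape[1])
        model_p = fit_reference_pca(
            X[:, perm], labels, loci=[model.loci[i] for i in perm]
        )
        g = simulate_individuals(panel, "POP2", 1, seed=33)[0]
        codes = genotype_codes(g, panel, model.loci)
        c1 = model.transform(codes)[0]
        c2 = model_p.transform(codes[perm])[0]
        np.testing.assert_allclose(c1, c2, atol=1e-8)


class TestFrequencyPca:
    def test_collinear_populations_rank_one(self):
        rng = np.random.default_rng(7)
        base = rng.uniform(0.2, 0.7, 30)
        freq = pd.DataFrame(
            [base, base + 0.05, base + 0.10],
            index=["P1", "P2", "P3"],
        )
        coords = population_frequency_pca(freq)
        assert coords["PC2"].var() == pytest.approx(0.0, abs=1e-12)

    def test_duplicate_rows_identical_coordinates(self):
        rng = np.random.default_rng(8)
        base = rng.uniform(0.2, 0.8, 20)
        freq = pd.DataFrame([base, base, rng.uniform(0.2, 0.8, 20)],
                            index=["A", "A2", "B"])
        coords = population_frequency_pca(freq)
        np.testing.assert_allclose(coords.loc["A"], coords.loc["A2"], atol=1e-12)

    def test_too_few_populations(self):
        with pytest.raises(ValueError, match=">= 3"):
            population_frequency_pca(np.array([[0.1, 0.2], [0.3, 0.4]]))

    def test_outlier_population_farthest_on_pc1(self):
        """A high-divergence population separates from the rest on PC1."""
        cfg = SimConfig(seed=9, n_populations=6, fst=(0.02, 0.02, 0.02, 0.02, 0.02, 0.5),
                        n_loci=56)
        panel, _ = simulate_panel(cfg)
        coords = population_frequency_pca(panel.freq)
        dist = (coords - coords.mean()).pow(2).sum(axis=1).pow(0.5)
        assert dist.idxmax() == "POP6"

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(10)
        freq = rng.uniform(0.1, 0.9, (5, 12))
        c1 = population_frequency_pca(freq)
        c2 = population_frequency_pca(freq.copy())
        pd.testing.assert_frame_equal(c1, c2)
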