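"""Ancestry coordinate system: PCA projection, classical MDS, Procrustes
alignment and genetic distance."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ortho_group, spearmanr

from prsport.data import GenotypePanel
from prsport.geodist import (AncestrySpace, ReferencePCA, apply_procrustes,
                             binned_accuracy_profile, build_ancestry_space,
                             genetic_distance, map_gwas_points, mds_from_freqs,
                             procrustes_fit, project_pcs)
from prsport.synthio import PopulationSpec, simulate_admixture_gradient, simulate_genotypes


def _three_pop_reference(n_per=150, m=400, seed=31):
    rng = np.random.default_rng(seed)
    base = rng.uniform(0.25, 0.75, m)
    panels = []
    freqs = {}
    for i, lab in enumerate(["A", "B", "C"]):
        shift = rng.choice([-1.0, 0.0, 1.0], m) * 0.2 * (i > 0) * rng.uniform(0.5, 1, m)
        p = np.clip(base + shift + (0.15 if lab == "C" else 0), 0.05, 0.95)
        freqs[lab] = p
        spec = PopulationSpec(lab, n_per, [1] * m, p, 0.0)
        panels.append(simulate_genotypes(spec, seed + i))
    ref = GenotypePanel(
        dosages=np.vstack([p.dosages for p in panels]),
        variants=panels[0].variants,
        samples=pd.concat([p.samples for p in panels], ignore_index=True))
    return ref, freqs


class TestProjection:
    def test_self_projection_close_to_reference_coordinates(self):
        # a study sample duplicating a reference sample should land near
        # that sample's PC position; the augmented-spectrum adjustment
        # leaves an O(1/n_ref) residual
        ref, _ = _three_pop_reference()
        pca = ReferencePCA(ref, k=2)
        dup = ref.subset_samples([0, 150, 300])
        proj = pca.project_oadp(dup)
        tgt = pca.scores[[0, 150, 300]]
        rel = np.linalg.norm(proj - tgt, axis=1) / np.linalg.norm(tgt, axis=1)
        assert rel.max() < 0.12

    def test_naive_projection_exact_for_reference_samples(self):
        ref, _ = _three_pop_reference()
        pca = ReferencePCA(ref, k=2)
        dup = ref.subset_samples([5, 200])
        assert np.allclose(pca.project_naive(dup), pca.scores[[5, 200]], atol=1e-8)

    def test_external_samples_shrunk_under_naive_projection(self):
        ref, freqs = _three_pop_reference()
        spec = PopulationSpec("A", 40, [1] * 400, freqs["A"], 0.0)
        study = simulate_genotypes(spec, 99)
        pca = ReferencePCA(ref, k=2)
        naive = pca.project_naive(study)
        oadp = pca.project_oadp(study)
        ratio = np.linalg.norm(naive, axis=1) / np.linalg.norm(oadp, axis=1)
        assert ratio.mean() < 1.0

    def test_admixture_gradient_monotone_on_pc1(self):
        rng = np.random.default_rng(7)
        m = 500
        pA = rng.uniform(0.2, 0.8, m)
        pB = np.clip(pA + rng.choice([-1.0, 1.0], m) * 0.2, 0.05, 0.95)
        sA = PopulationSpec("A", 150, [1] * m, pA, 0.0)
        sB = PopulationSpec("B", 150, [1] * m, pB, 0.0)
        ref = GenotypePanel(
            dosages=np.vstack([simulate_genotypes(sA, 1).dosages,
                               simulate_genotypes(sB, 2).dosages]),
            variants=simulate_genotypes(sA, 1).variants,
            samples=pd.DataFrame({"sample_id": [f"r{i}" for i in range(300)],
                                  "population": ["A"] * 150 + ["B"] * 150}))
        study = simulate_admixture_gradient(sA, sB, 400, 3)
        coords = project_pcs(study, ref, k=2, method="oadp")
        alpha = study.samples["admixture"].to_numpy()
        rho = spearmanr(alpha, coords[:, 0]).statistic
        assert abs(rho) > 0.9

    def test_k_beyond_rank_rejected(self, small_panel):
        with pytest.raises(ValueError):
            ReferencePCA(small_panel.subset_samples(np.arange(5)), k=10)


class TestMDS:
    def test_exact_three_dimensional_embedding(self):
        # 4 populations differing only in 3 frequency coordinates: the MDS
        # configuration is exactly 3-D and distances are reproduced
        base = np.full(50, 0.5)
        rows = []
        pts = np.array([[0.0, 0, 0], [0.2, 0, 0], [0, 0.15, 0.1], [0.1, 0.1, 0.2]])
        for pt in pts:
            r = base.copy()
            r[:3] = 0.4 + pt
            rows.append(r)
        F = np.vstack(rows)
        X = mds_from_freqs(F, k=3)
        from scipy.spatial.distance import cdist

        assert np.allclose(cdist(X, X), cdist(F, F), atol=1e-10)

    def test_identical_rows_embed_at_zero_distance(self):
        F = np.vstack([np.linspace(0.2, 0.8, 30)] * 2
                      + [np.linspace(0.8, 0.2, 30)] * 2)
        X = mds_from_freqs(F, k=2)
        assert np.linalg.norm(X[0] - X[1]) < 1e-6

    def test_matches_pcoa_oracle(self):
        # scikit-bio's principal coordinates analysis as independent oracle
        from scipy.spatial.distance import cdist
        from skbio.stats.ordination import pcoa

        rng = np.random.default_rng(17)
        F = rng.uniform(0.1, 0.9, (6, 100))
        X = mds_from_freqs(F, k=3)
        res = pcoa(cdist(F, F), number_of_dimensions=3)
        Y = res.samples.to_numpy()
        for d in range(3):
            assert (np.allclose(X[:, d], Y[:, d], atol=1e-8)
                    or np.allclose(X[:, d], -Y[:, d], atol=1e-8))

    def test_too_few_populations_rejected(self):
        with pytest.raises(ValueError):
            mds_from_freqs(np.random.default_rng(0).uniform(0.2, 0.8, (3, 20)), k=5)


class TestProcrustes:
    def test_identity_configuration(self):
        X = np.random.default_rng(2).normal(size=(6, 5))
        s, R, t = procrustes_fit(X, X)
        assert s == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(R, np.eye(5), atol=1e-10)
        assert np.allclose(t, 0.0, atol=1e-10)

    def test_recovers_known_transform(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 5))
        R_true = ortho_group.rvs(5, random_state=4)
        s_true, t_true = 2.7, rng.normal(size=5)
        Y = s_true * X @ R_true + t_true
        s, R, t = procrustes_fit(X, Y)
        assert s == pytest.approx(s_true, rel=1e-8)
        assert np.allclose(R, R_true, atol=1e-8)
        assert np.allclose(t, t_true, atol=1e-8)
        assert np.allclose(apply_procrustes(X, s, R, t), Y, atol=1e-8)

    def test_reflection_allowed_beats_rotation_only(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(7, 3))
        F = np.diag([1.0, 1.0, -1.0])  # reflection
        Y = X @ F
        s, R, t = procrustes_fit(X, Y, allow_reflection=True)
        assert np.linalg.det(R) < 0
        assert np.allclose(apply_procrustes(X, s, R, t), Y, atol=1e-10)
        s2, R2, t2 = procrustes_fit(X, Y, allow_reflection=False)
        err2 = np.sum((apply_procrustes(X, s2, R2, t2) - Y) ** 2)
        assert np.linalg.det(R2) > 0 and err2 > 1e-6

    def test_orthogonality_of_fitted_rotation(self):
        rng = np.random.default_rng(6)
        s, R, t = procrustes_fit(rng.normal(size=(9, 5)), rng.normal(size=(9, 5)))
        assert np.allclose(R.T @ R, np.eye(5), atol=1e-8)

    def test_degenerate_source_rejected(self):
        with pytest.raises(ValueError):
            procrustes_fit(np.ones((4, 3)), np.random.default_rng(0).normal(size=(4, 3)))


class TestMapping:
    def _space(self, seed=0, k=3):
        rng = np.random.default_rng(seed)
        mds = pd.DataFrame(rng.normal(size=(6, k)),
                           index=["A", "B", "C", "D", "gwas1", "gwas2"])
        centroids = pd.DataFrame(
            2.0 * mds.loc[["A", "B", "C", "D"]].to_numpy() @ ortho_group.rvs(k, random_state=1)
            + rng.normal(size=k),
            index=["A", "B", "C", "D"])
        return AncestrySpace(pc_coords=rng.normal(size=(10, k)),
                             ref_centroids=centroids, mds_coords=mds)

    def test_duplicate_gwas_row_maps_identically(self):
        space = self._space()
        space.mds_coords.loc["gwas2"] = space.mds_coords.loc["A"]
        mapped = map_gwas_points(space)
        assert np.allclose(mapped.loc["gwas2"], mapped.loc["A"])

    def test_reference_rows_recover_centroids_under_exact_transform(self):
        space = self._space()
        mapped = map_gwas_points(space)
        assert space.fit_residual == pytest.approx(0.0, abs=1e-16)
        assert np.allclose(mapped.loc[["A", "B", "C", "D"]],
                           space.ref_centroids.to_numpy(), atol=1e-10)

    def test_distance_ratios_preserved_up_to_scale(self):
        space = self._space(seed=8)
        mapped = map_gwas_points(space).to_numpy()
        src = space.mds_coords.to_numpy()
        from scipy.spatial.distance import cdist

        D0, D1 = cdist(src, src), cdist(mapped, mapped)
        mask = D0 > 0
        ratios = D1[mask] / D0[mask]
        assert np.allclose(ratios, space.scale, rtol=1e-8)

    def test_unfitted_space_flag(self):
        space = self._space()
        assert not space.fitted
        map_gwas_points(space)
        assert space.fitted


class TestGeneticDistance:
    def test_zero_at_gwas_point(self):
        g = np.array([1.0, 2, 3, 4, 5])
        assert genetic_distance(g[None, :], g)[0] == 0.0

    def test_three_four_five(self):
        p = np.zeros((1, 5))
        g = np.array([3.0, 4.0, 0, 0, 0])
        assert genetic_distance(p, g)[0] == pytest.approx(5.0)

    def test_matches_coordinate_loop_oracle(self):
        rng = np.random.default_rng(9)
        P = rng.normal(size=(20, 5))
        g = rng.normal(size=5)
        expected = [np.sqrt(sum((P[i, d] - g[d]) ** 2 for d in range(5)))
                    for i in range(20)]
        assert np.allclose(genetic_distance(P, g), expected)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            genetic_distance(np.zeros((3, 5)), np.zeros(4))

    def test_invariant_to_global_rotation(self):
        # rotating the PC space (coords and centroids together) leaves all
        # genetic distances unchanged
        rng = np.random.default_rng(10)
        k = 4
        mds = pd.DataFrame(rng.normal(size=(6, k)),
                           index=["A", "B", "C", "D", "E", "gwas"])
        centroids = pd.DataFrame(rng.normal(size=(5, k)),
                                 index=["A", "B", "C", "D", "E"])
        pcs = rng.normal(size=(50, k))
        space = AncestrySpace(pc_coords=pcs, ref_centroids=centroids.copy(),
                              mds_coords=mds.copy())
        gd0 = genetic_distance(pcs, map_gwas_points(space).loc["gwas"].to_numpy())
        Q = ortho_group.rvs(k, random_state=11)
        space_rot = AncestrySpace(pc_coords=pcs @ Q,
                                  ref_centroids=pd.DataFrame(centroids.to_numpy() @ Q,
                                                             index=centroids.index),
                                  mds_coords=mds.copy())
        gd1 = genetic_distance(pcs @ Q, map_gwas_points(space_rot).loc["gwas"].to_numpy())
        assert np.allclose(gd0, gd1, atol=1e-8)


class TestProfile:
    def test_degenerate_binning_rejected(self):
        rng = np.random.default_rng(12)
        n = 30
        with pytest.raises(ValueError):
            binned_accuracy_profile(rng.uniform(size=n), rng.normal(size=n),
                                    rng.normal(size=n), n_bins=n)

    def test_too_few_bins_rejected(self):
        rng = np.random.default_rng(13)
        with pytest.raises(ValueError):
            binned_accuracy_profile(rng.uniform(size=100), rng.normal(size=100),
                                    rng.normal(size=100), n_bins=2)

    def test_bins_equal_sized_and_means_nondecreasing(self):
        rng = np.random.default_rng(14)
        n = 503
        gd = rng.uniform(size=n)
        y = rng.normal(size=n)
        prs = 0.5 * y + rng.normal(size=n)
        prof = binned_accuracy_profile(gd, y, prs, n_bins=10)
        assert prof.bin_n.max() - prof.bin_n.min() <= 1
        assert np.all(np.diff(prof.bin_mean_gd) >= 0)
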