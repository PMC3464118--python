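"""Superimposition: centroid size, pairwise and generalized Procrustes fits,
matching symmetry, tangent projection, PCA reduction."""

import numpy as np
import pytest
from scipy.optimize import minimize

import morphomod as mm
from morphomod.procrustes import project_vector, similarity_basis, standardize


def random_similarity(rng, coords):
    theta = rng.uniform(0, 2 * np.pi)
    c, s = np.cos(theta), np.sin(theta)
    scale = rng.uniform(0.3, 3.0)
    shift = rng.uniform(-5, 5, size=2)
    return scale * coords @ np.array([[c, s], [-s, c]]) + shift


class TestCentroidSize:
    def test_unit_square_closed_form(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        assert mm.centroid_size(square) == pytest.approx(np.sqrt(2), abs=1e-12)

    def test_scale_equivariance_and_brute_force(self, rng):
        coords = rng.normal(size=(16, 2))
        cs = mm.centroid_size(coords)
        assert mm.centroid_size(3.0 * coords) == pytest.approx(3.0 * cs, rel=1e-12)
        # direct double-loop computation of the defining formula
        centroid = [sum(c[0] for c in coords) / 16, sum(c[1] for c in coords) / 16]
        total = 0.0
        for x, y in coords:
            total += (x - centroid[0]) ** 2 + (y - centroid[1]) ** 2
        assert cs == pytest.approx(np.sqrt(total), abs=1e-12)

    def test_coincident_landmarks_rejected(self):
        with pytest.raises(ValueError, match="zero centroid size"):
            mm.centroid_size(np.ones((4, 2)))


class TestOrdinaryProcrustes:
    def test_similarity_transform_invariance(self, rng):
        ref = rng.normal(size=(8, 2))
        target = random_similarity(rng, ref)
        _, dist = mm.ordinary_procrustes(ref, target)
        assert dist < 1e-10

    def test_reflection_semantics(self, rng):
        ref = rng.normal(size=(8, 2))
        mirrored = ref * np.array([-1.0, 1.0])
        _, d_no = mm.ordinary_procrustes(ref, mirrored, allow_reflection=False)
        _, d_yes = mm.ordinary_procrustes(ref, mirrored, allow_reflection=True)
        assert d_no > 0.1
        assert d_yes < 1e-10

    def test_grid_search_oracle(self):
        ref = np.array([[0, 0], [2, 0], [2, 1], [0.5, 1.5]], float)
        target = np.array([[0.1, -0.2], [1.8, 0.3], [2.2, 1.1], [0.4, 1.2]], float)
        _, dist = mm.ordinary_procrustes(ref, target)
        ref_s, tgt_s = standardize(ref), standardize(target)
        angles = np.linspace(0, 2 * np.pi, 100_000, endpoint=False)
        best = np.inf
        for theta in angles:
            c, s = np.cos(theta), np.sin(theta)
            rot = tgt_s @ np.array([[c, s], [-s, c]])
            best = min(best, np.sqrt(((rot - ref_s) ** 2).sum()))
        assert dist == pytest.approx(best, abs=1e-6)

    def test_distance_symmetric_and_triangle(self, rng):
        a, b, c = (rng.normal(size=(6, 2)) for _ in range(3))
        dab = mm.procrustes_distance(a, b)
        assert dab == pytest.approx(mm.procrustes_distance(b, a), abs=1e-10)
        assert dab <= mm.procrustes_distance(a, c) + mm.procrustes_distance(c, b) + 1e-12


class TestGPA:
    def test_identical_configs(self, rng):
        base = rng.normal(size=(6, 2))
        res = mm.gpa([base.copy() for _ in range(5)])
        assert res.converged
        dists = np.sqrt(((res.aligned - res.consensus) ** 2).sum(axis=(1, 2)))
        assert np.all(dists < 1e-10)

    def test_rotation_invariance(self, rng):
        configs = [rng.normal(size=(8, 2)) for _ in range(6)]
        res1 = mm.gpa(configs)
        rotated = [random_similarity(rng, c) for c in configs]
        res2 = mm.gpa(rotated)
        assert mm.procrustes_distance(res1.consensus, res2.consensus) < 1e-8

    def test_permutation_invariance(self, rng):
        configs = [rng.normal(size=(8, 2)) for _ in range(6)]
        res1 = mm.gpa(configs)
        res2 = mm.gpa(configs[::-1])
        assert mm.procrustes_distance(res1.consensus, res2.consensus) < 1e-8

    def test_joint_optimization_oracle(self, rng):
        """GPA attains the jointly minimized sum of squared distances to the
        mean over all per-configuration rotations."""
        configs = [rng.normal(size=(4, 2)) for _ in range(3)]
        res = mm.gpa(configs)
        achieved = float(
            ((res.aligned - res.aligned.mean(axis=0)) ** 2).sum()
        )
        std = np.stack([standardize(c) for c in configs])

        def objective(thetas):
            rots = []
            for cfg, t in zip(std, thetas):
                c, s = np.cos(t), np.sin(t)
                rots.append(cfg @ np.array([[c, s], [-s, c]]))
            stack = np.stack(rots)
            return float(((stack - stack.mean(axis=0)) ** 2).sum())

        best = min(
            minimize(objective, x0=rng.uniform(0, 2 * np.pi, 3), method="Nelder-Mead").fun
            for _ in range(5)
        )
        assert achieved == pytest.approx(best, abs=1e-6)


class TestMatchingSymmetry:
    @staticmethod
    def _paired_dataset(rng, n_spec=6, asym=None):
        base = rng.normal(size=(8, 2))
        configs = []
        for i in range(n_spec):
            left = base + rng.normal(0, 0.01, size=(8, 2))
            right = left.copy()
            if asym is not None:
                right = right + asym
            right = right * np.array([-1.0, 1.0])  # emitted mirrored
            for rep in (1, 2):
                configs.append(mm.LandmarkConfiguration(f"s{i}", "A", "L", rep, left))
                configs.append(mm.LandmarkConfiguration(f"s{i}", "A", "R", rep, right))
        return mm.Dataset(configs, [mm.StrainRecord("A", n_spec, is_reference=True)])

    def test_exact_mirror_has_no_asymmetry(self, rng):
        ds = self._paired_dataset(rng)
        decomp, _, _ = mm.matching_symmetry(ds)
        assert np.abs(decomp.asymmetric).max() < 1e-8

    def test_side_means_reconstruct(self, rng):
        ds = self._paired_dataset(rng, asym=rng.normal(0, 0.02, size=(8, 2)))
        decomp, res, meta = mm.matching_symmetry(ds)
        spec0 = decomp.specimens[0]
        idx_l = meta.index[(meta["specimen"] == spec0) & (meta["side"] == "L")]
        mean_l = res.aligned[idx_l].mean(axis=0)
        np.testing.assert_allclose(
            mean_l, decomp.symmetric[0] + decomp.asymmetric[0], atol=1e-12
        )

    def test_directional_asymmetry_recovered(self, rng):
        d = rng.normal(0, 0.03, size=(8, 2))
        ds = self._paired_dataset(rng, asym=d)
        decomp, res, _ = mm.matching_symmetry(ds)
        # mean asymmetric component = -(projection of d into shape space)/2,
        # up to the joint GPA's global alignment
        da = decomp.asymmetric.mean(axis=0)
        expected = project_vector(d / mm.centroid_size(ds.configurations[0].coords), res.consensus)
        cos = np.abs(np.sum(da * expected)) / (
            np.linalg.norm(da) * np.linalg.norm(expected)
        )
        assert cos > 0.95

    def test_relabel_invariance(self, rng):
        ds = self._paired_dataset(rng, asym=rng.normal(0, 0.02, size=(8, 2)))
        swapped = mm.Dataset(
            [
                mm.LandmarkConfiguration(
                    c.specimen_id,
                    c.strain_id,
                    "L" if c.side == "R" else "R",
                    c.replicate,
                    c.coords,
                )
                for c in ds.configurations
            ],
            ds.strain_table,
        )
        d1, _, _ = mm.matching_symmetry(ds)
        d2, _, _ = mm.matching_symmetry(swapped)
        # swapping the labels flips which side is mirrored, so the symmetric
        # shapes agree up to one global reflection
        for a, b in zip(d1.symmetric, d2.symmetric):
            _, dist = mm.ordinary_procrustes(a, b, allow_reflection=True)
            assert dist < 1e-8

    def test_one_sided_specimen_excluded(self, rng, caplog):
        ds = self._paired_dataset(rng)
        extra = mm.LandmarkConfiguration("lonely", "A", "L", 1, rng.normal(size=(8, 2)))
        ds.configurations.append(extra)
        with caplog.at_level("WARNING"):
            decomp, _, _ = mm.matching_symmetry(ds)
        assert "lonely" not in decomp.specimens
        assert "lonely" in caplog.text


class TestTangent:
    def test_rank_and_zero_projection(self, small_symmetrized):
        tangent = small_symmetrized["tangent"]
        k = small_symmetrized["k"]
        assert np.linalg.matrix_rank(tangent) <= 2 * k - 4
        # the consensus itself maps to the zero tangent vector
        res = small_symmetrized["gpa"]
        basis = similarity_basis(res.consensus)
        v = res.consensus.ravel() - res.consensus.ravel()
        assert np.linalg.norm(v - basis @ (basis.T @ v)) < 1e-15

    def test_tangent_distances_match_procrustes(self, rng):
        base = rng.normal(size=(10, 2))
        configs = [base + rng.normal(0, 0.005, size=(10, 2)) for _ in range(8)]
        res = mm.gpa(configs)
        tangent = mm.tangent_project(res)
        for i, j in [(0, 1), (2, 5), (3, 7)]:
            td = np.linalg.norm(tangent[i] - tangent[j])
            pd_ = mm.procrustes_distance(configs[i], configs[j])
            assert td == pytest.approx(pd_, rel=0.01)


class TestPCA:
    def test_reconstruction_and_orthonormality(self, rng):
        X = rng.normal(size=(20, 12))
        model = mm.pca_reduce(X, n_components=5)
        np.testing.assert_allclose(model.loadings.T @ model.loadings, np.eye(model.loadings.shape[1]), atol=1e-10)
        recon = model.scores @ model.loadings.T + model.mean
        np.testing.assert_allclose(recon, X, atol=1e-10)
        assert model.variance_fractions.sum() == pytest.approx(1.0)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)

    def test_dominant_direction_recovered(self, rng):
        direction = rng.normal(size=12)
        direction /= np.linalg.norm(direction)
        X = np.outer(rng.normal(0, 5, 40), direction) + rng.normal(0, 0.1, size=(40, 12))
        model = mm.pca_reduce(X, n_components=2)
        corr = abs(float(model.loadings[:, 0] @ direction))
        assert corr > 0.99

    def test_variance_threshold_policy(self, rng):
        X = rng.normal(size=(30, 10))
        model = mm.pca_reduce(X, variance_threshold=0.9)
        fr = model.variance_fractions
        assert fr[: model.n_retained].sum() >= 0.9
        assert fr[: model.n_retained - 1].sum() < 0.9

    def test_overlarge_request_capped(self, rng):
        X = rng.normal(size=(5, 10))  # rank 4
        model = mm.pca_reduce(X, n_components=14)
        assert model.n_retained <= 4
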