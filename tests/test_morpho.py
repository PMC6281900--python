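"""GPA, symmetrization, shape PCA, permutation tests, allometry."""

import numpy as np
import pytest

from hybridbracket.errors import CoverageError, DegeneracyError, InputError
from hybridbracket.morpho import (
    LandmarkSet,
    SymmetryPairing,
    centroid_size,
    generalized_procrustes,
    group_geometric_mean,
    procrustes_permutation_test,
    quadratic_allometry,
    read_tps,
    shape_pca,
    symmetrize,
)
from hybridbracket.synthetic_data import default_landmark_model, simulate_landmark_sample


def random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


@pytest.fixture
def base_shape(rng):
    shape = rng.normal(size=(12, 3))
    return shape - shape.mean(axis=0)


class TestSymmetrize:
    @pytest.fixture
    def pairing(self):
        # landmarks 0-1 midline, (2,3), (4,5), (6,7) mirror pairs
        return SymmetryPairing(pairs=[(2, 3), (4, 5), (6, 7)], midline=[0, 1])

    @pytest.fixture
    def symmetric_config(self):
        mid = np.array([[0, 0, 0], [0, 1, 2]], float)
        right = np.array([[1, 0.5, 0.2], [2, -1, 0.3], [1.5, 2, -1]], float)
        left = right * np.array([-1, 1, 1])
        return np.vstack([mid, np.stack([right, left], axis=1).reshape(-1, 3)])

    def test_symmetric_configuration_unchanged(self, pairing, symmetric_config):
        out = symmetrize(symmetric_config, pairing)
        np.testing.assert_allclose(out, symmetric_config, atol=1e-10)

    def test_idempotent(self, pairing, symmetric_config, rng):
        noisy = symmetric_config + rng.normal(0, 0.05, symmetric_config.shape)
        once = symmetrize(noisy, pairing)
        twice = symmetrize(once, pairing)
        np.testing.assert_allclose(once, twice, atol=1e-8)

    def test_removes_asymmetric_component_against_projection_oracle(
            self, pairing, symmetric_config):
        # perturb one paired landmark off-plane; for a configuration already
        # in its symmetry frame the least-squares symmetric fit is the plain
        # average with its reflected-relabelled copy (no rotation needed)
        noisy = symmetric_config.copy()
        noisy[2, 0] += 2e-3
        perm = pairing.permutation(noisy.shape[0])
        reflected = (noisy * np.array([-1, 1, 1]))[perm]
        oracle = (noisy + reflected) / 2
        out = symmetrize(noisy, pairing)
        # compare as shapes: the rotation-fitting symmetrizer and the
        # fixed-frame projection agree to second order in the perturbation,
        # i.e. far below the 2e-3 asymmetry being removed
        np.testing.assert_allclose(out - out.mean(axis=0),
                                   oracle - oracle.mean(axis=0), atol=5e-5)

    def test_bad_pairing_rejected(self, symmetric_config):
        with pytest.raises(InputError):
            symmetrize(symmetric_config,
                       SymmetryPairing(pairs=[(2, 3), (3, 4)], midline=[0, 1]))


class TestGPA:
    def test_single_shape_under_similarity_transforms(self, base_shape, rng):
        coords = []
        for _ in range(6):
            coords.append(base_shape @ random_rotation(rng)
                          * rng.uniform(0.5, 3.0) + rng.normal(size=3) * 10)
        space = generalized_procrustes(
            LandmarkSet([f"s{i}" for i in range(6)], np.stack(coords)))
        for aligned in space.aligned[1:]:
            np.testing.assert_allclose(aligned, space.aligned[0], atol=1e-8)

    def test_output_invariant_to_input_similarity_transforms(self, rng):
        lms = simulate_landmark_sample(default_landmark_model(n_per_group=4, seed=3))
        s1 = generalized_procrustes(lms)
        coords2 = np.stack([
            c @ random_rotation(rng) * rng.uniform(0.5, 2) + rng.normal(size=3)
            for c in lms.coords])
        s2 = generalized_procrustes(LandmarkSet(lms.ids, coords2))
        np.testing.assert_allclose(s1.aligned, s2.aligned, atol=1e-8)

    def test_two_shape_distance_matches_pairwise_opa_oracle(self, base_shape, rng):
        other = base_shape + rng.normal(0, 0.1, base_shape.shape)
        other -= other.mean(axis=0)
        space = generalized_procrustes(
            LandmarkSet(["a", "b"], np.stack([base_shape, other])))
        gpa_dist = np.linalg.norm(space.aligned[0] - space.aligned[1])
        # oracle: direct two-configuration orthogonal Procrustes fit
        a = base_shape / centroid_size(base_shape)
        b = other / centroid_size(other)
        u, s, vt = np.linalg.svd(b.T @ a)
        d = np.sign(np.linalg.det(u @ vt))
        flip = np.ones(3)
        flip[-1] = d
        opa_dist = np.linalg.norm(a - b @ ((u * flip) @ vt))
        assert gpa_dist == pytest.approx(opa_dist, abs=1e-6)

    def test_consensus_is_mean_of_aligned(self):
        lms = simulate_landmark_sample(default_landmark_model(n_per_group=3, seed=1))
        space = generalized_procrustes(lms)
        np.testing.assert_allclose(space.consensus, space.aligned.mean(axis=0),
                                   atol=1e-12)
        assert space.converged

    def test_aligned_shapes_unit_size_centred(self):
        lms = simulate_landmark_sample(default_landmark_model(n_per_group=3, seed=2))
        space = generalized_procrustes(lms)
        for shape in space.aligned:
            assert centroid_size(shape) == pytest.approx(1.0)
            np.testing.assert_allclose(shape.mean(axis=0), 0, atol=1e-12)

    def test_collinear_configuration_raises(self):
        line = np.column_stack([np.arange(6.0), np.zeros(6), np.zeros(6)])
        good = np.random.default_rng(0).normal(size=(6, 3))
        with pytest.raises(DegeneracyError, match="bad"):
            generalized_procrustes(
                LandmarkSet(["good", "bad"], np.stack([good, line])))


class TestShapePCA:
    def test_single_direction_gives_pc1_everything(self, base_shape, rng):
        direction = rng.normal(size=base_shape.shape)
        coords = np.stack([
            base_shape + t * 0.01 * direction for t in np.linspace(-1, 1, 8)])
        space = generalized_procrustes(
            LandmarkSet([f"s{i}" for i in range(8)], coords))
        pca = shape_pca(space)
        assert pca.explained_pct[0] > 99.0

    def test_variance_sums_to_100_and_roundtrip(self):
        lms = simulate_landmark_sample(default_landmark_model(n_per_group=4, seed=5))
        space = generalized_procrustes(lms)
        pca = shape_pca(space)
        assert pca.explained_pct.sum() == pytest.approx(100.0)
        recon = pca.scores @ pca.loadings + pca.mean
        np.testing.assert_allclose(recon, space.flat(), atol=1e-8)

    def test_total_variance_matches_procrustes_residuals(self):
        lms = simulate_landmark_sample(default_landmark_model(n_per_group=4, seed=6))
        space = generalized_procrustes(lms)
        pca = shape_pca(space)
        X = space.flat()
        total_var = ((X - X.mean(axis=0)) ** 2).sum() / (X.shape[0] - 1)
        sing_var = ((pca.scores ** 2).sum() / (X.shape[0] - 1))
        assert sing_var == pytest.approx(total_var)


class TestPermutationTest:
    def test_identical_groups_p_near_one(self, base_shape):
        coords = np.stack([base_shape] * 8)
        space = generalized_procrustes(
            LandmarkSet([f"s{i}" for i in range(8)], coords))
        mask = np.zeros(8, bool)
        mask[:4] = True
        res = procrustes_permutation_test(space, mask, ~mask, n_perm=200, seed=1)
        assert res.distance == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0

    def test_separated_species_reject(self):
        lms = simulate_landmark_sample(default_landmark_model(seed=8))
        space = generalized_procrustes(lms)
        nb = space.mask_for(age_class="newborn")
        res = procrustes_permutation_test(
            space, nb & space.mask_for(species="ringed"),
            nb & space.mask_for(species="grey"), n_perm=999, seed=8)
        assert res.p_value < 0.01

    def test_reproducible_under_seed_and_bounded(self):
        lms = simulate_landmark_sample(default_landmark_model(n_per_group=3, seed=9))
        space = generalized_procrustes(lms)
        m1 = space.mask_for(species="ringed")
        r1 = procrustes_permutation_test(space, m1, ~m1, n_perm=300, seed=4)
        r2 = procrustes_permutation_test(space, m1, ~m1, n_perm=300, seed=4)
        assert r1.p_value == r2.p_value
        assert 0 < r1.p_value <= 1

    def test_small_group_rejected(self, base_shape):
        space = generalized_procrustes(
            LandmarkSet(["a", "b", "c"], np.stack([base_shape] * 3)))
        mask = np.array([True, False, False])
        with pytest.raises(CoverageError):
            procrustes_permutation_test(space, mask, ~mask)


class TestAllometry:
    @staticmethod
    def quadratic_space(n=9, noise=0.0, seed=0):
        """ShapeSpace whose aligned coordinates are exactly quadratic in size."""
        from hybridbracket.morpho import ShapeSpace

        rng = np.random.default_rng(seed)
        base = rng.normal(size=(10, 3))
        base -= base.mean(axis=0)
        base /= centroid_size(base)
        lin = rng.normal(size=(10, 3)) * 0.02
        quad = rng.normal(size=(10, 3)) * 0.01
        sizes = np.linspace(1.0, 3.0, n)
        aligned = np.stack([
            base + lin * s + quad * s**2 + rng.normal(0, noise, base.shape)
            for s in sizes])
        return ShapeSpace(aligned, sizes, aligned.mean(axis=0),
                          [f"s{i}" for i in range(n)])

    def test_exact_recovery_on_noiseless_quadratic_shapes(self):
        space = self.quadratic_space()
        model = quadratic_allometry(space)
        assert model.residual_ss < 1e-8

    def test_coefficients_match_normal_equations_oracle(self):
        space = self.quadratic_space(n=5, noise=0.01)
        model = quadratic_allometry(space)
        s = space.sizes
        D = np.column_stack([np.ones_like(s), s, s**2])
        oracle = np.linalg.solve(D.T @ D, D.T @ space.flat())
        np.testing.assert_allclose(model.coefficients, oracle, atol=1e-8)

    def test_mean_of_fitted_equals_mean_shape(self):
        space = self.quadratic_space(n=7, noise=0.02, seed=3)
        model = quadratic_allometry(space)
        fitted = model.predict(space.sizes)
        np.testing.assert_allclose(fitted.mean(axis=0), space.flat().mean(axis=0),
                                   atol=1e-10)

    def test_all_equal_sizes_rejected(self, base_shape):
        coords = np.stack([base_shape] * 5)
        space = generalized_procrustes(
            LandmarkSet([f"s{i}" for i in range(5)], coords))
        space.sizes = np.full(5, 2.0)
        with pytest.raises(InputError):
            quadratic_allometry(space)


class TestGroupMean:
    def test_identical_subset_returns_that_shape(self, base_shape):
        coords = np.stack([base_shape] * 5)
        space = generalized_procrustes(
            LandmarkSet([f"s{i}" for i in range(5)], coords))
        mean = group_geometric_mean(space, np.array([True, True, False, False, False]))
        np.testing.assert_allclose(mean, space.aligned[0], atol=1e-10)

    def test_two_shape_mean_is_rescaled_midpoint(self):
        lms = simulate_landmark_sample(default_landmark_model(n_per_group=2, seed=11))
        space = generalized_procrustes(lms)
        mask = np.zeros(space.n_specimens, bool)
        mask[:2] = True
        mean = group_geometric_mean(space, mask)
        midpoint = (space.aligned[0] + space.aligned[1]) / 2
        np.testing.assert_allclose(mean, midpoint / centroid_size(midpoint),
                                   atol=1e-12)

    def test_full_set_mean_matches_consensus(self):
        lms = simulate_landmark_sample(default_landmark_model(n_per_group=2, seed=12))
        space = generalized_procrustes(lms)
        mean = group_geometric_mean(space, np.ones(space.n_specimens, bool))
        np.testing.assert_allclose(
            mean, space.consensus / centroid_size(space.consensus), atol=1e-10)

    def test_empty_subset_rejected(self):
        lms = simulate_landmark_sample(default_landmark_model(n_per_group=2, seed=13))
        space = generalized_procrustes(lms)
        with pytest.raises(CoverageError):
            group_geometric_mean(space, np.zeros(space.n_specimens, bool))


class TestIO:
    def test_tps_round_trip(self, tmp_path):
        tps = """LM3=4
0.0 0.0 0.0
1.0 0.0 0.5
0.0 1.0 0.5
1.0 1.0 0.0
ID=spec1
LM3=4
0.1 0.0 0.0
1.1 0.0 0.5
0.1 1.0 0.5
1.1 1.0 0.0
ID=spec2
"""
        path = tmp_path / "toy.tps"
        path.write_text(tps)
        lms = read_tps(path)
        assert lms.ids == ["spec1", "spec2"]
        assert lms.coords.shape == (2, 4, 3)
        assert lms.coords[1, 0, 0] == pytest.approx(0.1)

    def test_long_csv_round_trip(self, tmp_path):
        lms = simulate_landmark_sample(default_landmark_model(n_per_group=1, seed=14))
        path = tmp_path / "landmarks.csv"
        lms.to_long_csv(path)
        back = LandmarkSet.from_long_csv(path)
        np.testing.assert_allclose(back.coords, lms.coords)
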