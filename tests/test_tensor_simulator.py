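import numpy as np
import pytest

from dia3 import (
    make_tensor,
    rotate_tensor,
    rotation_matrix,
    scheme_directions,
    synthesize_phantom,
    tensor_adc,
    tensor_fa,
)
from dia3.tensor_simulator import fibonacci_directions, repulsion_directions


class TestMakeTensor:
    def test_isotropic(self):
        T = make_tensor([1e-3, 1e-3, 1e-3])
        np.testing.assert_allclose(T.matrix, 1e-3 * np.eye(3))

    def test_reference_diagonal(self, reference_tensor):
        np.testing.assert_allclose(
            reference_tensor.matrix, np.diag([1e-3, 0.3e-3, 0.3e-3])
        )

    def test_eigendecomposition_round_trip(self, rng):
        from scipy.stats import special_ortho_group

        lam = np.array([2.5e-3, 0.9e-3, 0.2e-3])
        V = special_ortho_group.rvs(3, random_state=rng)
        T = make_tensor(lam, V)
        np.testing.assert_allclose(T.eigenvalues, lam, atol=1e-15)
        recon = T.eigenvectors @ np.diag(T.eigenvalues) @ T.eigenvectors.T
        np.testing.assert_allclose(recon, T.matrix, atol=1e-12)

    def test_non_orthonormal_eigenvectors_rejected(self):
        with pytest.raises(ValueError, match="orthonormal"):
            make_tensor([1e-3] * 3, np.ones((3, 3)))

    def test_negative_eigenvalue_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            make_tensor([1e-3, -1e-3, 0.3e-3])


class TestRotations:
    @pytest.mark.parametrize("scheme", ["plane", "spatial"])
    def test_proper_rotation_over_full_circle(self, scheme):
        for theta in np.deg2rad(np.arange(360)):
            R = rotation_matrix(scheme, theta)
            assert np.linalg.norm(R.T @ R - np.eye(3)) < 1e-12
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)

    def test_plane_zero_is_identity(self):
        np.testing.assert_allclose(rotation_matrix("plane", 0.0), np.eye(3))

    def test_plane_quarter_turn_maps_x_to_minus_z(self):
        R = rotation_matrix("plane", np.pi / 2)
        np.testing.assert_allclose(R @ [1, 0, 0], [0, 0, -1], atol=1e-15)

    def test_spatial_120_degrees_is_cyclic_permutation(self):
        R = rotation_matrix("spatial", 2 * np.pi / 3)
        P = np.array([[0, 0, 1], [1, 0, 0], [0, 1, 0]], float)
        np.testing.assert_allclose(R, P, atol=1e-12)

    def test_spatial_diagonal_pattern(self):
        # diagonal of the corner-axis rotation is 1/3 + (2/3)cosθ
        theta = 0.7
        R = rotation_matrix("spatial", theta)
        np.testing.assert_allclose(
            np.diag(R), 1 / 3 + (2 / 3) * np.cos(theta), atol=1e-12
        )

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="unknown rotation"):
            rotation_matrix("euler", 0.1)

    def test_rotation_preserves_eigenvalues(self, rng, reference_tensor):
        from scipy.stats import special_ortho_group

        for _ in range(200):
            R = special_ortho_group.rvs(3, random_state=rng)
            Tr = rotate_tensor(reference_tensor, R)
            np.testing.assert_allclose(
                Tr.eigenvalues, reference_tensor.eigenvalues, atol=1e-12
            )

    def test_isotropic_tensor_rotation_invariant(self):
        T = make_tensor([0.7e-3] * 3)
        R = rotation_matrix("spatial", 1.234)
        np.testing.assert_allclose(rotate_tensor(T, R).matrix, T.matrix, atol=1e-15)

    def test_plane_quarter_turn_permutes_diagonal(self, reference_tensor):
        Tr = rotate_tensor(reference_tensor, rotation_matrix("plane", np.pi / 2))
        np.testing.assert_allclose(
            np.diag(Tr.matrix), [0.3e-3, 0.3e-3, 1e-3], atol=1e-15
        )


class TestADCAndFA:
    def test_principal_axis_adc(self, reference_tensor):
        assert tensor_adc(reference_tensor, [1, 0, 0]) == pytest.approx(1e-3)

    def test_diagonal_direction_adc(self, reference_tensor):
        u = np.ones(3) / np.sqrt(3)
        assert tensor_adc(reference_tensor, u) == pytest.approx(1.6e-3 / 3)

    def test_isotropic_adc_any_direction(self, rng):
        T = make_tensor([0.9e-3] * 3)
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        assert tensor_adc(T, u) == pytest.approx(0.9e-3)

    def test_reference_fa_worked_example(self, reference_tensor):
        assert tensor_fa(reference_tensor) == pytest.approx(0.6444, abs=5e-5)

    def test_isotropic_fa_zero(self):
        assert tensor_fa(make_tensor([1e-3] * 3)) == pytest.approx(0.0)

    def test_stick_limit_fa_one(self):
        assert tensor_fa(make_tensor([1e-3, 0.0, 0.0])) == pytest.approx(1.0)

    def test_zero_tensor_fa_undefined(self):
        with pytest.raises(ValueError, match="zero tensor"):
            tensor_fa(make_tensor([0.0, 0.0, 0.0]))


class TestDirectionSets:
    @pytest.mark.parametrize("n", [3, 4, 5, 6, 16, 64])
    def test_unit_norm_and_no_antipodal_duplicates(self, n):
        d = scheme_directions(n).directions
        assert d.shape == (n, 3)
        np.testing.assert_allclose(np.linalg.norm(d, axis=1), 1.0)
        dots = np.abs(d @ d.T)
        np.fill_diagonal(dots, 0.0)
        assert dots.max() < 1.0 - 1e-9

    def test_repulsion_set_is_deterministic(self):
        np.testing.assert_array_equal(
            repulsion_directions(5), repulsion_directions(5)
        )

    def test_dense_repulsion_set_reasonably_uniform(self):
        d = scheme_directions(64).directions
        dots = np.abs(d @ d.T)
        np.fill_diagonal(dots, 0.0)
        min_angle = np.degrees(np.arccos(dots.max()))
        assert min_angle > 12.0  # ideal packing for 64 antipodal dirs ≈ 16°


class TestPhantom:
    def test_signal_along_principal_axis(self, axes_phantom):
        # S0·exp(−b·λ1) = 1000·e⁻¹ along x
        np.testing.assert_allclose(
            axes_phantom.data[0, 0, 0, 1], 1000 * np.exp(-1.0), rtol=1e-12
        )

    def test_noiseless_phantom_seed_independent(self, reference_tensor):
        s = scheme_directions(3)
        p1 = synthesize_phantom(reference_tensor, s, seed=1)
        p2 = synthesize_phantom(reference_tensor, s, seed=2)
        np.testing.assert_array_equal(p1.data, p2.data)

    def test_noisy_phantom_reproducible_under_seed(self, reference_tensor):
        s = scheme_directions(6)
        p1 = synthesize_phantom(reference_tensor, s, noise_sigma=50.0, seed=3)
        p2 = synthesize_phantom(reference_tensor, s, noise_sigma=50.0, seed=3)
        p3 = synthesize_phantom(reference_tensor, s, noise_sigma=50.0, seed=4)
        np.testing.assert_array_equal(p1.data, p2.data)
        assert np.any(p1.data != p3.data)

    def test_b0_volume_prepended(self, axes_phantom):
        assert axes_phantom.table.b0_mask[0]
        assert axes_phantom.data[..., 0] == pytest.approx(1000.0)

    def test_full_pipeline_dia_constant(self, axes_phantom):
        from dia3 import compute_adc, dia_simplified, normalize

        mask = np.ones(axes_phantom.data.shape[:3], bool)
        D = compute_adc(normalize(axes_phantom, mask=mask)).D
        dia = dia_simplified(D[..., 0], D[..., 1], D[..., 2])
        np.testing.assert_allclose(dia, 0.27684, atol=5e-6)
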