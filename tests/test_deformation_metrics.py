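import numpy as np
import pytest
from scipy import ndimage

from grouptemplate.core_io import AffineTransform, DisplacementField, Volume
from grouptemplate.deformation_metrics import (
    MetricsSummary,
    foreground_mask,
    hessian_frobenius_map,
    hfm,
    interior_mask,
    jacobian_determinant_map,
    jacobian_difference_map,
    jacobian_stats,
    jsd,
    summarize_field,
)
from grouptemplate.transforms import affine_to_dfield


def centred_similarity_field(scale, shape=(32, 32, 32)):
    grid = Volume(np.zeros(shape), 1.0)
    c = (np.array(shape) - 1) / 2.0
    aff = AffineTransform(scale * np.eye(3), c - scale * c)
    return affine_to_dfield(aff, grid)


def smooth_field(rng, shape=(16, 16, 16), amplitude=1.0):
    v = rng.standard_normal((3, *shape))
    for c in range(3):
        v[c] = ndimage.gaussian_filter(v[c], sigma=2)
    v *= amplitude / np.abs(v).max()
    return DisplacementField(v, (1.0, 1.0, 1.5))


def brute_force_jdet(field):
    """Independent per-voxel 3x3 determinant from manual central differences."""
    u = field.vectors
    sp = field.spacing
    shape = field.grid_shape
    out = np.empty(shape)
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                J = np.eye(3)
                for c in range(3):
                    for a, idx in enumerate((i, j, k)):
                        lo = [i, j, k]
                        hi = [i, j, k]
                        if idx == 0:
                            hi[a] = 1
                            denom = sp[a]
                        elif idx == shape[a] - 1:
                            lo[a] = shape[a] - 2
                            denom = sp[a]
                        else:
                            lo[a] = idx - 1
                            hi[a] = idx + 1
                            denom = 2 * sp[a]
                        J[c, a] += (u[c][tuple(hi)] - u[c][tuple(lo)]) / denom
                out[i, j, k] = np.linalg.det(J)
    return out


class TestJacobianDeterminant:
    def test_zero_field_has_unit_determinant(self):
        field = DisplacementField.zeros((8, 8, 8))
        np.testing.assert_allclose(jacobian_determinant_map(field).values, 1.0)

    def test_similarity_scale_cubes(self):
        s = 1.07
        jmap = jacobian_determinant_map(centred_similarity_field(s))
        interior = jmap.values[interior_mask(jmap.shape)]
        np.testing.assert_allclose(interior, s**3, atol=1e-10)

    def test_matches_brute_force_oracle(self, rng):
        field = smooth_field(rng)
        jmap = jacobian_determinant_map(field)
        np.testing.assert_allclose(jmap.values, brute_force_jdet(field), atol=1e-10)

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError):
            jacobian_determinant_map(DisplacementField.zeros((2, 8, 8)))


class TestJsd:
    def test_affine_field_has_zero_jsd(self, rng):
        aff = AffineTransform(np.eye(3) + 0.03 * rng.standard_normal((3, 3)), [1, 0, 0])
        field = affine_to_dfield(aff, Volume(np.zeros((16, 16, 16)), 1.0))
        jmap = jacobian_determinant_map(field)
        assert jsd(jmap, interior_mask(jmap.shape)) < 1e-10

    def test_hand_arithmetic(self):
        jmap = Volume(np.array([0.9, 1.1]).reshape(2, 1, 1))
        mask = np.ones((2, 1, 1), dtype=bool)
        stats = jacobian_stats(jmap, mask)
        assert stats.mean == pytest.approx(1.0)
        assert stats.sd == pytest.approx(0.1)

    def test_empty_mask_rejected(self):
        jmap = Volume(np.ones((4, 4, 4)))
        with pytest.raises(ValueError):
            jsd(jmap, np.zeros((4, 4, 4), dtype=bool))


class TestHessian:
    def test_affine_field_has_zero_hessian(self, rng):
        aff = AffineTransform(np.eye(3) + 0.05 * rng.standard_normal((3, 3)), [0, 2, 0])
        field = affine_to_dfield(aff, Volume(np.zeros((32, 32, 32)), 1.0))
        hmap = hessian_frobenius_map(field)
        assert hfm(hmap, interior_mask(hmap.shape)) < 1e-9

    def test_quadratic_field_analytic_second_derivative(self):
        # u_x = a x^2 -> d2 phi_x / dx2 = 2a exactly under central differences
        a = 0.01
        x = np.meshgrid(*[np.arange(16, dtype=float)] * 3, indexing="ij")[0]
        field = DisplacementField(
            np.stack([a * x**2, np.zeros_like(x), np.zeros_like(x)]), 1.0
        )
        hmap = hessian_frobenius_map(field)
        interior = interior_mask(hmap.shape, border=2)
        np.testing.assert_allclose(hmap.values[interior], 2 * a, atol=1e-12)

    def test_matches_independent_stencil_oracle(self, rng):
        field = smooth_field(rng)
        hmap = hessian_frobenius_map(field)
        # independent implementation: explicit 1D convolution stencils
        sp = field.spacing
        acc = np.zeros(field.grid_shape)
        for c in range(3):
            first = [
                np.gradient(field.vectors[c], sp[a], axis=a, edge_order=1)
                for a in range(3)
            ]
            for a in range(3):
                for b in range(3):
                    second = np.gradient(first[a], sp[b], axis=b, edge_order=1)
                    acc += second**2
        np.testing.assert_allclose(hmap.values, np.sqrt(acc), atol=1e-10)


class TestJacobianDifference:
    def test_equal_fields_give_zero_map(self, rng):
        f = smooth_field(rng)
        diff = jacobian_difference_map(f, f.copy())
        np.testing.assert_allclose(diff.values, 0.0, atol=1e-14)

    def test_uniform_expansion_vs_identity(self):
        s = 1.2 ** (1 / 3)  # linear scale with det 1.2
        a = centred_similarity_field(s)
        b = DisplacementField.zeros(a.grid_shape)
        diff = jacobian_difference_map(a, b)
        interior = interior_mask(diff.shape)
        np.testing.assert_allclose(diff.values[interior], 0.2, atol=1e-10)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            jacobian_difference_map(
                DisplacementField.zeros((8, 8, 8)), DisplacementField.zeros((6, 8, 8))
            )


class TestProperties:
    def test_divergence_free_field_preserves_mean_volume(self, rng):
        # u = curl(A) is divergence-free, so det(I + grad u) ~ 1 on average
        shape = (24, 24, 24)
        A = rng.standard_normal((3, *shape))
        for c in range(3):
            A[c] = ndimage.gaussian_filter(A[c], sigma=4)
        A *= 5.0 / np.abs(A).max()
        dA = [[np.gradient(A[c], axis=a) for a in range(3)] for c in range(3)]
        u = np.stack(
            [
                dA[2][1] - dA[1][2],
                dA[0][2] - dA[2][0],
                dA[1][0] - dA[0][1],
            ]
        )
        field = DisplacementField(u, 1.0)
        jmap = jacobian_determinant_map(field)
        stats = jacobian_stats(jmap, interior_mask(jmap.shape, border=2))
        assert stats.mean == pytest.approx(1.0, abs=1e-2)

    def test_metrics_decrease_under_gaussian_smoothing(self, rng):
        field = smooth_field(np.random.default_rng(0), shape=(24, 24, 24), amplitude=3.0)
        jsds, hfms = [], []
        for sigma in (0, 1, 2):
            v = np.stack(
                [ndimage.gaussian_filter(field.vectors[c], sigma) for c in range(3)]
            )
            f = DisplacementField(v, field.spacing)
            mask = interior_mask(f.grid_shape)
            jsds.append(jsd(jacobian_determinant_map(f), mask))
            hfms.append(hfm(hessian_frobenius_map(f), mask))
        assert jsds[0] > jsds[1] > jsds[2]
        assert hfms[0] > hfms[1] > hfms[2]

    def test_affine_exclusion_contract(self, rng):
        # folding a global scale INTO the field changes jdet_mean; carrying
        # the same affine as a separate composite component must not, because
        # metrics consume the deformable component only
        field = smooth_field(rng, amplitude=0.5)
        base = summarize_field(field)
        s = 1.1
        grid = Volume(np.zeros(field.grid_shape), field.spacing)
        c = (np.array(field.grid_shape) - 1) * field.spacing / 2.0
        scale_field = affine_to_dfield(
            AffineTransform(s * np.eye(3), c - s * c), grid
        )
        folded = DisplacementField(
            field.vectors + scale_field.vectors, field.spacing
        )
        assert summarize_field(folded).jdet_mean != pytest.approx(base.jdet_mean, abs=1e-3)
        # a separate affine component leaves the field untouched
        again = summarize_field(field)
        assert again.jdet_mean == pytest.approx(base.jdet_mean, abs=1e-15)
        assert again.jsd == pytest.approx(base.jsd, abs=1e-15)

    def test_foreground_mask_excludes_border(self, small_brain):
        mask = foreground_mask(small_brain.reference)
        assert not mask[0].any() and not mask[-1].any()
        assert mask.sum() > 0

    def test_summary_validation(self):
        with pytest.raises(ValueError):
            MetricsSummary(jsd=-0.1, jdet_mean=1.0, hfm=0.0, voxel_count=1, mask_description="x")
        with pytest.raises(ValueError):
            MetricsSummary(jsd=0.1, jdet_mean=1.0, hfm=0.0, voxel_count=0, mask_description="x")
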