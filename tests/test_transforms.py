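import numpy as np
import pytest
from scipy import ndimage

from grouptemplate.core_io import (
    AffineTransform,
    CompositeTransform,
    DisplacementField,
    Volume,
)
from grouptemplate.transforms import (
    affine_to_dfield,
    apply_to_image,
    apply_to_points,
    compose,
    invert_dfield,
    mirror_transform,
    total_displacement,
    transform_points_forward,
)


def smooth_random_field(shape, amplitude, rng, spacing=1.0):
    v = rng.standard_normal((3, *shape))
    for c in range(3):
        v[c] = ndimage.gaussian_filter(v[c], sigma=4)
    v *= amplitude / np.sqrt((v**2).mean() * 3)
    return DisplacementField(v, spacing)


class TestApplyToImage:
    def test_identity_is_exact(self, random_volume):
        out = apply_to_image(random_volume, AffineTransform.identity(), random_volume)
        np.testing.assert_array_equal(out.values, random_volume.values)

    def test_one_voxel_translation_nearest(self, random_volume):
        t = AffineTransform.from_translation(random_volume.spacing * [1, 0, 0])
        out = apply_to_image(
            random_volume, t, random_volume, interpolation="nearest"
        )
        np.testing.assert_array_equal(out.values[:-1], random_volume.values[1:])
        assert np.all(out.values[-1] == 0)  # fill value beyond the far edge

    def test_random_affine_matches_scalar_loop_oracle(self, rng):
        vol = Volume(rng.random((16, 16, 16)), (1.0, 1.0, 1.5), (2.0, 0.0, -1.0))
        aff = AffineTransform(
            np.eye(3) + 0.05 * rng.standard_normal((3, 3)), rng.standard_normal(3)
        )
        out = apply_to_image(vol, aff, vol, interpolation="linear")
        # independent per-voxel trilinear resampler
        expected = np.zeros(vol.shape)
        for i in range(16):
            for j in range(16):
                for k in range(16):
                    x = vol.origin + np.array([i, j, k]) * vol.spacing
                    y = aff.matrix @ x + aff.translation
                    f = (y - vol.origin) / vol.spacing
                    if np.any(f < 0) or np.any(f > 15):
                        expected[i, j, k] = 0.0  # outside -> fill value
                        continue
                    i0 = np.floor(f).astype(int)
                    w = f - i0
                    acc = 0.0
                    for di in (0, 1):
                        for dj in (0, 1):
                            for dk in (0, 1):
                                idx = i0 + [di, dj, dk]
                                if np.all(idx >= 0) and np.all(idx < 16):
                                    val = vol.values[tuple(idx)]
                                else:
                                    val = 0.0
                                wt = (
                                    (w[0] if di else 1 - w[0])
                                    * (w[1] if dj else 1 - w[1])
                                    * (w[2] if dk else 1 - w[2])
                                )
                                acc += wt * val
                    expected[i, j, k] = acc
        np.testing.assert_allclose(out.values, expected, atol=1e-5)

    def test_zero_extent_grid_rejected(self, random_volume):
        bad = Volume(np.zeros((0, 4, 4)), 1.0)
        with pytest.raises(ValueError):
            apply_to_image(random_volume, AffineTransform.identity(), bad)


class TestApplyToPoints:
    def test_identity(self, rng):
        p = rng.random((10, 3)) * 10
        out = apply_to_points(p, CompositeTransform.identity(), "forward")
        np.testing.assert_allclose(out, p, atol=1e-12)

    def test_forward_uses_analytic_affine_inverse(self):
        # pull-back x -> 2x; points travel moving -> fixed, i.e. p -> p/2
        doubling = AffineTransform(2 * np.eye(3), 0)
        out = apply_to_points(np.array([[4.0, 6.0, 8.0]]), doubling, "forward")
        np.testing.assert_allclose(out, [[2.0, 3.0, 4.0]], atol=1e-12)

    def test_inverse_direction_applies_pullback_as_is(self):
        doubling = AffineTransform(2 * np.eye(3), 0)
        out = apply_to_points(np.array([[4.0, 6.0, 8.0]]), doubling, "inverse")
        np.testing.assert_allclose(out, [[8.0, 12.0, 16.0]], atol=1e-12)

    def test_roundtrip_under_smooth_field(self, rng):
        field = smooth_random_field((32, 32, 32), 1.0, rng)
        t = CompositeTransform.of(field)
        p = 8 + rng.random((50, 3)) * 16  # keep well inside the grid
        there = apply_to_points(p, t, "inverse")
        back = apply_to_points(there, t, "forward", inversion_tol=0.005)
        assert np.abs(back - p).max() < 2 * 0.005 + 0.01

    def test_out_of_bounds_points_flagged(self, rng):
        field = smooth_random_field((16, 16, 16), 0.5, rng)
        pts = np.array([[5.0, 5.0, 5.0], [100.0, 5.0, 5.0]])
        _, flags = apply_to_points(
            pts, CompositeTransform.of(field), "inverse", return_flags=True
        )
        assert flags.tolist() == [True, False]


class TestCompose:
    def test_identity_neutral(self, rng):
        t = AffineTransform(np.eye(3) + 0.05 * rng.standard_normal((3, 3)), [1, 2, 3])
        c = compose(CompositeTransform.identity(), CompositeTransform.of(t))
        p = rng.random((100, 3)) * 20
        np.testing.assert_allclose(
            transform_points_forward(p, c), t.apply(p), atol=1e-9
        )

    def test_translations_add(self):
        t1 = CompositeTransform.of(AffineTransform.from_translation([1, 0, 0]))
        t2 = CompositeTransform.of(AffineTransform.from_translation([0, 2, 0]))
        c = compose(t2, t1)
        out = transform_points_forward(np.zeros((1, 3)), c)
        np.testing.assert_allclose(out, [[1, 2, 0]], atol=1e-12)

    def test_affine_after_field_equals_sequential(self, rng):
        field = smooth_random_field((16, 16, 16), 1.0, rng)
        aff = AffineTransform(np.eye(3) * 1.1, [0.5, 0, 0])
        c = compose(CompositeTransform.of(aff), CompositeTransform.of(field))
        p = 4 + rng.random((40, 3)) * 8
        seq = aff.apply(transform_points_forward(p, field))
        np.testing.assert_allclose(transform_points_forward(p, c), seq, atol=1e-6)

    def test_associative_on_points(self, rng):
        a = CompositeTransform.of(AffineTransform.from_translation([1, 0, 0]))
        b = CompositeTransform.of(AffineTransform(np.eye(3) * 0.9, 0))
        c = CompositeTransform.of(smooth_random_field((16, 16, 16), 0.5, rng))
        p = 4 + rng.random((30, 3)) * 8
        left = transform_points_forward(p, compose(compose(a, b), c))
        right = transform_points_forward(p, compose(a, compose(b, c)))
        np.testing.assert_allclose(left, right, atol=1e-9)


class TestInvertDfield:
    def test_zero_field(self):
        inv, res = invert_dfield(DisplacementField.zeros((8, 8, 8)), full_output=True)
        assert np.all(inv.vectors == 0)
        assert res == 0.0

    def test_constant_translation_exact(self):
        field = DisplacementField(np.full((3, 8, 8, 8), 1.5), 1.0)
        inv = invert_dfield(field)
        np.testing.assert_allclose(inv.vectors, -1.5, atol=1e-12)

    def test_sinusoidal_residual_small(self):
        n = 32
        x = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")[0].astype(float)
        u = np.stack(
            [np.sin(2 * np.pi * x / 32), np.zeros((n, n, n)), np.zeros((n, n, n))]
        )
        field = DisplacementField(u, 1.0)
        _, res = invert_dfield(field, max_iter=50, tol=1e-4, full_output=True)
        assert res < 0.01

    def test_residual_nonincreasing_with_iterations(self):
        n = 32
        x = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")[0].astype(float)
        u = np.stack(
            [np.sin(2 * np.pi * x / 32), np.zeros((n, n, n)), np.zeros((n, n, n))]
        )
        field = DisplacementField(u, 1.0)
        residuals = [
            invert_dfield(field, max_iter=k, tol=0.0, full_output=True)[1]
            for k in (1, 3, 10, 30)
        ]
        assert all(b <= a + 1e-9 for a, b in zip(residuals, residuals[1:]))


class TestMirror:
    def test_involution_on_points(self, rng):
        grid = Volume(np.zeros((20, 16, 12)), (1.0, 1.5, 2.0), (3.0, -1.0, 0.0))
        for axis in "xyz":
            m = mirror_transform(grid, axis)
            p = rng.random((50, 3)) * 30
            np.testing.assert_allclose(m.apply(m.apply(p)), p, atol=1e-9)

    def test_reflection_about_midplane(self):
        # grid spanning x in [0, 100]: x=10 -> x=90
        grid = Volume(np.zeros((101, 5, 5)), 1.0)
        m = mirror_transform(grid, "x")
        out = m.apply(np.array([[10.0, 2.0, 2.0]]))
        np.testing.assert_allclose(out, [[90.0, 2.0, 2.0]], atol=1e-12)

    def test_double_flip_restores_volume(self, random_volume):
        m = mirror_transform(random_volume, "y")
        once = apply_to_image(random_volume, m, random_volume, interpolation="nearest")
        twice = apply_to_image(once, m, random_volume, interpolation="nearest")
        np.testing.assert_array_equal(twice.values, random_volume.values)


class TestAffineToDfield:
    def test_identity_gives_zero_field(self, random_volume):
        f = affine_to_dfield(AffineTransform.identity(), random_volume)
        assert np.all(f.vectors == 0)

    def test_translation_gives_constant_field(self, random_volume):
        f = affine_to_dfield(AffineTransform.from_translation([1, -2, 3]), random_volume)
        np.testing.assert_allclose(f.vectors[0], 1.0)
        np.testing.assert_allclose(f.vectors[1], -2.0)
        np.testing.assert_allclose(f.vectors[2], 3.0)

    def test_field_resampling_matches_direct_affine(self, rng):
        vol = Volume(
            ndimage.gaussian_filter(rng.random((24, 24, 24)), 2), 1.0
        )
        aff = AffineTransform(np.eye(3) + 0.02 * rng.standard_normal((3, 3)), [0.5, -0.5, 0])
        via_field = apply_to_image(vol, affine_to_dfield(aff, vol), vol)
        direct = apply_to_image(vol, aff, vol)
        np.testing.assert_allclose(via_field.values, direct.values, atol=1e-4)

    def test_total_displacement_folds_composite(self, rng):
        grid = Volume(np.zeros((12, 12, 12)), 1.0)
        aff = AffineTransform.from_translation([1, 0, 0])
        field = DisplacementField(np.full((3, 12, 12, 12), 0.5), 1.0)
        total = total_displacement(CompositeTransform.of(field, aff), grid)
        np.testing.assert_allclose(total.vectors[0], 1.5, atol=1e-9)
        np.testing.assert_allclose(total.vectors[1], 0.5, atol=1e-9)
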