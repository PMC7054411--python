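import numpy as np
import pytest
from scipy import ndimage

import nanoct as nc
from nanoct.synthetic import (
    ContractError,
    PhantomSpec,
    PhantomSpecError,
    Primitive,
)


def _sphere_spec(n=48, r=12.0, mu=2.0, resin=1.0):
    c = (n - 1) / 2
    return PhantomSpec(
        grid_shape=(n, n, n),
        voxel_size_nm=540.0,
        resin_mu=resin,
        primitives=(Primitive("sphere", (c, c, c), (r,), mu),),
    )


class TestPhantom:
    def test_pure_resin_cylinder(self):
        spec = PhantomSpec((32, 32, 32), 540.0, resin_mu=1.5, resin_radius_vox=10.0)
        vol = nc.generate_phantom(spec)
        zz, yy, xx = np.ogrid[0:32, 0:32, 0:32]
        inside = (xx - 15.5) ** 2 + (yy - 15.5) ** 2 <= 100.0
        assert np.all(vol.data[np.broadcast_to(inside, vol.shape)] == 1.5)
        assert np.all(vol.data[~np.broadcast_to(inside, vol.shape)] == 0.0)

    def test_sphere_voxel_count_matches_analytic_volume(self):
        r = 12.0
        vol = nc.generate_phantom(_sphere_spec(r=r))
        count = int(np.count_nonzero(vol.data == 2.0))
        assert count == pytest.approx(4 / 3 * np.pi * r**3, rel=0.02)

    def test_deterministic(self):
        spec = nc.default_phantom_spec(24, 540.0, seed=7)
        a = nc.generate_phantom(spec)
        b = nc.generate_phantom(spec)
        np.testing.assert_array_equal(a.data, b.data)

    def test_out_of_bounds_primitive_rejected(self):
        spec = PhantomSpec(
            (16, 16, 16), 540.0, 1.0,
            primitives=(Primitive("sphere", (15.0, 8.0, 8.0), (4.0,), 2.0),),
        )
        with pytest.raises(PhantomSpecError):
            nc.generate_phantom(spec)

    def test_later_primitives_overwrite(self):
        c = 7.5
        spec = PhantomSpec(
            (16, 16, 16), 540.0, 0.5,
            primitives=(
                Primitive("sphere", (c, c, c), (5.0,), 2.0),
                Primitive("sphere", (c, c, c), (2.0,), 9.0),
            ),
        )
        vol = nc.generate_phantom(spec)
        assert vol.data[8, 8, 8] == 9.0


class TestDrift:
    def test_zero_amplitudes_give_zero_offsets(self):
        comp = nc.DriftComponents(0.0, 5.0, 0.0, 0.0)
        trace = nc.generate_drift(500, comp, seed=3)
        assert np.all(trace.offsets_u == 0.0)
        assert np.all(trace.offsets_v == 0.0)

    def test_jitter_sample_sigma(self):
        comp = nc.DriftComponents(0.0, 5.0, 1.0, 0.0)
        trace = nc.generate_drift(10000, comp, seed=5)
        assert 0.97 < trace.offsets_u.std() < 1.03

    def test_random_walk_variance_grows_linearly(self):
        comp = nc.DriftComponents(0.0, 5.0, 0.0, 1.0)
        n_views, n_traces = 200, 200
        traces = np.stack(
            [nc.generate_drift(n_views, comp, seed=s).offsets_u for s in range(n_traces)]
        )
        var_k = traces.var(axis=0)
        k = np.arange(n_views) + 1.0
        slope = (k @ var_k) / (k @ k)  # least squares through the origin
        assert slope == pytest.approx(1.0, rel=0.10)

    def test_smooth_amplitude_is_peak_normalised(self):
        comp = nc.DriftComponents(3.0, 5.0, 0.0, 0.0)
        trace = nc.generate_drift(360, comp, seed=2)
        assert np.abs(trace.offsets_u).max() == pytest.approx(3.0, rel=1e-9)

    def test_determinism(self):
        comp = nc.DriftComponents(2.0, 5.0, 0.5, 0.1)
        a = nc.generate_drift(100, comp, seed=9)
        b = nc.generate_drift(100, comp, seed=9)
        np.testing.assert_array_equal(a.offsets_u, b.offsets_u)
        np.testing.assert_array_equal(a.offsets_v, b.offsets_v)


class TestProjector:
    def test_empty_volume_gives_unit_transmission(self, geom48):
        vol = nc.Volume.centred(np.zeros((32, 32, 32), dtype=np.float32), 540.0)
        stack = nc.project_cone_beam(vol, geom48, nc.make_angular_grid(4, 360.0))
        np.testing.assert_array_equal(stack.images, 1.0)

    def test_central_ray_matches_analytic_chord(self):
        """Central-pixel transmission of a centred sphere equals exp(−µ·2r)."""
        n, r, mu = 64, 20.0, 10.0
        vol = nc.generate_phantom(_sphere_spec(n=n, r=r, mu=mu, resin=0.0))
        # odd detector so one pixel row/column passes through the axis
        geom = nc.ConeBeamGeometry.from_effective_pixel(540.0, 97, 97, sod_mm=0.6)
        stack = nc.project_cone_beam(vol, geom, nc.make_angular_grid(2, 360.0))
        chord_mm = 2 * r * 540e-6
        expected = np.exp(-mu * chord_mm)
        assert stack.images[0, 48, 48] == pytest.approx(expected, rel=0.01)

    def test_integer_drift_is_exact_pixel_shift(self, phantom48, geom48):
        """Detector drift is a pure resampling: shifting the grid by whole
        and fractional amounts that differ by an integer gives identical rays."""
        angles = nc.make_angular_grid(1, 360.0)

        def at(du):
            drift = nc.DriftTrace(
                np.array([du]), np.zeros(1), nc.DriftComponents(0, 5, 0, 0)
            )
            return nc.project_cone_beam(phantom48, geom48, angles, drift).images[0]

        np.testing.assert_array_equal(
            at(2.7)[:, 10:-10], np.roll(at(0.7), 2, axis=1)[:, 10:-10]
        )

    def test_drift_equals_shifted_projection(self, geom48):
        """A view recorded with drift (Δu, 0) is the zero-drift view shifted +Δu.

        Uses a smooth Gaussian-blob object and cubic volume interpolation so
        the spline-shift oracle is accurate at the tolerance being checked.
        """
        n = 48
        zz, yy, xx = np.mgrid[0:n, 0:n, 0:n].astype(float)
        c = (n - 1) / 2
        rng = np.random.default_rng(0)
        data = np.zeros((n, n, n))
        for _ in range(6):
            cx, cy, cz = rng.uniform(c - 5, c + 5, 3)
            s = rng.uniform(2.5, 3.5)
            data += rng.uniform(5, 15) * np.exp(
                -((xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2) / (2 * s * s)
            )
        vol = nc.Volume.centred(data.astype(np.float32), 540.0)
        du = 2.7
        angles = nc.make_angular_grid(2, 360.0)
        base = nc.project_cone_beam(vol, geom48, angles, interp_order=3)
        drift = nc.DriftTrace(
            np.array([du, 0.0]), np.zeros(2), nc.DriftComponents(0, 5, 0, 0)
        )
        moved = nc.project_cone_beam(vol, geom48, angles, drift, interp_order=3)
        shifted = ndimage.shift(base.images[0].astype(float), (0, du), order=3)
        interior = (slice(8, -8), slice(8, -8))
        dyn = np.ptp(base.images[0])
        assert np.abs(moved.images[0][interior] - shifted[interior]).max() < 1e-3 * dyn

    def test_log_transmission_linear_in_mu(self, phantom48, geom48):
        angles = nc.make_angular_grid(3, 360.0)
        s1 = nc.project_cone_beam(phantom48, geom48, angles)
        doubled = nc.Volume.centred(2.0 * phantom48.data, phantom48.voxel_size_nm)
        s2 = nc.project_cone_beam(doubled, geom48, angles)
        od1 = -np.log(s1.images.astype(np.float64))
        od2 = -np.log(s2.images.astype(np.float64))
        np.testing.assert_allclose(od2, 2 * od1, rtol=2e-5, atol=2e-5)

    def test_opposed_views_mirror(self, phantom48):
        """Over a full turn, view(θ+180°) is view(θ) mirrored in u (small cone)."""
        geom = nc.ConeBeamGeometry.from_effective_pixel(540.0, 72, 72, sod_mm=2.4)
        angles = nc.make_angular_grid(2, 360.0)  # 0° and 180°
        stack = nc.project_cone_beam(phantom48, geom, angles)
        a = stack.images[0].astype(float)
        b = stack.images[1, :, ::-1].astype(float)
        assert np.abs(a - b).max() < 0.01 * np.ptp(a)

    def test_voxel_detector_mismatch_rejected(self, phantom48):
        geom = nc.ConeBeamGeometry.from_effective_pixel(700.0, 72, 72)
        with pytest.raises(ContractError):
            nc.project_cone_beam(phantom48, geom, nc.make_angular_grid(2, 360.0))


class TestNoiseAndFlats:
    def test_infinite_flux_limit_preserves_transmission(self, clean_stack48):
        out = nc.apply_noise_and_flats(clean_stack48, i0=1.0e4, poisson=False)
        trans = (out.images - out.dark) / (out.flat - out.dark)
        np.testing.assert_allclose(
            trans, clean_stack48.images.astype(np.float64), atol=1e-9
        )

    def test_uniform_field_unchanged_by_fresnel_term(self, geom48):
        ones = np.ones((2, 72, 72), dtype=np.float32)
        stack = nc.ProjectionStack(ones, geom48, nc.make_angular_grid(2, 360.0))
        out = nc.apply_noise_and_flats(stack, i0=1000.0, fresnel_strength=5.0, poisson=False)
        trans = (out.images - out.dark) / (out.flat - out.dark)
        np.testing.assert_allclose(trans, 1.0, atol=1e-9)

    def test_poisson_counting_statistics(self):
        """Mean ≈ i0 and dispersion index ≈ 1 over 10⁶ uniform pixels."""
        geom = nc.ConeBeamGeometry.from_effective_pixel(540.0, 100, 100)
        ones = np.ones((100, 100, 100), dtype=np.float32)
        stack = nc.ProjectionStack(ones, geom, nc.make_angular_grid(100, 360.0))
        out = nc.apply_noise_and_flats(stack, i0=1.0e4, seed=21)
        expected = out.flat[None].astype(np.float64)  # i0 × vignette
        assert out.images.mean() == pytest.approx(1.0e4, rel=0.02)
        dispersion = np.mean((out.images - expected) ** 2 / expected)
        assert 0.95 < dispersion < 1.05

    def test_determinism(self, clean_stack48):
        a = nc.apply_noise_and_flats(clean_stack48, i0=5000.0, seed=3)
        b = nc.apply_noise_and_flats(clean_stack48, i0=5000.0, seed=3)
        np.testing.assert_array_equal(a.images, b.images)
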