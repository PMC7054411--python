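import numpy as np
import pytest

import nanoct as nc
from nanoct.synthetic import ContractError


class TestRampFilter:
    def test_constant_row_killed(self):
        row = np.full((4, 64), 7.0)
        out = nc.ramp_filter_rows(row)
        assert np.abs(out).max() < 1e-6 * 7.0

    def test_linearity(self, rng):
        x = rng.normal(size=(3, 50))
        y = rng.normal(size=(3, 50))
        lhs = nc.ramp_filter_rows(3.0 * x + y)
        rhs = 3.0 * nc.ramp_filter_rows(x) + nc.ramp_filter_rows(y)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_impulse_response_matches_ramlak_kernel(self):
        """The discrete response equals the closed-form Ram-Lak kernel.

        Oracle: h[0] = 1/4, h[n] = −1/(πn)² for odd n, 0 for even n (unit
        spacing), whose FFT at Nyquist tends to the analytic |k| = 1/2.
        """
        big = 1 << 20
        m = np.minimum(np.arange(big), big - np.arange(big))
        h = np.zeros(big)
        h[0] = 0.25
        odd = m % 2 == 1
        h[odd] = -1.0 / (np.pi**2 * m[odd] ** 2)
        nyquist = np.fft.rfft(h)[-1].real
        assert nyquist == pytest.approx(0.5, abs=1e-6)

        n = 512
        imp = np.zeros((1, n))
        imp[0, n // 2] = 1.0
        resp = nc.ramp_filter_rows(imp, "ramlak")[0]
        idx = np.arange(n) - n // 2
        kernel = np.zeros(n)
        kernel[n // 2] = 0.25
        odd = np.abs(idx) % 2 == 1
        kernel[odd] = -1.0 / (np.pi**2 * idx[odd] ** 2)
        assert np.abs(resp - kernel).max() < 1e-6

    def test_apodized_variants_reduce_high_frequencies(self, rng):
        x = rng.normal(size=(2, 64))
        e_ram = np.sum(nc.ramp_filter_rows(x, "ramlak") ** 2)
        e_hann = np.sum(nc.ramp_filter_rows(x, "hann-ramp") ** 2)
        e_shepp = np.sum(nc.ramp_filter_rows(x, "shepp-logan") ** 2)
        assert e_hann < e_shepp < e_ram

    def test_unknown_filter_rejected(self):
        with pytest.raises(ValueError):
            nc.ramp_filter_rows(np.ones((2, 8)), "butterworth")


class TestShiftProjection:
    def test_zero_shift_is_identity(self, rng):
        img = rng.normal(size=(20, 20))
        np.testing.assert_array_equal(nc.shift_projection(img, 0.0, 0.0), img)

    def test_integer_shift_equals_roll(self, rng):
        img = rng.normal(size=(24, 24))
        out = nc.shift_projection(img, 3.0, -2.0)
        np.testing.assert_allclose(out, np.roll(img, (-2, 3), axis=(0, 1)), atol=1e-9)

    @pytest.mark.parametrize(
        "method, tol",
        [("fourier", 1e-4), ("spline", 1e-3)],  # cubic splines are not all-pass
    )
    def test_subpixel_round_trip(self, rng, method, tol):
        from scipy import fft as sp_fft

        # band-limited image, as real projections are after source blur
        spec = sp_fft.fft2(rng.normal(size=(32, 32)))
        fy = np.abs(sp_fft.fftfreq(32))[:, None]
        fx = np.abs(sp_fft.fftfreq(32))[None, :]
        spec[(fy > 0.15) | (fx > 0.15)] = 0
        img = 20.0 * sp_fft.ifft2(spec).real
        back = nc.shift_projection(
            nc.shift_projection(img, 1.3, -0.7, method=method), -1.3, 0.7, method=method
        )
        interior = (slice(4, -4), slice(4, -4))
        rmse = np.sqrt(np.mean((back[interior] - img[interior]) ** 2))
        assert rmse < tol * np.ptp(img)

    def test_oversized_shift_rejected(self):
        with pytest.raises(ValueError):
            nc.shift_projection(np.ones((16, 16)), 9.0)


class TestFdk:
    def test_zero_projections_give_zero_volume(self, geom48):
        stack = nc.ProjectionStack(
            np.ones((12, 72, 72), dtype=np.float32), geom48,
            nc.make_angular_grid(12, 360.0),
        )
        vol = nc.fdk_reconstruct(stack, nc.ReconConfig(output_shape=(16, 16, 16)))
        assert np.abs(vol.data).max() < 1e-6

    def test_homogeneous_sphere_interior_value(self):
        """Interior of a reconstructed uniform sphere reads the true µ."""
        from nanoct.benchmarks import sphere_accuracy_benchmark

        res = sphere_accuracy_benchmark(n=48, n_views=120, radius_vox=15.0, mu=10.0)
        assert res["rel_error"] < 0.05

    def test_known_offsets_cancel_drift(self, phantom48, geom48):
        """Compensating with the true drift recovers the drift-free volume."""
        angles = nc.make_angular_grid(60, 360.0)
        drift = nc.generate_drift(
            60, nc.DriftComponents(smooth_amplitude=3.0, jitter_sigma=0.5), seed=4
        )
        clean = nc.project_cone_beam(phantom48, geom48, angles)
        moved = nc.project_cone_beam(phantom48, geom48, angles, drift)
        shape = (32, 48, 48)
        ref = nc.fdk_reconstruct(clean, nc.ReconConfig(output_shape=shape))
        offsets = np.column_stack([drift.offsets_u, drift.offsets_v])
        comp = nc.fdk_reconstruct(
            moved, nc.ReconConfig(per_view_offsets=offsets, output_shape=shape)
        )
        mu_range = np.ptp(phantom48.data)
        rmse = np.sqrt(np.mean((comp.data - ref.data) ** 2))
        assert rmse < 0.02 * mu_range

    def test_linear_in_log_projections(self, clean_stack48):
        logp = -np.log(clean_stack48.normalized().astype(np.float64))
        cfg = nc.ReconConfig(output_shape=(8, 32, 32))
        v1 = nc.fdk_reconstruct(clean_stack48, cfg, log_projs=logp)
        v2 = nc.fdk_reconstruct(clean_stack48, cfg, log_projs=2.0 * logp)
        np.testing.assert_allclose(v2.data, 2.0 * v1.data, atol=1e-4 * np.abs(v1.data).max())

    def test_quarter_rotation_equivariance(self, phantom48, geom48):
        """Reconstructing a 90°-rotated phantom yields the rotated volume."""
        angles = nc.make_angular_grid(90, 360.0)
        shape = (16, 48, 48)
        rot = nc.Volume.centred(
            np.rot90(phantom48.data, k=1, axes=(1, 2)).copy(), phantom48.voxel_size_nm
        )
        rec = nc.fdk_reconstruct(
            nc.project_cone_beam(phantom48, geom48, angles),
            nc.ReconConfig(output_shape=shape),
        )
        rec_rot = nc.fdk_reconstruct(
            nc.project_cone_beam(rot, geom48, angles), nc.ReconConfig(output_shape=shape)
        )
        expected = np.rot90(rec.data, k=1, axes=(1, 2))
        rmse = np.sqrt(np.mean((rec_rot.data - expected) ** 2))
        assert rmse < 0.02 * np.ptp(rec.data)

    def test_error_decreases_with_view_count(self):
        """Reconstruction RMSE drops monotonically as views double 45→90→180."""
        n = 32
        phantom = nc.generate_phantom(nc.default_phantom_spec(n, 540.0, seed=2))
        geom = nc.ConeBeamGeometry.from_effective_pixel(540.0, 48, 48, sod_mm=0.6)
        zz, yy, xx = np.ogrid[0:n, 0:n, 0:n]
        c = (n - 1) / 2
        mask = ((xx - c) ** 2 + (yy - c) ** 2 <= (0.4 * n) ** 2) & (np.abs(zz - c) < 0.3 * n)
        errs = []
        for n_views in (45, 90, 180):
            stack = nc.project_cone_beam(phantom, geom, nc.make_angular_grid(n_views, 360.0))
            vol = nc.fdk_reconstruct(stack, nc.ReconConfig(output_shape=(n, n, n)))
            errs.append(np.sqrt(np.mean((vol.data[mask] - phantom.data[mask]) ** 2)))
        assert errs[0] > errs[1] > errs[2]

    def test_shape_mismatch_rejected(self, clean_stack48):
        with pytest.raises(ContractError):
            nc.fdk_reconstruct(clean_stack48, log_projs=np.zeros((3, 72, 72)))
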