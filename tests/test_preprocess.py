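import numpy as np
import pytest
from scipy import ndimage

import nanoct as nc
from nanoct.preprocess import EPS, paganin_filter_response


class TestFlatField:
    def test_flat_input_gives_unity(self, rng):
        flat = rng.uniform(900, 1100, (32, 32))
        out, flagged = nc.flat_field_normalize(flat, flat, 0.0)
        np.testing.assert_allclose(out, 1.0, rtol=1e-6)
        assert not flagged.any()

    def test_dark_input_floors_at_epsilon(self, rng):
        dark = rng.uniform(90, 110, (16, 16))
        out, _ = nc.flat_field_normalize(dark, dark + 500.0, dark)
        np.testing.assert_array_equal(out, np.float32(EPS))

    def test_half_mixture(self, rng):
        flat = rng.uniform(900, 1100, (16, 16))
        dark = rng.uniform(40, 60, (16, 16))
        raw = 0.5 * flat + 0.5 * dark
        out, _ = nc.flat_field_normalize(raw, flat, dark)
        np.testing.assert_allclose(out, 0.5, rtol=1e-5)

    def test_dead_pixel_flagged_and_median_filled(self):
        flat = np.full((8, 8), 1000.0)
        flat[3, 4] = 0.0  # dead: flat − dark not positive
        raw = np.full((8, 8), 500.0)
        out, flagged = nc.flat_field_normalize(raw, flat, 0.0)
        assert flagged[3, 4] and flagged.sum() == 1
        assert out[3, 4] == pytest.approx(0.5, rel=1e-6)  # neighbours' median


class TestPaganin:
    def _params(self, delta=1e-7, mu=10.0):
        return nc.PhaseRetrievalParams(
            energy_kev=20.0, delta=delta, mu_per_mm=mu,
            propagation_dist_mm=190.5, magnification=318.5, eff_pixel_nm=540.0,
        )

    def test_zero_delta_is_pure_attenuation(self, rng):
        trans = rng.uniform(0.3, 1.0, (40, 56))
        p = self._params(delta=0.0)
        out = nc.paganin_retrieve(trans, p)
        np.testing.assert_allclose(out, -np.log(trans) / p.mu_per_mm, atol=1e-12)

    def test_uniform_transmission_any_delta(self):
        p = self._params(delta=5e-7)
        trans = np.full((32, 32), np.exp(-0.8))
        out = nc.paganin_retrieve(trans, p)
        np.testing.assert_allclose(out, 0.8 / p.mu_per_mm, rtol=1e-9)

    def test_single_frequency_response_matches_closed_form(self):
        """A small cosine modulation is attenuated by 1/(1 + (R δ/µ)4π²f²)."""
        p = self._params(delta=1e-6)
        n, cycles, a = 128, 12, 1e-3
        x = np.arange(n)
        trans = 1.0 + a * np.cos(2 * np.pi * cycles * x / n)[None, :].repeat(32, 0)
        out = nc.paganin_retrieve(trans, p, pad=False)
        filtered = np.exp(-p.mu_per_mm * out)  # undo log to read the modulation
        amp = 2 * np.abs(np.fft.rfft(filtered[0])[cycles]) / n
        f_mm = cycles / (n * p.eff_pixel_nm * 1e-6)  # cycles per mm
        expected = a * paganin_filter_response(f_mm, p)
        assert amp == pytest.approx(expected, abs=1e-4 * a)

    def test_filter_is_monotone_low_pass_with_unit_dc(self):
        p = self._params(delta=1e-6)
        f = np.linspace(0, 2000, 500)
        resp = paganin_filter_response(f, p)
        assert resp[0] == 1.0
        assert np.all(np.diff(resp) <= 0)

    def test_commutes_with_mirroring(self, rng):
        trans = rng.uniform(0.4, 1.0, (48, 48))
        p = self._params(delta=1e-6)
        a = nc.paganin_retrieve(trans[::-1, ::-1], p, pad=False)
        b = nc.paganin_retrieve(trans, p, pad=False)[::-1, ::-1]
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_clip_count_reported(self):
        p = self._params(delta=0.0)
        trans = np.full((8, 8), 0.5)
        out, n_clipped = nc.paganin_retrieve(trans, p, full_output=True)
        assert n_clipped == 0


class TestDeblur:
    def test_delta_psf_identity(self, rng):
        img = rng.normal(size=(40, 40))
        out = nc.gureyev_deblur(img, nc.DeblurParams(alpha=0.0, psf_sigma=0.0))
        np.testing.assert_allclose(out, img, atol=1e-10)

    def test_linearity(self, rng):
        x = rng.normal(size=(32, 32))
        y = rng.normal(size=(32, 32))
        p = nc.DeblurParams(alpha=1e-3, psf_sigma=1.5)
        lhs = nc.gureyev_deblur(2.5 * x + y, p)
        rhs = 2.5 * nc.gureyev_deblur(x, p) + nc.gureyev_deblur(y, p)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_restores_blurred_projection(self, clean_stack48):
        """Matched-σ deconvolution beats the blurred image against the truth."""
        sharp = -np.log(clean_stack48.images[0].astype(np.float64))
        blurred = ndimage.gaussian_filter(sharp, 2.0)
        restored = nc.gureyev_deblur(blurred, nc.DeblurParams(alpha=1e-3, psf_sigma=2.0))
        rmse_blur = np.sqrt(np.mean((blurred - sharp) ** 2))
        rmse_rest = np.sqrt(np.mean((restored - sharp) ** 2))
        assert rmse_rest < rmse_blur

    def test_unregularized_inversion_warns(self, rng):
        with pytest.warns(UserWarning, match="amplifies noise"):
            nc.gureyev_deblur(rng.normal(size=(16, 16)), nc.DeblurParams(0.0, 1.0))


class TestChain:
    def test_homogeneous_object_thickness_recovery(self, clean_stack48):
        """Phase retrieval + deblur preserve projected thickness away from edges."""
        p = nc.PhaseRetrievalParams(
            delta=1e-7, mu_per_mm=10.0, propagation_dist_mm=190.5,
            magnification=318.5, eff_pixel_nm=540.0,
        )
        out = nc.preprocess_stack(
            clean_stack48, p, nc.DeblurParams(alpha=1e-2, psf_sigma=0.5)
        )
        ref = -np.log(clean_stack48.normalized().astype(np.float64))
        interior = np.abs(ndimage.gaussian_gradient_magnitude(ref[0], 1.0)) < 0.02
        interior &= ref[0] > 0.05
        assert interior.sum() > 100
        err = np.abs(out[0][interior] - ref[0][interior]) / ref[0][interior]
        assert np.median(err) < 0.02
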