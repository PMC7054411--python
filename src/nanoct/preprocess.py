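"""Projection preprocessing: flat-field normalisation, single-distance
(Paganin / TIE-homogeneous) phase retrieval, and regularized deblurring.

Phase retrieval assumes a homogeneous object (fixed delta/mu ratio of the
complex refractive index n = 1 − delta + i*beta, mu = 4*pi*beta/lambda): the
near-field edge enhancement recorded at an effective propagation distance
R_eff = R_detector / M is inverted by a single low-pass Fourier filter,

    T(x, y) = -(1/mu) ln( F^-1 [ F(I/I0) / (1 + (R_eff*delta/mu) * 4*pi^2*|f|^2) ] ),

yielding a projected-thickness image.  The polychromatic 60 kVp spectrum of
the instrument is reduced to a single detected mean energy (default 20 keV).

Deblurring is a Wiener-type regularized inversion of an assumed Gaussian
point-spread function with weight ``alpha``; alpha and the phase coefficients
are image-quality tuning parameters, not physical constants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft

__all__ = [
    "PhaseRetrievalParams",
    "DeblurParams",
    "flat_field_normalize",
    "paganin_retrieve",
    "gureyev_deblur",
    "preprocess_stack",
]

EPS = 1e-6  # positivity floor for transmissions

#: hc in keV·nm — lambda[nm] = KEV_NM / E[keV]
KEV_NM = 1.2398


@dataclass(frozen=True)
class PhaseRetrievalParams:
    """Inputs of the single-distance phase-retrieval filter.

    delta/mu acts as a single tunable ratio (length² per unit frequency²);
    neither coefficient is tabulated for the instrument, so defaults target a
    filter length of a few pixels at the fixture geometry.
    """

    energy_kev: float = 20.0
    delta: float = 1e-7
    mu_per_mm: float = 10.0  # linear attenuation of the homogeneous material
    propagation_dist_mm: float = 100.0  # detector-side distance (SDD − SOD)
    magnification: float = 100.0
    eff_pixel_nm: float = 540.0

    def __post_init__(self) -> None:
        if self.energy_kev <= 0:
            raise ValueError("energy must be > 0")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.mu_per_mm <= 0:
            raise ValueError("mu must be > 0")
        if self.magnification < 1:
            raise ValueError("magnification must be >= 1")
        if self.eff_pixel_nm <= 0:
            raise ValueError("effective pixel size must be > 0")

    @property
    def wavelength_nm(self) -> float:
        return KEV_NM / self.energy_kev

    @property
    def r_eff_mm(self) -> float:
        """Effective propagation distance on the object scale."""
        return self.propagation_dist_mm / self.magnification


@dataclass(frozen=True)
class DeblurParams:
    alpha: float = 1e-3  # regularization weight
    psf_sigma: float = 1.0  # Gaussian PSF width, detector pixels

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.psf_sigma < 0:
            raise ValueError("alpha and psf_sigma must be >= 0")


# --------------------------------------------------------------------------- #
# Flat-field
# --------------------------------------------------------------------------- #

def flat_field_normalize(
    raw: np.ndarray, flat: np.ndarray, dark: np.ndarray | float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """(raw − dark) / (flat − dark), floored at a small positive epsilon.

    Pixels where flat − dark is not positive cannot be normalised; they are
    returned flagged and filled with the median of their 4-neighbours.

    Returns
    -------
    trans : float32 transmission image
    flagged : boolean mask of unnormalisable pixels
    """
    raw = np.asarray(raw, dtype=np.float64)
    flat = np.asarray(flat, dtype=np.float64)
    dark = np.broadcast_to(np.asarray(dark, dtype=np.float64), raw.shape)
    if flat.shape != raw.shape:
        raise ValueError(f"shape mismatch: raw {raw.shape} vs flat {flat.shape}")
    denom = flat - dark
    flagged = denom <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        trans = (raw - dark) / denom
    trans = np.where(flagged, np.nan, trans)
    if flagged.any():
        # 4-neighbour median fill (NaN-aware; isolated bad pixels assumed)
        shifts = [
            np.roll(trans, 1, axis=0), np.roll(trans, -1, axis=0),
            np.roll(trans, 1, axis=1), np.roll(trans, -1, axis=1),
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fill = np.nanmedian(np.stack(shifts), axis=0)
        fill = np.where(np.isnan(fill), 1.0, fill)
        trans = np.where(flagged, fill, trans)
    return np.maximum(trans, EPS).astype(np.float32), flagged


# --------------------------------------------------------------------------- #
# Phase retrieval
# --------------------------------------------------------------------------- #

def _pad_symmetric(img: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
    ny, nx = img.shape
    py = sp_fft.next_fast_len(ny) - ny
    px = sp_fft.next_fast_len(nx) - nx
    if py or px:
        img = np.pad(img, ((0, py), (0, px)), mode="symmetric")
    return img, (ny, nx)


def paganin_retrieve(
    trans: np.ndarray,
    params: PhaseRetrievalParams,
    pad: bool = True,
    full_output: bool = False,
):
    """Single-distance phase retrieval of a flat-field-normalised projection.

    Returns the projected thickness T in mm (thickness-proportional image);
    the filter has unit gain at zero frequency, so ``delta = 0`` reduces
    exactly to the pure-attenuation limit −ln(trans)/mu.

    With ``full_output=True`` also returns the number of pixels clipped to
    the positivity floor before the logarithm.
    """
    trans = np.asarray(trans, dtype=np.float64)
    if trans.ndim != 2:
        raise ValueError("expected a 2D projection")
    if np.any(trans <= 0):
        raise ValueError("transmission must be positive (flat-field first)")

    if pad:
        work, orig = _pad_symmetric(trans)
    else:
        work, orig = trans, trans.shape

    pix_mm = params.eff_pixel_nm * 1e-6
    fy = sp_fft.fftfreq(work.shape[0], d=pix_mm)  # cycles / mm, object scale
    fx = sp_fft.rfftfreq(work.shape[1], d=pix_mm)
    factor = params.r_eff_mm * params.delta / params.mu_per_mm  # mm²
    denom = 1.0 + factor * 4.0 * np.pi**2 * (fy[:, None] ** 2 + fx[None, :] ** 2)

    filtered = sp_fft.irfft2(sp_fft.rfft2(work) / denom, s=work.shape)
    filtered = filtered[: orig[0], : orig[1]]
    n_clipped = int(np.count_nonzero(filtered < EPS))
    thickness = -np.log(np.maximum(filtered, EPS)) / params.mu_per_mm
    if full_output:
        return thickness, n_clipped
    return thickness


def paganin_filter_response(f_cycles_per_mm: np.ndarray, params: PhaseRetrievalParams) -> np.ndarray:
    """Closed-form radial frequency response 1 / (1 + (R_eff δ/µ)·4π²f²)."""
    f = np.asarray(f_cycles_per_mm, dtype=float)
    factor = params.r_eff_mm * params.delta / params.mu_per_mm
    return 1.0 / (1.0 + factor * 4.0 * np.pi**2 * f**2)


# --------------------------------------------------------------------------- #
# Deblurring
# --------------------------------------------------------------------------- #

def gureyev_deblur(
    img: np.ndarray, params: DeblurParams, pad: bool = True
) -> np.ndarray:
    """Regularized inverse filtering of an assumed Gaussian PSF.

    out = F⁻¹[ F(img) · H / (H² + alpha) ] with H(f) = exp(−2π²σ²|f|²)
    (H is real and symmetric, so H* = H).  A delta PSF with alpha = 0 is the
    identity; alpha = 0 with a finite PSF is an unregularized inversion and
    triggers a warning because it amplifies noise without bound.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2D image")
    if params.alpha == 0 and params.psf_sigma > 0:
        warnings.warn(
            "unregularized inverse filtering (alpha=0) amplifies noise",
            stacklevel=2,
        )
    if pad:
        work, orig = _pad_symmetric(img)
    else:
        work, orig = img, img.shape
    fy = sp_fft.fftfreq(work.shape[0])  # cycles / pixel
    fx = sp_fft.rfftfreq(work.shape[1])
    h = np.exp(-2.0 * np.pi**2 * params.psf_sigma**2 * (fy[:, None] ** 2 + fx[None, :] ** 2))
    gain = h / (h**2 + params.alpha) if params.alpha > 0 else 1.0 / h
    out = sp_fft.irfft2(sp_fft.rfft2(work) * gain, s=work.shape)
    return out[: orig[0], : orig[1]]


# --------------------------------------------------------------------------- #
# Stack-level chain
# --------------------------------------------------------------------------- #

def preprocess_stack(
    stack,
    phase_params: PhaseRetrievalParams | None = None,
    deblur_params: DeblurParams | None = None,
    deblur_first: bool = False,
):
    """Full projection preprocessing of a :class:`~nanoct.synthetic.ProjectionStack`.

    Flat-field normalises every view, then applies phase retrieval and/or
    deblurring (default order: phase retrieval, then deblurring).  Returns a
    (n_views, n_v, n_u) float32 array in the −ln (line-integral) domain:
    mu × thickness when phase retrieval is enabled, −ln(transmission)
    otherwise — ready for filtered back-projection without double logging.
    """
    trans = stack.normalized()
    out = np.empty_like(trans, dtype=np.float32)
    for i in range(trans.shape[0]):
        img = trans[i].astype(np.float64)
        if deblur_first and deblur_params is not None:
            img = np.maximum(gureyev_deblur(img, deblur_params), EPS)
        if phase_params is not None:
            img = paganin_retrieve(img, phase_params) * phase_params.mu_per_mm
        else:
            img = -np.log(np.maximum(img, EPS))
        if not deblur_first and deblur_params is not None:
            img = gureyev_deblur(img, deblur_params)
        out[i] = img
    return out
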