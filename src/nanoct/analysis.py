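"""Quantitative image analysis: ROI statistics, CNR and line profiles.

CNR between a region of interest and a reference (resin background) region:

    CNR = (µ_ROI − µ_ref) / sqrt(σ²_ROI + σ²_ref)

with sample means and population (1/n) standard deviations over the ROI
pixels.  Reported means are referenced so that the resin background is 0;
line profiles are background-subtracted and normalised to a maximum of 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import polygon2mask

__all__ = [
    "RoiStats",
    "CnrReport",
    "LineProfile",
    "roi_stats",
    "compute_cnr",
    "cnr_report",
    "line_profile",
    "polygon_mask",
]


@dataclass(frozen=True)
class RoiStats:
    mu: float  # mean grey value, image units
    sigma: float  # population standard deviation (1/n)
    n_pixels: int
    label: str = ""


@dataclass(frozen=True)
class CnrReport:
    """Per-ROI referenced statistics against a reference (resin) ROI.

    ``rows`` holds dicts with keys label, mu (referenced: resin mean = 0),
    sigma, cnr.  Referencing changes the reported means, never the CNR.
    """

    rows: tuple[dict, ...]
    reference_label: str

    def as_dict(self) -> dict[str, dict]:
        return {r["label"]: r for r in self.rows}


@dataclass(frozen=True)
class LineProfile:
    positions_um: np.ndarray
    values: np.ndarray  # background-subtracted; max = 1 unless degenerate
    degenerate: bool = False  # no positive value after background subtraction


def roi_stats(img: np.ndarray, mask: np.ndarray, label: str = "") -> RoiStats:
    """Sample mean and population σ of the masked pixels."""
    img = np.asarray(img)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.shape:
        raise ValueError(f"mask shape {mask.shape} != image shape {img.shape}")
    vals = img[mask]
    if vals.size < 2:
        raise ValueError(f"ROI {label!r} must contain at least 2 pixels")
    return RoiStats(
        mu=float(vals.mean()),
        sigma=float(vals.std(ddof=0)),
        n_pixels=int(vals.size),
        label=label,
    )


def compute_cnr(roi: RoiStats, ref: RoiStats) -> float:
    """Contrast-to-noise ratio (µ_ROI − µ_ref)/√(σ²_ROI + σ²_ref).

    The sign is preserved: negative when the ROI is darker than the
    reference.  Undefined when both standard deviations are zero.
    """
    denom = np.hypot(roi.sigma, ref.sigma)
    if denom == 0:
        raise ZeroDivisionError("CNR undefined: both ROIs have zero variance")
    return float((roi.mu - ref.mu) / denom)


def cnr_report(
    img: np.ndarray,
    masks: dict[str, np.ndarray],
    reference_label: str = "resin",
) -> CnrReport:
    """CNR of every ROI against the reference ROI, resin mean referenced to 0."""
    if reference_label not in masks:
        raise ValueError(f"reference ROI {reference_label!r} missing from masks")
    stats = {lbl: roi_stats(img, m, lbl) for lbl, m in masks.items()}
    ref = stats[reference_label]
    rows = []
    for lbl, st in stats.items():
        rows.append(
            {
                "label": lbl,
                "mu": st.mu - ref.mu,  # referenced: resin mean = 0
                "sigma": st.sigma,
                "n_pixels": st.n_pixels,
                "cnr": 0.0 if lbl == reference_label else compute_cnr(st, ref),
            }
        )
    return CnrReport(rows=tuple(rows), reference_label=reference_label)


def line_profile(
    img: np.ndarray,
    p0: tuple[float, float],
    p1: tuple[float, float],
    background: float = 0.0,
    pixel_size_um: float = 1.0,
) -> LineProfile:
    """Background-subtracted, max-normalised grey-value profile along a line.

    ``p0``/``p1`` are (row, col) endpoints inside the image; sampling is
    bilinear at unit-pixel spacing (endpoints inclusive).  When no value is
    positive after background subtraction the normalisation is skipped and
    the profile flagged degenerate.
    """
    img = np.asarray(img, dtype=np.float64)
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    if np.allclose(p0, p1):
        raise ValueError("profile endpoints must differ")
    for p in (p0, p1):
        if np.any(p < 0) or np.any(p > np.array(img.shape) - 1):
            raise ValueError(f"endpoint {tuple(p)} lies outside the image")
    length = float(np.linalg.norm(p1 - p0))
    # unit-pixel spacing along the segment, endpoint included
    t = np.arange(np.floor(length) + 1, dtype=float)
    if t[-1] < length:
        t = np.append(t, length)
    t = t / length
    pts = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
    vals = ndimage.map_coordinates(img, pts.T, order=1, mode="nearest")
    vals = vals - background
    vmax = vals.max()
    degenerate = vmax <= 0
    if not degenerate:
        vals = vals / vmax
    return LineProfile(
        positions_um=t * length * pixel_size_um,
        values=vals,
        degenerate=bool(degenerate),
    )


def polygon_mask(shape: tuple[int, int], vertices) -> np.ndarray:
    """Boolean ROI mask from polygon vertices in (row, col) order."""
    return polygon2mask(shape, np.asarray(vertices, dtype=float))
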