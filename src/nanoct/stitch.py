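"""Combining vertically overlapping partial reconstructions into one volume.

Scans taller than the detector are acquired as a stack of partial volumes
offset along the rotation axis (12 sub-volumes for the overview scan, 7 at
high resolution in the reference acquisition this models).  Adjacent pairs
are registered by a 3D shift vector estimated from normalised
cross-correlation with quadratic subvoxel refinement, then resampled onto a
union grid and blended with a linear ramp across the overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sp_fft
from scipy import ndimage

from .volume import Volume

__all__ = ["StitchError", "ShiftEstimate", "StitchPlan", "estimate_shift_3d", "merge_volumes"]


class StitchError(ValueError):
    """Raised when volumes cannot be stitched as requested."""


@dataclass(frozen=True)
class ShiftEstimate:
    """3D displacement (z, y, x voxels) with its correlation peak value.

    ``low_confidence`` flags a normalised correlation peak below threshold.
    """

    shift: tuple[float, float, float]
    peak_correlation: float
    low_confidence: bool


@dataclass
class StitchPlan:
    """Per-adjacent-pair displacements and blending settings.

    ``shifts[i]`` is the displacement of volume ``order[i+1]`` relative to
    volume ``order[i]`` (voxels, (z, y, x), subvoxel precision).
    """

    shifts: list[tuple[float, float, float]]
    order: list[int] = field(default_factory=list)
    blend_width: int = 8


def estimate_shift_3d(
    vol_a: Volume | np.ndarray,
    vol_b: Volume | np.ndarray,
    peak_threshold: float = 0.2,
) -> ShiftEstimate:
    """Displacement d with vol_b(x) ≈ vol_a(x − d), by cross-correlation.

    Both volumes are mean-subtracted, cross-correlated via zero-padded
    Fourier products, and the integer correlation peak is refined per axis by
    a quadratic three-point fit.  The peak value is normalised by the product
    of the volumes' norms; below ``peak_threshold`` the estimate is flagged
    low-confidence.
    """
    a = np.asarray(vol_a.data if isinstance(vol_a, Volume) else vol_a, dtype=np.float64)
    b = np.asarray(vol_b.data if isinstance(vol_b, Volume) else vol_b, dtype=np.float64)
    if isinstance(vol_a, Volume) and isinstance(vol_b, Volume):
        if not np.isclose(vol_a.voxel_size_nm, vol_b.voxel_size_nm):
            raise StitchError("volumes must share a voxel size")
    if a.ndim != 3 or b.ndim != 3:
        raise StitchError("expected 3D volumes")

    if (a == a.flat[0]).all() or (b == b.flat[0]).all():
        return ShiftEstimate((0.0, 0.0, 0.0), 0.0, True)
    # offset for conditioning only; per-lag means are subtracted exactly below
    a0 = a - a.mean()
    b0 = b - b.mean()
    shape = [sp_fft.next_fast_len(sa + sb - 1) for sa, sb in zip(a.shape, b.shape)]
    fa = sp_fft.rfftn(a0, s=shape)
    fb = sp_fft.rfftn(b0, s=shape)
    fwa = sp_fft.rfftn(np.ones(a.shape), s=shape)
    fwb = sp_fft.rfftn(np.ones(b.shape), s=shape)
    # sliding overlap sums via FFT correlations: zero-mean NCC per lag
    cross = sp_fft.irfftn(fb * np.conj(fa), s=shape)
    sa_ = sp_fft.irfftn(fwb * np.conj(fa), s=shape)  # Σ a over overlap
    sb_ = sp_fft.irfftn(sp_fft.rfftn(b0, s=shape) * np.conj(fwa), s=shape)
    ea = sp_fft.irfftn(fwb * np.conj(sp_fft.rfftn(a0**2, s=shape)), s=shape)
    eb = sp_fft.irfftn(sp_fft.rfftn(b0**2, s=shape) * np.conj(fwa), s=shape)
    n_overlap = sp_fft.irfftn(fwb * np.conj(fwa), s=shape)
    n_overlap = np.maximum(n_overlap, 1.0)
    num = cross - sa_ * sb_ / n_overlap
    var_a = np.maximum(ea - sa_**2 / n_overlap, 0.0)
    var_b = np.maximum(eb - sb_**2 / n_overlap, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ncc = num / np.sqrt(var_a * var_b)
    ncc[~np.isfinite(ncc)] = -np.inf
    min_overlap = 0.1 * min(a.size, b.size)
    ncc[n_overlap < min_overlap] = -np.inf

    peak_idx = np.unravel_index(np.argmax(ncc), ncc.shape)
    peak = float(ncc[peak_idx])
    shift = []
    for ax, idx in enumerate(peak_idx):
        n = shape[ax]
        centred = idx - n if idx > n // 2 else idx  # wrap to signed lag
        if peak >= 1.0 - 1e-6:
            shift.append(float(centred))  # exact match: no refinement needed
            continue
        nb = [list(peak_idx) for _ in range(2)]
        nb[0][ax] = (idx - 1) % n
        nb[1][ax] = (idx + 1) % n
        ym, yp = ncc[tuple(nb[0])], ncc[tuple(nb[1])]
        denom = ym - 2 * peak + yp
        delta = 0.5 * (ym - yp) / denom if (np.isfinite(denom) and denom < 0) else 0.0
        shift.append(centred + float(np.clip(delta, -0.5, 0.5)))
    return ShiftEstimate(tuple(shift), peak, peak < peak_threshold)


def merge_volumes(vols: list[Volume], plan: StitchPlan) -> Volume:
    """Resample shifted partial volumes onto the union grid and blend.

    Overlaps are blended with a linear ramp of ``plan.blend_width`` voxels
    along each volume's boundary in the stacking direction (weights of the
    contributing volumes sum to 1), so identical inputs merge without seams
    and overlapping noisy copies average down.
    """
    if not vols:
        raise StitchError("no volumes to merge")
    order = plan.order or list(range(len(vols)))
    vols = [vols[i] for i in order]
    vox = vols[0].voxel_size_nm
    if any(not np.isclose(v.voxel_size_nm, vox) for v in vols):
        raise StitchError("volumes must share a voxel size")
    if len(vols) == 1:
        return vols[0].copy()
    if len(plan.shifts) != len(vols) - 1:
        raise StitchError("need one shift per adjacent pair")

    # absolute positions (float, (z, y, x)) of each volume's voxel (0,0,0)
    pos = [np.zeros(3)]
    for i, s in enumerate(plan.shifts):
        if vols[i].shape[0] - s[0] < 0:
            raise StitchError(
                f"negative z-overlap after shift between volumes {i} and {i + 1}"
            )
        pos.append(pos[-1] + np.asarray(s, dtype=float))
    pos = np.array(pos)

    lo = np.floor(pos.min(axis=0)).astype(int)
    hi = np.ceil(
        (pos + np.array([v.shape for v in vols])).max(axis=0)
    ).astype(int)
    out_shape = tuple(hi - lo)
    acc = np.zeros(out_shape, dtype=np.float64)
    wacc = np.zeros(out_shape, dtype=np.float64)

    bw = max(1, int(plan.blend_width))
    for v, p in zip(vols, pos):
        data = v.data.astype(np.float64)
        frac = p - np.floor(p)
        if np.any(frac > 1e-9):
            data = ndimage.shift(data, frac, order=1, mode="nearest")
        base = np.floor(p).astype(int) - lo
        # ramp weight along the stacking axis (z)
        nz = data.shape[0]
        wz = np.ones(nz)
        ramp = np.linspace(1.0 / (bw + 1), bw / (bw + 1), bw)
        w_edge = min(bw, nz // 2)
        wz[:w_edge] = ramp[:w_edge]
        wz[nz - w_edge :] = ramp[:w_edge][::-1]
        w = wz[:, None, None]
        sl = tuple(slice(b, b + s) for b, s in zip(base, data.shape))
        acc[sl] += data * w
        wacc[sl] += np.broadcast_to(w, data.shape)

    covered = wacc > 0
    if not covered.all():
        # trim uncovered margins introduced by subvoxel rounding
        idx = np.where(covered)
        sl = tuple(slice(i.min(), i.max() + 1) for i in idx)
        acc, wacc, covered = acc[sl], wacc[sl], covered[sl]
    merged = np.where(covered, acc / np.maximum(wacc, 1e-300), 0.0)

    origin = tuple(
        np.array(vols[0].origin_nm) + lo * vox
    )
    return Volume(merged.astype(np.float32), vox, origin)  # type: ignore[arg-type]
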