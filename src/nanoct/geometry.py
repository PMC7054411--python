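"""Cone-beam acquisition geometry and the closed-form optics arithmetic.

The instrument modelled here is a lens-less "shadow microscope": a nanofocus
X-ray source projects the specimen onto a photon-counting detector with purely
geometric magnification M = SDD/SOD, so the effective (object-side) pixel size
is the physical detector pitch divided by M.  Angles are exposed in degrees and
converted to radians internally; rotation is counter-clockwise viewed from +z,
with the rotation axis along the volume z-axis.  Detector coordinates are
u (horizontal, perpendicular to the rotation axis) and v (vertical), with the
origin at the detector centre and values taken at pixel centres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "InvalidGeometryError",
    "ConeBeamGeometry",
    "AngularGrid",
    "compute_magnification",
    "compute_effective_pixel_size",
    "compute_fov",
    "rayleigh_resolution",
    "make_angular_grid",
]

#: Pixel pitch of a PILATUS 300K-W photon-counting detector, in micrometres.
PILATUS_PITCH_UM = 172.0


class InvalidGeometryError(ValueError):
    """Raised for physically impossible geometry parameters."""


def compute_magnification(sod_mm: float, sdd_mm: float) -> float:
    """Geometric magnification M = SDD / SOD of a point-source projection.

    Parameters
    ----------
    sod_mm : source-to-object (rotation axis) distance in mm.
    sdd_mm : source-to-detector distance in mm.
    """
    if not (0 < sod_mm <= sdd_mm):
        raise InvalidGeometryError(
            f"need 0 < SOD <= SDD, got SOD={sod_mm}, SDD={sdd_mm}"
        )
    return sdd_mm / sod_mm


def compute_effective_pixel_size(det_pitch_um: float, magnification: float) -> float:
    """Object-side pixel size (µm) = detector pitch / magnification."""
    if det_pitch_um <= 0:
        raise InvalidGeometryError(f"detector pitch must be > 0, got {det_pitch_um}")
    if magnification < 1:
        raise InvalidGeometryError(
            f"magnification must be >= 1 for a shadow microscope, got {magnification}"
        )
    return det_pitch_um / magnification


def compute_fov(n_u: int, n_v: int, eff_pixel_um: float) -> tuple[float, float]:
    """Field of view (u, v) in µm covered by an n_u × n_v detector grid."""
    if n_u < 1 or n_v < 1:
        raise InvalidGeometryError("pixel counts must be >= 1")
    if eff_pixel_um <= 0:
        raise InvalidGeometryError("effective pixel size must be > 0")
    return n_u * eff_pixel_um, n_v * eff_pixel_um


def rayleigh_resolution(wavelength_nm: float, numerical_aperture: float) -> float:
    """Rayleigh two-point resolution 0.61 λ / NA of a light-microscope objective.

    Returns the resolution in the same length unit as ``wavelength_nm``.
    """
    if wavelength_nm <= 0:
        raise InvalidGeometryError("wavelength must be > 0")
    if not (0 < numerical_aperture <= 1.5):
        raise InvalidGeometryError(
            f"numerical aperture must lie in (0, 1.5], got {numerical_aperture}"
        )
    return 0.61 * wavelength_nm / numerical_aperture


@dataclass(frozen=True)
class AngularGrid:
    """Evenly spaced view angles, end-exclusive over the scan span.

    End-exclusivity avoids duplicating the 0°/360° view over a full turn:
    angle i equals ``i * span_deg / n_views``.
    """

    n_views: int
    span_deg: float

    def __post_init__(self) -> None:
        if self.n_views < 1:
            raise InvalidGeometryError("n_views must be >= 1")
        if self.span_deg <= 0:
            raise InvalidGeometryError("span must be > 0")

    @property
    def spacing_deg(self) -> float:
        return self.span_deg / self.n_views

    @property
    def angles_deg(self) -> np.ndarray:
        return np.arange(self.n_views) * self.spacing_deg

    @property
    def angles_rad(self) -> np.ndarray:
        return np.deg2rad(self.angles_deg)


def make_angular_grid(n_views: int, span_deg: float = 360.0) -> AngularGrid:
    """Angular grid of ``n_views`` views evenly distributed over ``span_deg``."""
    return AngularGrid(n_views=n_views, span_deg=span_deg)


@dataclass(frozen=True)
class ConeBeamGeometry:
    """Circular cone-beam scan geometry.

    Parameters
    ----------
    sod_mm, sdd_mm :
        Source-to-rotation-axis and source-to-detector distances (mm).
    det_pitch_um :
        Physical detector pixel pitch (µm).
    det_n_u, det_n_v :
        Detector pixel counts, horizontal × vertical.
    rot_axis_offset_px :
        Signed horizontal offset (detector pixels) of the rotation-axis
        projection from the detector centre column — the quantity a global
        "centre shift" correction removes.
    """

    sod_mm: float
    sdd_mm: float
    det_pitch_um: float
    det_n_u: int
    det_n_v: int
    rot_axis_offset_px: float = 0.0

    def __post_init__(self) -> None:
        compute_magnification(self.sod_mm, self.sdd_mm)  # validates distances
        if self.det_pitch_um <= 0:
            raise InvalidGeometryError("detector pitch must be > 0")
        if self.det_n_u < 1 or self.det_n_v < 1:
            raise InvalidGeometryError("detector pixel counts must be >= 1")

    @property
    def magnification(self) -> float:
        return compute_magnification(self.sod_mm, self.sdd_mm)

    @property
    def eff_pixel_um(self) -> float:
        return compute_effective_pixel_size(self.det_pitch_um, self.magnification)

    @property
    def eff_pixel_nm(self) -> float:
        return self.eff_pixel_um * 1e3

    @property
    def fov_um(self) -> tuple[float, float]:
        return compute_fov(self.det_n_u, self.det_n_v, self.eff_pixel_um)

    @classmethod
    def from_effective_pixel(
        cls,
        eff_pixel_nm: float,
        det_n_u: int,
        det_n_v: int,
        sod_mm: float = 0.6,
        det_pitch_um: float = PILATUS_PITCH_UM,
        rot_axis_offset_px: float = 0.0,
    ) -> "ConeBeamGeometry":
        """Geometry with SDD chosen to realise a target effective pixel size.

        The instrument's true distances are free parameters; only the effective
        pixel size is constrained.  SDD = SOD * pitch / eff_pixel.
        """
        if eff_pixel_nm <= 0:
            raise InvalidGeometryError("effective pixel size must be > 0")
        magnification = det_pitch_um * 1e3 / eff_pixel_nm
        if magnification < 1:
            raise InvalidGeometryError(
                "effective pixel size exceeds the detector pitch"
            )
        return cls(
            sod_mm=sod_mm,
            sdd_mm=sod_mm * magnification,
            det_pitch_um=det_pitch_um,
            det_n_u=det_n_u,
            det_n_v=det_n_v,
            rot_axis_offset_px=rot_axis_offset_px,
        )

    def binned(self, factor: int) -> "ConeBeamGeometry":
        """Geometry after factor×factor detector binning (coarse grid)."""
        if factor < 1:
            raise InvalidGeometryError("binning factor must be >= 1")
        return replace(
            self,
            det_pitch_um=self.det_pitch_um * factor,
            det_n_u=self.det_n_u // factor,
            det_n_v=self.det_n_v // factor,
            rot_axis_offset_px=self.rot_axis_offset_px / factor,
        )

    # -- sidecar serialisation -------------------------------------------------

    def to_dict(self, grid: AngularGrid | None = None) -> dict:
        d = {
            "sod_mm": float(self.sod_mm),
            "sdd_mm": float(self.sdd_mm),
            "det_pitch_um": float(self.det_pitch_um),
            "det_n_u": int(self.det_n_u),
            "det_n_v": int(self.det_n_v),
            "rot_axis_offset_px": float(self.rot_axis_offset_px),
        }
        if grid is not None:
            d["n_views"] = int(grid.n_views)
            d["span_deg"] = float(grid.span_deg)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ConeBeamGeometry":
        return cls(
            sod_mm=d["sod_mm"],
            sdd_mm=d["sdd_mm"],
            det_pitch_um=d["det_pitch_um"],
            det_n_u=d["det_n_u"],
            det_n_v=d["det_n_v"],
            rot_axis_offset_px=d.get("rot_axis_offset_px", 0.0),
        )

    def to_yaml(self, path, grid: AngularGrid | None = None) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(grid), fh, sort_keys=True)
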