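"""3D scalar volume container shared by the simulator, reconstructor and stitcher."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Volume"]


@dataclass
class Volume:
    """Isotropic 3D scalar grid (attenuation, arbitrary linear units).

    ``data`` is indexed ``[z, y, x]`` (z along the rotation axis), the
    conventional slice-stack order for CT volumes.  ``voxel_size_nm`` is the
    isotropic voxel edge length and ``origin_nm`` the physical coordinate of
    the centre of voxel (0, 0, 0) in (z, y, x) order.
    """

    data: np.ndarray
    voxel_size_nm: float
    origin_nm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got shape {self.data.shape}")
        if self.voxel_size_nm <= 0:
            raise ValueError("voxel size must be > 0")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size_mm(self) -> float:
        return self.voxel_size_nm * 1e-6

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.voxel_size_nm, self.origin_nm)

    @classmethod
    def centred(cls, data: np.ndarray, voxel_size_nm: float) -> "Volume":
        """Volume whose physical origin places the grid centre at (0, 0, 0)."""
        data = np.asarray(data)
        origin = tuple(-(n - 1) / 2 * voxel_size_nm for n in data.shape)
        return cls(data, voxel_size_nm, origin)  # type: ignore[arg-type]
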