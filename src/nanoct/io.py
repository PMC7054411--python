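"""TIFF / YAML / CSV input-output for stacks, volumes and offset tables.

Image data travels as multi-page TIFF (or a directory of numbered 2D TIFFs)
with a YAML geometry sidecar; offset tables as CSV (view_index, du_px, dv_px).
Volumes are stored as z-slice multi-page TIFF with a voxel-size sidecar.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .geometry import AngularGrid, ConeBeamGeometry
from .synthetic import DriftComponents, DriftTrace, ProjectionStack
from .volume import Volume

__all__ = [
    "FormatError",
    "write_stack",
    "read_stack",
    "write_volume",
    "read_volume",
    "write_offsets_csv",
    "read_offsets_csv",
]


class FormatError(ValueError):
    """Raised for malformed or inconsistent on-disk data."""


# --------------------------------------------------------------------------- #
# Offsets
# --------------------------------------------------------------------------- #

def write_offsets_csv(path, offsets_u, offsets_v=None) -> None:
    offsets_u = np.asarray(offsets_u, dtype=float)
    if offsets_v is None:
        offsets_v = np.zeros_like(offsets_u)
    pd.DataFrame(
        {
            "view_index": np.arange(len(offsets_u), dtype=int),
            "du_px": offsets_u,
            "dv_px": np.asarray(offsets_v, dtype=float),
        }
    ).to_csv(path, index=False)


def read_offsets_csv(path) -> np.ndarray:
    """(n_views, 2) array of (du, dv) in detector pixels."""
    df = pd.read_csv(path)
    for col in ("view_index", "du_px", "dv_px"):
        if col not in df.columns:
            raise FormatError(f"offsets CSV {path} lacks column {col!r}")
    df = df.sort_values("view_index")
    return df[["du_px", "dv_px"]].to_numpy(dtype=float)


# --------------------------------------------------------------------------- #
# Projection stacks
# --------------------------------------------------------------------------- #

def write_stack(stack: ProjectionStack, directory) -> Path:
    """Write projections/flat/dark TIFFs, geometry sidecar and true offsets."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(directory / "projections.tif", stack.images)
    tifffile.imwrite(directory / "flat.tif", stack.flat)
    tifffile.imwrite(directory / "dark.tif", stack.dark)
    meta = stack.geometry.to_dict(stack.angles)
    meta["i0"] = float(stack.i0)
    with open(directory / "geometry.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    if stack.true_offsets is not None:
        write_offsets_csv(
            directory / "true_offsets.csv",
            stack.true_offsets.offsets_u,
            stack.true_offsets.offsets_v,
        )
    return directory


def _read_numbered_dir(directory: Path) -> np.ndarray:
    files = sorted(directory.glob("proj_*.tif"))
    if not files:
        raise FormatError(f"no projections.tif or proj_*.tif in {directory}")
    indices = []
    for f in files:
        m = re.fullmatch(r"proj_(\d+)\.tif", f.name)
        if not m:
            raise FormatError(f"unexpected projection filename {f.name}")
        indices.append(int(m.group(1)))
    expect = list(range(min(indices), min(indices) + len(indices)))
    missing = sorted(set(expect) - set(indices))
    if missing:
        raise FormatError(f"missing projection index {missing[0]} in {directory}")
    pages = [tifffile.imread(f) for f in files]
    shapes = {p.shape for p in pages}
    if len(shapes) > 1:
        raise FormatError(f"inconsistent projection shapes {shapes}")
    return np.stack(pages)


def read_stack(path) -> ProjectionStack:
    """Read a projection stack written by :func:`write_stack`.

    ``path`` may be the stack directory, or a multi-page TIFF with a YAML
    sidecar of the same stem.  A directory may alternatively hold numbered
    2D TIFFs ``proj_0000.tif`` …; a gap in the numbering is an error.
    """
    path = Path(path)
    if path.is_dir():
        sidecar = path / "geometry.yaml"
        proj_file = path / "projections.tif"
        images = (
            tifffile.imread(proj_file) if proj_file.exists() else _read_numbered_dir(path)
        )
        flat_f, dark_f = path / "flat.tif", path / "dark.tif"
        flat = tifffile.imread(flat_f) if flat_f.exists() else None
        dark = tifffile.imread(dark_f) if dark_f.exists() else None
        offsets_f = path / "true_offsets.csv"
    else:
        sidecar = path.with_suffix(".yaml")
        images = tifffile.imread(path)
        flat = dark = None
        offsets_f = path.parent / "true_offsets.csv"
    if not sidecar.exists():
        raise FormatError(f"missing geometry sidecar {sidecar}")
    with open(sidecar) as fh:
        meta = yaml.safe_load(fh)
    if images.ndim == 2:
        images = images[None]
    n_views = int(meta.get("n_views", images.shape[0]))
    if n_views != images.shape[0]:
        raise FormatError(
            f"sidecar declares {n_views} views but stack holds {images.shape[0]} pages"
        )
    geom = ConeBeamGeometry.from_dict(meta)
    angles = AngularGrid(n_views=n_views, span_deg=float(meta.get("span_deg", 360.0)))
    true_offsets = None
    if offsets_f.exists():
        offs = read_offsets_csv(offsets_f)
        if len(offs) == n_views:
            true_offsets = DriftTrace(
                offs[:, 0], offs[:, 1], DriftComponents(0.0, 5.0, 0.0, 0.0)
            )
    return ProjectionStack(
        images=images,
        geometry=geom,
        angles=angles,
        i0=float(meta.get("i0", 1.0)),
        flat=flat,
        dark=dark,
        true_offsets=true_offsets,
    )


# --------------------------------------------------------------------------- #
# Volumes
# --------------------------------------------------------------------------- #

def write_volume(vol: Volume, path, extra_meta: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(vol.data, dtype=np.float32))
    meta = {
        "voxel_size_nm": float(vol.voxel_size_nm),
        "origin_nm": [float(o) for o in vol.origin_nm],
    }
    if extra_meta:
        meta.update(extra_meta)
    with open(path.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return path


def read_volume(path) -> Volume:
    path = Path(path)
    data = tifffile.imread(path)
    sidecar = path.with_suffix(".yaml")
    if not sidecar.exists():
        raise FormatError(f"missing volume sidecar {sidecar}")
    with open(sidecar) as fh:
        meta = yaml.safe_load(fh)
    return Volume(
        data=data,
        voxel_size_nm=float(meta["voxel_size_nm"]),
        origin_nm=tuple(meta.get("origin_nm", (0.0, 0.0, 0.0))),
    )
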