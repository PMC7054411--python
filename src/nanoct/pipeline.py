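"""Configuration-driven pipeline chaining simulate → preprocess → align →
reconstruct → stitch → analyze, with a JSON run report.

Every stage reads its inputs from disk and writes new artifacts (inputs are
never mutated); the report records per-stage timings and SHA-256 hashes of
all written artifacts, so a rerun with the same configuration and seed is
verifiable bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import time
from copy import deepcopy
from pathlib import Path

import numpy as np
import tifffile
import yaml

from . import align as align_mod
from . import analysis as analysis_mod
from . import io as io_mod
from . import preprocess as pre_mod
from . import reconstruct as rec_mod
from . import stitch as stitch_mod
from . import synthetic as syn_mod
from .geometry import AngularGrid, ConeBeamGeometry

__all__ = ["PipelineConfig", "run_pipeline", "demo_config"]

_STAGES = ("simulate", "preprocess", "align", "reconstruct", "stitch", "analyze")
_STAGE_BLOCK = {
    "simulate": ("geometry", "synthetic"),
    "preprocess": ("preprocess",),
    "align": ("align",),
    "reconstruct": ("reconstruct",),
    "stitch": ("stitch",),
    "analyze": ("analysis",),
}


class PipelineConfig:
    """Nested stage configuration plus a global seed and output directory."""

    def __init__(self, cfg: dict):
        self.cfg = deepcopy(cfg)
        if "output_dir" not in cfg:
            raise ValueError("config must define output_dir")
        self.output_dir = Path(cfg["output_dir"])
        self.seed = int(cfg.get("seed", 0))
        self.stages = list(cfg.get("stages", ["simulate", "preprocess", "align",
                                              "reconstruct", "analyze"]))
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown pipeline stages {sorted(unknown)}")
        for stage in self.stages:
            for block in _STAGE_BLOCK[stage]:
                if block not in cfg:
                    raise ValueError(
                        f"stage {stage!r} requires missing config block {block!r}"
                    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    def block(self, name: str) -> dict:
        return self.cfg.get(name, {})

    def canonical_json(self) -> str:
        # output_dir is a location, not a parameter: excluded so runs of the
        # same configuration in different places hash identically
        cfg = {k: v for k, v in self.cfg.items() if k != "output_dir"}
        return json.dumps(cfg, sort_keys=True, default=str)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def demo_config(output_dir, seed: int = 0, n: int = 32, n_views: int = 90) -> dict:
    """Small end-to-end demonstration configuration (32³ phantom, 90 views)."""
    return {
        "output_dir": str(output_dir),
        "seed": seed,
        "stages": ["simulate", "preprocess", "align", "reconstruct", "analyze"],
        "geometry": {
            "det_n_u": int(np.ceil(1.5 * n)),
            "det_n_v": int(np.ceil(1.5 * n)),
            "sod_mm": 0.6,
            "rot_axis_offset_px": 1.5,
            "n_views": n_views,
            "span_deg": 360.0,
        },
        "synthetic": {
            "n": n,
            "voxel_size_nm": 540.0,
            "i0": 5000.0,
            "fresnel_strength": 0.5,
            "src_blur_sigma": 0.5,
            "drift": {
                "smooth_amplitude": 1.5,
                "smooth_cutoff": 5.0,
                "jitter_sigma": 0.3,
                "walk_sigma": 0.0,
            },
        },
        "preprocess": {
            "phase_retrieval": True,
            "energy_kev": 20.0,
            "delta": 4e-7,
            "mu_per_mm": 10.0,
            "deblur": {"alpha": 1e-3, "psf_sigma": 0.5},
        },
        "align": {
            "per_view": True,
            "coarse_factor": 2,
            "search_halfwidth_px": 4.0,
            "tol_px": 0.1,
            "max_sweeps": 3,
            "eval_slab": 6,
        },
        "reconstruct": {"filter_kind": "ramlak"},
        "analysis": {"reference_radius_frac": 0.08},
    }


# --------------------------------------------------------------------------- #
# Stage implementations
# --------------------------------------------------------------------------- #

def _stage_simulate(cfg: PipelineConfig, out: Path, seed: int) -> list[Path]:
    g = cfg.block("geometry")
    s = cfg.block("synthetic")
    spec = syn_mod.default_phantom_spec(
        n=int(s.get("n", 32)), voxel_size_nm=float(s.get("voxel_size_nm", 540.0)),
        seed=seed,
    )
    phantom = syn_mod.generate_phantom(spec)
    geom = ConeBeamGeometry.from_effective_pixel(
        eff_pixel_nm=spec.voxel_size_nm,
        det_n_u=int(g["det_n_u"]),
        det_n_v=int(g["det_n_v"]),
        sod_mm=float(g.get("sod_mm", 0.6)),
        rot_axis_offset_px=float(g.get("rot_axis_offset_px", 0.0)),
    )
    angles = AngularGrid(int(g.get("n_views", 90)), float(g.get("span_deg", 360.0)))
    d = s.get("drift", {})
    drift = syn_mod.generate_drift(
        angles.n_views,
        syn_mod.DriftComponents(
            smooth_amplitude=float(d.get("smooth_amplitude", 0.0)),
            smooth_cutoff=float(d.get("smooth_cutoff", 5.0)),
            jitter_sigma=float(d.get("jitter_sigma", 0.0)),
            walk_sigma=float(d.get("walk_sigma", 0.0)),
        ),
        seed=seed + 1,
    )
    stack = syn_mod.project_cone_beam(phantom, geom, angles, drift)
    stack = syn_mod.apply_noise_and_flats(
        stack,
        i0=float(s.get("i0", 5000.0)),
        fresnel_strength=float(s.get("fresnel_strength", 0.0)),
        src_blur_sigma=float(s.get("src_blur_sigma", 0.0)),
        seed=seed + 2,
    )
    stack_dir = io_mod.write_stack(stack, out / "stack")
    vol_path = io_mod.write_volume(
        phantom, out / "phantom.tif", extra_meta={"config_sha256": cfg.config_hash}
    )
    paths = sorted(stack_dir.glob("*")) + [vol_path, vol_path.with_suffix(".yaml")]
    return paths


def _stage_preprocess(cfg: PipelineConfig, out: Path, seed: int) -> list[Path]:
    p = cfg.block("preprocess")
    stack = io_mod.read_stack(out / "stack")
    phase = None
    if p.get("phase_retrieval", False):
        phase = pre_mod.PhaseRetrievalParams(
            energy_kev=float(p.get("energy_kev", 20.0)),
            delta=float(p.get("delta", 1e-7)),
            mu_per_mm=float(p.get("mu_per_mm", 10.0)),
            propagation_dist_mm=stack.geometry.sdd_mm - stack.geometry.sod_mm,
            magnification=stack.geometry.magnification,
            eff_pixel_nm=stack.geometry.eff_pixel_nm,
        )
    deblur = None
    if "deblur" in p:
        deblur = pre_mod.DeblurParams(
            alpha=float(p["deblur"].get("alpha", 1e-3)),
            psf_sigma=float(p["deblur"].get("psf_sigma", 0.0)),
        )
    log_projs = pre_mod.preprocess_stack(stack, phase, deblur)
    path = out / "preprocessed.tif"
    tifffile.imwrite(path, log_projs)
    return [path]


def _stage_align(cfg: PipelineConfig, out: Path, seed: int) -> list[Path]:
    a = cfg.block("align")
    stack = io_mod.read_stack(out / "stack")
    acfg = align_mod.AlignConfig(
        coarse_factor=int(a.get("coarse_factor", 2)),
        search_halfwidth_px=float(a.get("search_halfwidth_px", 6.0)),
        line_search=a.get("line_search", "golden"),
        tol_px=float(a.get("tol_px", 0.1)),
        max_sweeps=int(a.get("max_sweeps", 8)),
        eval_slab=int(a.get("eval_slab", 8)),
        optimize_v=bool(a.get("optimize_v", False)),
        seed=seed,
    )
    if a.get("per_view", True):
        result = align_mod.align_per_view(stack, acfg)
        offsets_u, offsets_v = result.offsets_u, result.offsets_v
        report = {
            "centre_shift_px": result.centre_shift_px,
            "metric_trace": [float(m) for m in result.metric_trace],
            "n_sweeps": result.n_sweeps,
            "converged": bool(result.converged),
            "coarse_factor": result.coarse_factor,
        }
    else:
        cs = align_mod.estimate_centre_shift(stack, acfg)
        offsets_u = np.zeros(stack.n_views)
        offsets_v = np.zeros(stack.n_views)
        report = {"centre_shift_px": cs, "metric_trace": [], "n_sweeps": 0,
                  "converged": True, "coarse_factor": acfg.coarse_factor}
    io_mod.write_offsets_csv(out / "offsets.csv", offsets_u, offsets_v)
    with open(out / "align_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return [out / "offsets.csv", out / "align_report.json"]


def _stage_reconstruct(cfg: PipelineConfig, out: Path, seed: int) -> list[Path]:
    r = cfg.block("reconstruct")
    stack = io_mod.read_stack(out / "stack")
    log_path = out / "preprocessed.tif"
    log_projs = tifffile.imread(log_path) if log_path.exists() else None
    centre_shift = float(r.get("centre_shift_px", 0.0))
    offsets = None
    if (out / "align_report.json").exists():
        with open(out / "align_report.json") as fh:
            centre_shift = float(json.load(fh)["centre_shift_px"])
    if (out / "offsets.csv").exists():
        offsets = io_mod.read_offsets_csv(out / "offsets.csv")
    rcfg = rec_mod.ReconConfig(
        filter_kind=r.get("filter_kind", "ramlak"),
        centre_shift_px=centre_shift,
        per_view_offsets=offsets,
    )
    vol = rec_mod.fdk_reconstruct(stack, rcfg, log_projs=log_projs)
    path = io_mod.write_volume(
        vol, out / "reconstruction.tif", extra_meta={"config_sha256": cfg.config_hash}
    )
    return [path, path.with_suffix(".yaml")]


def _stage_stitch(cfg: PipelineConfig, out: Path, seed: int) -> list[Path]:
    s = cfg.block("stitch")
    paths = [Path(p) for p in s.get("volumes", [])]
    if not paths:
        raise ValueError("stitch stage requires a 'volumes' list in the config")
    vols = [io_mod.read_volume(p) for p in paths]
    shifts = []
    for a, b in zip(vols[:-1], vols[1:]):
        est = stitch_mod.estimate_shift_3d(a, b)
        # estimate: b(x) = a(x − d); the next volume therefore sits at −d
        shifts.append(tuple(-s for s in est.shift))
    plan = stitch_mod.StitchPlan(shifts=shifts, blend_width=int(s.get("blend_width", 8)))
    merged = stitch_mod.merge_volumes(vols, plan)
    path = io_mod.write_volume(
        merged, out / "stitched.tif", extra_meta={"config_sha256": cfg.config_hash}
    )
    with open(out / "stitch_plan.json", "w") as fh:
        json.dump({"shifts": [list(map(float, sh)) for sh in shifts],
                   "blend_width": plan.blend_width}, fh, indent=2, sort_keys=True)
    return [path, path.with_suffix(".yaml"), out / "stitch_plan.json"]


def _stage_analyze(cfg: PipelineConfig, out: Path, seed: int) -> list[Path]:
    a = cfg.block("analysis")
    vol = io_mod.read_volume(out / "reconstruction.tif")
    nz, ny, nx = vol.shape
    img = vol.data[nz // 2]
    rad = max(2, int(a.get("reference_radius_frac", 0.08) * nx))
    yy, xx = np.ogrid[0:ny, 0:nx]

    def disk(cy, cx, r):
        return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2

    # resin reference near the cylinder edge, feature ROI near the gut tube
    masks = {
        "resin": disk(ny // 2 + int(0.30 * ny), nx // 2 - int(0.30 * nx), rad),
        "gut_wall": disk(ny // 2 - int(0.05 * ny), nx // 2 + int(0.12 * nx), rad),
        "muscle": disk(ny // 2 + int(0.16 * ny), nx // 2 - int(0.22 * nx), rad),
    }
    report = analysis_mod.cnr_report(img, masks, reference_label="resin")
    rows = "label,mu,sigma,n_pixels,cnr\n" + "\n".join(
        f"{r['label']},{r['mu']:.6g},{r['sigma']:.6g},{r['n_pixels']},{r['cnr']:.6g}"
        for r in report.rows
    )
    (out / "cnr.csv").write_text(rows + "\n")
    prof = analysis_mod.line_profile(
        img, (ny // 2, 2), (ny // 2, nx - 3),
        background=report.as_dict()["resin"]["mu"],
        pixel_size_um=vol.voxel_size_nm * 1e-3,
    )
    lines = "position_um,value\n" + "\n".join(
        f"{p:.6g},{v:.6g}" for p, v in zip(prof.positions_um, prof.values)
    )
    (out / "profile.csv").write_text(lines + "\n")
    return [out / "cnr.csv", out / "profile.csv"]


_STAGE_FN = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "align": _stage_align,
    "reconstruct": _stage_reconstruct,
    "stitch": _stage_stitch,
    "analyze": _stage_analyze,
}


def run_pipeline(cfg: PipelineConfig | dict, stages: list[str] | None = None) -> dict:
    """Execute the configured stages in order and write ``report.json``.

    Returns the report dict: per-stage status and timing, SHA-256 hashes of
    every artifact, the configuration hash and the seed.  A stage failure is
    recorded in the report (prior artifacts are retained) and re-raised.
    """
    if isinstance(cfg, dict):
        cfg = PipelineConfig(cfg)
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    stages = stages or cfg.stages
    report: dict = {
        "seed": cfg.seed,
        "config_sha256": cfg.config_hash,
        "stages": {},
        "hashes": {},
    }
    try:
        for stage in stages:
            t0 = time.perf_counter()
            paths = _STAGE_FN[stage](cfg, out, cfg.seed)
            dt = time.perf_counter() - t0
            report["stages"][stage] = {"status": "ok", "seconds": round(dt, 3)}
            for p in paths:
                report["hashes"][str(Path(p).relative_to(out))] = _sha256(Path(p))
    except Exception as exc:
        report["stages"][stage] = {"status": "failed", "error": str(exc)}
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        raise
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
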