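"""End-to-end pipeline: ingest (phantom or real) -> segment -> register ->
reconstruct -> quantify, with all artefacts written to an output directory
and a JSON run report.

All randomness flows from a single top-level seed, fanned out per stage,
so a rerun with the same configuration and seed reproduces the report
byte-for-byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import io as ario
from . import metrics as met
from . import phantom as ph
from . import reconstruction as rec
from . import registration as reg
from . import segmentation as seg
from .geometry import ContourSet, InvalidInputError, resample_contour

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger(__name__)

PHANTOM_KINDS = {
    "cylinder": ph.CylinderSpec,
    "elliptical_tube": ph.EllipticalTubeSpec,
    "hourglass": ph.HourglassSpec,
    "bichannel": ph.BichannelSpec,
}


@dataclass
class PipelineConfig:
    """Everything one run needs.  ``mode`` is 'phantom' or 'real'."""

    mode: str = "phantom"
    output_dir: str = "airwayrec_out"
    rng_seed: int = 0
    # phantom mode
    phantom_kind: str = "elliptical_tube"
    phantom_params: dict = field(default_factory=dict)
    noise_sigma_frac: float = 0.0  # fraction of lumen-background contrast
    motions: dict = field(default_factory=dict)  # orientation -> motion dict
    matrix: tuple[int, int] = (512, 512)
    # real mode
    paths: dict = field(default_factory=dict)  # orientation -> stack dir
    seed_paths: dict = field(default_factory=dict)  # orientation -> contour file
    # stage parameters
    segmentation: dict = field(default_factory=dict)  # LevelSetParams kwargs
    registration: dict = field(default_factory=lambda: {"max_dist": 4.0})
    reconstruction: dict = field(
        default_factory=lambda: {"n_samples": 120, "degree_u": 3, "degree_v": 3,
                                 "nu": 160, "nv": 80}
    )
    metrics: dict = field(default_factory=lambda: {"step": 0.2, "exclude_ends": 2.0})

    def validate(self) -> None:
        if self.mode not in ("phantom", "real"):
            raise InvalidInputError(f"unknown mode {self.mode!r}")
        if self.mode == "phantom" and self.phantom_kind not in PHANTOM_KINDS:
            raise InvalidInputError(f"unknown phantom kind {self.phantom_kind!r}")
        if self.mode == "real":
            for orient in ("coronal", "axial", "sagittal"):
                if orient not in self.paths:
                    raise InvalidInputError(f"missing {orient} path")
                if not Path(self.paths[orient]).exists():
                    raise InvalidInputError(f"path does not exist: {self.paths[orient]}")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        d = json.loads(Path(path).read_text())
        cfg = cls(**d)
        cfg.validate()
        return cfg


def _phantom_seeds(spec, acq, rng) -> dict[int, list[np.ndarray]]:
    """Emulate manual seeding: shrink each analytic cross-section toward
    its centroid (a user would draw a rough polygon inside the lumen)."""
    truth = ph.analytic_contours(spec, acq, resolution=0.25)
    seeds: dict[int, list[np.ndarray]] = {}
    for c in truth:
        small = resample_contour(c, 32)
        cen = small.points.mean(axis=0)
        pts = cen + 0.7 * (small.points - cen)
        seeds.setdefault(c.slice_index, []).append(pts)
    return seeds


def _segment_stacks(stacks, seeds_by_orient, params) -> dict[str, ContourSet]:
    out = {}
    for orient, stack in stacks.items():
        out[orient] = seg.segment_stack(stack, seeds_by_orient[orient], params)
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the run report."""
    config.validate()
    t_start = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": _config_dict(config), "timings_s": {}, "warnings": []}
    timings = report["timings_s"]

    handler = _CollectWarnings(report["warnings"])
    logging.getLogger("airwayrec").addHandler(handler)
    try:
        # ---- ingest ----
        t0 = time.time()
        if config.mode == "phantom":
            spec = PHANTOM_KINDS[config.phantom_kind](**config.phantom_params)
            contrast = spec.intensity_background - spec.intensity_lumen
            motions = {
                k: ph.RigidMotion(**v) for k, v in (config.motions or {}).items()
            }
            stacks = ph.acquire(
                spec,
                noise_sigma=config.noise_sigma_frac * abs(contrast),
                motions=motions,
                seed=config.rng_seed,
                matrix=tuple(config.matrix),
            )
            rng = np.random.default_rng(config.rng_seed)
            seeds = {
                orient: _phantom_seeds(
                    spec,
                    _acq_of(stacks[orient], orient),
                    rng,
                )
                for orient in stacks
            }
            report["phantom"] = {
                "kind": spec.kind,
                "ground_truth_volume_mm3": spec.volume(),
            }
            if isinstance(spec, ph.BichannelSpec):
                report["phantom"]["merge_y_mm"] = spec.merge_y
        else:
            stacks = {
                orient: ario.read_image_stack(config.paths[orient], orient)
                for orient in ("coronal", "axial", "sagittal")
            }
            seeds = {}
            for orient in stacks:
                cs = ario.read_contours(config.seed_paths[orient])
                d: dict[int, list[np.ndarray]] = {}
                for c in cs:
                    d.setdefault(c.slice_index, []).append(c.points)
                seeds[orient] = d
            spec = None
        timings["ingest"] = time.time() - t0

        # ---- segmentation ----
        t0 = time.time()
        params = seg.LevelSetParams(**config.segmentation)
        csets = _segment_stacks(stacks, seeds, params)
        timings["segmentation"] = time.time() - t0
        for orient, cs in csets.items():
            ario.write_contours(cs, outdir / f"contours_{orient}.txt")

        # ---- registration ----
        t0 = time.time()
        cor, axi, sag = reg.register_all(
            csets["coronal"], csets["axial"], csets["sagittal"],
            max_dist=config.registration.get("max_dist", 4.0),
        )
        rms = {}
        for name, m in (("axial", axi), ("sagittal", sag)):
            try:
                rms[name] = reg.crossing_rms(m, cor)
            except reg.RegistrationError:
                rms[name] = None
        report["registration_rms_mm"] = rms
        timings["registration"] = time.time() - t0
        for orient, cs in (("coronal", cor), ("axial", axi), ("sagittal", sag)):
            ario.write_contours(cs, outdir / f"contours_{orient}_registered.txt")

        # ---- reconstruction ----
        t0 = time.time()
        rcfg = config.reconstruction
        solids = _reconstruct(cor, axi, sag, rcfg, report)
        meshes = {
            name: rec.tessellate(s, rcfg.get("nu", 160), rcfg.get("nv", 80))
            for name, s in solids.items()
        }
        timings["reconstruction"] = time.time() - t0
        ario.write_nurbs_json(solids, outdir / "nurbs_surfaces.json")
        for name, m in meshes.items():
            ario.write_mesh(m, outdir / f"mesh_{name}.stl")

        # ---- metrics ----
        t0 = time.time()
        import trimesh as _tm

        merged = _tm.util.concatenate([m.to_trimesh() for m in meshes.values()])
        profile = met.area_profile(
            merged, axis=(0.0, 1.0, 0.0), step=config.metrics.get("step", 0.2)
        )
        met.write_profile(profile, outdir / "area_profile.tsv")
        pos, area = met.min_area_site(
            profile, exclude_ends=config.metrics.get("exclude_ends", 2.0)
        )
        volumes = {name: met.mesh_volume(m) for name, m in meshes.items()}
        report["volumes_mm3"] = volumes
        report["total_volume_mm3"] = float(sum(volumes.values()))
        report["profile_volume_mm3"] = met.profile_volume(profile)
        report["min_area_site"] = {"position_mm": pos, "area_mm2": area}
        timings["metrics"] = time.time() - t0

        if config.mode == "phantom" and spec is not None:
            gt = spec.volume()
            report["volume_error_pct"] = 100.0 * (report["total_volume_mm3"] / gt - 1.0)
    finally:
        logging.getLogger("airwayrec").removeHandler(handler)
    report["timings_s"]["total"] = time.time() - t_start
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _acq_of(stack, orient) -> ph.AcquisitionSpec:
    """Reconstruct the acquisition geometry of an existing stack (for
    analytic seeding)."""
    fr = stack.frame
    rows, cols = fr.matrix
    center = fr.origin + (
        fr.axis_u * (cols - 1) / 2 * fr.pixel_spacing[0]
        + fr.axis_v * (rows - 1) / 2 * fr.pixel_spacing[1]
        + fr.normal * (stack.n_slices - 1) / 2 * fr.slice_spacing
    )
    return ph.AcquisitionSpec(
        orientation=orient,
        fov=cols * fr.pixel_spacing[0],
        matrix=fr.matrix,
        slice_thickness=fr.slice_thickness,
        slice_gap=fr.slice_gap,
        n_slices=stack.n_slices,
        stack_center=tuple(center),
    )


def _reconstruct(cor, axi, sag, rcfg, report) -> dict:
    """Build the airway solids from the registered sets.

    With a bichannel topology (a persistent 2 -> 1 coronal region-count
    transition) the two nasal passages and the merged lumen are lofted as
    three bodies meeting at the refined merge plane, the nasal lofts
    guided by the anterior nasopharynx wall trace.  Otherwise each lumen
    component is lofted on its own."""
    n_samples = rcfg.get("n_samples", 120)
    du, dv = rcfg.get("degree_u", 3), rcfg.get("degree_v", 3)
    half = cor.frame.slice_spacing / 2.0
    solids: dict[str, object] = {}
    try:
        interval = reg.locate_septum_interval(cor)
    except reg.SeptumNotFoundError:
        interval = None
    if interval is None:
        for i, chain in enumerate(rec.contour_chains(cor)):
            if len(chain) < 2:
                continue
            name = f"component_{i}" if i else "airway"
            solids[name] = rec.reconstruct_stack(
                chain, n_samples=n_samples, degree_u=du, degree_v=dv,
                extend_ends=(half, half),
            )
        return solids
    trace = reg.refine_nasopharynx_wall(cor, axi, sag, interval)
    nrm = cor.frame.normal
    y_star = float(np.mean(trace @ nrm))
    report["septum"] = {
        "coronal_interval": list(interval),
        "wall_y_mm": y_star,
        "n_trace_points": int(len(trace)),
    }
    slices = cor.slice_indices()
    ka, kb = interval
    two_part = ContourSet(cor.orientation, cor.frame)
    one_part = ContourSet(cor.orientation, cor.frame)
    for k in slices[: ka + 1]:
        for c in cor.contours[k]:
            two_part.add(c)
    for k in slices[kb:]:
        for c in cor.contours[k]:
            one_part.add(c)
    chains2 = [ch for ch in rec.contour_chains(two_part) if len(ch) >= 2]
    # name nasal chains by world-x of their centroids (left = +x in LPS)
    def mean_x(ch):
        return float(np.mean([c.world_points().mean(axis=0)[0] for c in ch]))

    chains2.sort(key=mean_x)
    names = ["right_nasal", "left_nasal"] if len(chains2) == 2 else [
        f"nasal_{i}" for i in range(len(chains2))
    ]
    for name, ch in zip(names, chains2):
        end_pos = ch[-1].frame.slice_origin(ch[-1].slice_index) @ nrm
        solids[name] = rec.reconstruct_stack(
            ch, n_samples=n_samples, degree_u=du, degree_v=dv,
            extend_ends=(half, max(y_star - end_pos, 0.0)),
        )
    for ch in [c for c in rec.contour_chains(one_part) if len(c) >= 2]:
        start_pos = ch[0].frame.slice_origin(ch[0].slice_index) @ nrm
        solids["pharynx"] = rec.reconstruct_stack(
            ch, n_samples=n_samples, degree_u=du, degree_v=dv,
            guides=trace,
            extend_ends=(max(start_pos - y_star, 0.0), half),
        )
    return solids


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["matrix"] = list(d["matrix"])
    return d


class _CollectWarnings(logging.Handler):
    def __init__(self, sink: list):
        super().__init__(level=logging.WARNING)
        self.sink = sink

    def emit(self, record):
        self.sink.append(self.format(record))
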