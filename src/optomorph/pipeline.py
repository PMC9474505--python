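"""End-to-end orchestration: configuration, stages and the timelapse analysis.

:func:`analyze_timelapse` is the library entry point that chains the
stack-level stages exactly as the experiments are analysed: rescale to
isotropic voxels, 3D watershed segmentation, per-cell morphometry,
maximum-overlap tracking, quality control, and stimulated/layer
classification.  :func:`run_stage` exposes the stages individually for
the command line, writing tidy CSV artifacts plus the verbatim
configuration into the output directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import curvature as curv
from . import flow as flow_mod
from . import intensity as intens
from . import morphometry as morph
from . import segmentation as seg
from . import shape_model
from . import synthetic as synth
from . import tracking as track_mod
from .stack import ImageStack, LabelVolume, read_stack, write_labels, write_stack
from .tracking import StimulationROI

log = logging.getLogger("optomorph")

STAGES = ("simulate", "segment", "measure", "model", "curvature", "flow", "intensity", "pipeline")


@dataclass
class PipelineConfig:
    """All tunable stage parameters, with experiment-convention defaults.

    Defaults follow the conventions of the experiments this package
    reproduces: 0.30 volume-jump QC threshold, 20/320 px curvature
    spacings, 64 px PIV interrogation windows, 26.5 µm square ROI.
    """

    output_dir: str = "optomorph_out"
    seed: int = 0
    # synthetic monolayer / constriction program
    grid_shape: tuple[int, int] = (5, 5)
    cell_footprint_um: float = 10.0
    tissue_height_um: float = 10.0
    n_frames: int = 4
    frame_interval_min: float = 2.0
    plateau_reduction: float = 0.254
    roi_size_um: float = 26.5
    # segmentation
    target_voxel_um: float | None = None
    watershed_h: float = 0.3
    # tracking / classification
    qc_threshold: float = 0.30
    max_layer: int = 3
    # curvature
    skeleton_spacing_px: int = 20
    perimeter_spacing_px: int = 320
    # flow
    piv_window_px: int = 64
    adjacent_width_um: float | None = None

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)


@dataclass
class TimelapseAnalysis:
    """Result of the full segment → track → QC → measure chain."""

    table: pd.DataFrame  # track_id, frame, label, metrics, qc_status, class
    labels: list[LabelVolume]
    tracks: list[track_mod.CellTrack]
    rejected: list[track_mod.CellTrack]
    stimulated_contact: set[int]
    stimulated_majority: set[int]
    layers: dict[int, str]


def analyze_timelapse(
    stacks: list[ImageStack],
    roi: StimulationROI | None = None,
    target_voxel: float | None = None,
    watershed_h: float = 0.3,
    max_layer: int = 3,
) -> TimelapseAnalysis:
    """Segment, measure, track, QC and classify a membrane timelapse.

    Classification follows the two conventions used for the two
    analyses: *contact* (any apical pixel inside the ROI) marks the
    stimulated set for the stimulated-vs-outer comparison, while
    *majority* (>50% of apical area inside) seeds the layer analysis.
    Classes in the returned table come from the majority/layer scheme,
    with a separate boolean column for the contact rule.
    """
    labels: list[LabelVolume] = []
    frames_df: list[pd.DataFrame] = []
    for f, st in enumerate(stacks):
        iso = seg.rescale_isotropic(st, target_voxel)
        lab = seg.segment_cells_3d(iso, h_frac=watershed_h)
        labels.append(lab)
        frames_df.append(morph.measure_cells(lab, frame=f))
    records = pd.concat(frames_df, ignore_index=True)
    volumes = {
        (int(r.frame), int(r.label)): float(r.volume_um3) for r in records.itertuples()
    }
    tracks = track_mod.build_tracks(labels)
    passing, rejected = track_mod.qc_filter(tracks, volumes, n_frames=len(stacks))

    stim_contact: set[int] = set()
    stim_majority: set[int] = set()
    layers: dict[int, str] = {}
    apical0 = morph.apical_label_image(labels[0])
    if roi is not None:
        px = labels[0].voxel_size[2]
        stim_contact = track_mod.classify_stimulated(apical0, px, roi, mode="contact")
        stim_majority = track_mod.classify_stimulated(apical0, px, roi, mode="majority")
        graph = track_mod.build_adjacency(apical0)
        layers = track_mod.assign_layers(graph, stim_majority, max_layer=max_layer)

    # attach track ids and classes (defined at t0) to the tidy table
    by_frame_label: dict[tuple[int, int], track_mod.CellTrack] = {}
    for tr in tracks:
        for f, lab_id in tr.labels_by_frame.items():
            by_frame_label[(f, lab_id)] = tr
    rows = []
    for r in records.itertuples():
        tr = by_frame_label.get((int(r.frame), int(r.label)))
        label0 = tr.labels_by_frame.get(0) if tr is not None else None
        rows.append(
            {
                "track_id": tr.track_id if tr is not None else -1,
                "qc_status": tr.qc_status if tr is not None else "untracked",
                "stimulated_contact": bool(label0 in stim_contact) if label0 else False,
                "class": layers.get(label0, "unclassified") if label0 else "unclassified",
            }
        )
    table = pd.concat([records, pd.DataFrame(rows)], axis=1)
    return TimelapseAnalysis(
        table=table,
        labels=labels,
        tracks=passing,
        rejected=rejected,
        stimulated_contact=stim_contact,
        stimulated_majority=stim_majority,
        layers=layers,
    )


def _default_roi(cfg: PipelineConfig) -> StimulationROI:
    spec = _spec_from_config(cfg)
    w, h = spec.field_size
    half = cfg.roi_size_um / 2.0
    return StimulationROI(
        x_min=w / 2 - half, x_max=w / 2 + half, y_min=h / 2 - half, y_max=h / 2 + half,
        t_start=0.5 * cfg.frame_interval_min,
    )


def _spec_from_config(cfg: PipelineConfig) -> synth.SyntheticTissueSpec:
    return synth.SyntheticTissueSpec(
        grid_shape=cfg.grid_shape,
        cell_footprint=cfg.cell_footprint_um,
        tissue_height=cfg.tissue_height_um,
        n_frames=cfg.n_frames,
        frame_interval=cfg.frame_interval_min,
        seed=cfg.seed,
    )


def run_stage(name: str, cfg: PipelineConfig) -> dict:
    """Run one named stage; artifacts are written under ``cfg.output_dir``.

    Returns a manifest dict (paths and SHA-256 checksums of the
    artifacts).  Raises ``ValueError`` for an unknown stage name and
    ``FileNotFoundError`` naming the producing stage when an input is
    missing.
    """
    if name not in STAGES:
        raise ValueError(f"unknown stage {name!r}; expected one of {STAGES}")
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    fn = {
        "simulate": _stage_simulate,
        "segment": _stage_segment,
        "measure": _stage_measure,
        "model": _stage_model,
        "curvature": _stage_curvature,
        "flow": _stage_flow,
        "intensity": _stage_intensity,
        "pipeline": _stage_pipeline,
    }[name]
    log.info("stage %s -> %s", name, out)
    artifacts = fn(cfg, out)
    manifest = {p.name: _sha256(p) for p in artifacts}
    (out / f"{name}.manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_simulate(cfg: PipelineConfig, out: Path) -> list[Path]:
    spec = _spec_from_config(cfg)
    roi = _default_roi(cfg)
    program = synth.ConstrictionProgram(roi=roi, plateau_reduction=cfg.plateau_reduction)
    mono = synth.generate_monolayer(spec, program)
    paths = []
    for f, (st, lab) in enumerate(zip(mono.stacks, mono.labels)):
        p = out / f"membrane_t{f:03d}.tif"
        write_stack(p, st)
        paths.append(p)
        p = out / f"truth_labels_t{f:03d}.tif"
        write_labels(p, lab)
        paths.append(p)
    tp = out / "ground_truth.csv"
    mono.truth.to_csv(tp, index=False)
    paths.append(tp)
    rp = out / "roi.yaml"
    rp.write_text(yaml.safe_dump(dataclasses.asdict(roi)))
    paths.append(rp)
    return paths


def _load_sim_stacks(cfg: PipelineConfig, out: Path) -> list[ImageStack]:
    paths = sorted(out.glob("membrane_t*.tif"))
    if not paths:
        raise FileNotFoundError(
            f"no membrane stacks in {out}; run the 'simulate' stage first"
        )
    return [read_stack(p, channel="membrane") for p in paths]


def _load_roi(out: Path) -> StimulationROI:
    rp = out / "roi.yaml"
    if not rp.exists():
        raise FileNotFoundError(f"{rp} missing; run the 'simulate' stage first")
    d = yaml.safe_load(rp.read_text())
    return StimulationROI(**{k: d[k] for k in ("x_min", "x_max", "y_min", "y_max", "t_start", "t_end")})


def _stage_segment(cfg: PipelineConfig, out: Path) -> list[Path]:
    stacks = _load_sim_stacks(cfg, out)
    paths = []
    for f, st in enumerate(stacks):
        iso = seg.rescale_isotropic(st, cfg.target_voxel_um)
        lab = seg.segment_cells_3d(iso, h_frac=cfg.watershed_h)
        p = out / f"labels_t{f:03d}.tif"
        write_labels(p, lab)
        paths.append(p)
    return paths


def _stage_measure(cfg: PipelineConfig, out: Path) -> list[Path]:
    stacks = _load_sim_stacks(cfg, out)
    roi = _load_roi(out)
    res = analyze_timelapse(
        stacks, roi, target_voxel=cfg.target_voxel_um,
        watershed_h=cfg.watershed_h, max_layer=cfg.max_layer,
    )
    p = out / "morphometry.csv"
    res.table.to_csv(p, index=False)
    return [p]


def _stage_model(cfg: PipelineConfig, out: Path) -> list[Path]:
    mp = out / "morphometry.csv"
    if not mp.exists():
        raise FileNotFoundError(f"{mp} missing; run the 'measure' stage first")
    df = pd.read_csv(mp)
    ok = df[df["qc_status"] == track_mod.QC_PASS]
    avg = ok.groupby("frame")[
        ["volume_um3", "apical_area_um2", "basal_area_um2", "height_um"]
    ].mean()
    avg["predicted_height_um"] = shape_model.predict_series(avg, predict="height_um")
    p = out / "model_prediction.csv"
    avg.to_csv(p)
    return [p]


def _stage_curvature(cfg: PipelineConfig, out: Path) -> list[Path]:
    px = 0.207
    img, true_k = synth.generate_colony_profile(
        arc_radius=100.0, arc_span=120.0, thickness=8.0,
        shape=(640, 1024), pixel_size=px, seed=cfg.seed,
    )
    skel = curv.extract_skeleton(img, pixel_size=px)
    prof = curv.local_curvature(skel, spacing=cfg.skeleton_spacing_px, pixel_size=px)
    df = pd.DataFrame({"arc_position_um": prof.positions, "kappa_per_um": prof.kappa})
    p = out / "skeleton_curvature.csv"
    df.to_csv(p, index=False)
    s = out / "curvature_summary.csv"
    pd.DataFrame(
        [{"mean_kappa_per_um": prof.mean, "true_kappa_per_um": true_k}]
    ).to_csv(s, index=False)
    return [p, s]


def _stage_flow(cfg: PipelineConfig, out: Path) -> list[Path]:
    roi = StimulationROI(60.0, 95.3, 60.0, 95.3, t_start=0.0, t_end=20.0)
    fields = synth.generate_flow_field(
        center=roi.center,
        magnitude_profile=lambda d: 0.1 * max(0.0, 1.0 - d / 60.0),
        grid_spacing=cfg.piv_window_px * 0.207,
        extent=(160.0, 160.0),
        n_frames=cfg.n_frames,
    )
    adj = cfg.adjacent_width_um or cfg.piv_window_px * 0.207
    zones = flow_mod.classify_zones(fields[0], roi, adjacent_width=adj)
    df = flow_mod.zonal_series(fields, zones, roi.center)
    p = out / "zonal_series.csv"
    df.to_csv(p, index=False)
    return [p]


def _stage_intensity(cfg: PipelineConfig, out: Path) -> list[Path]:
    t = np.arange(0.0, 400.0, 2.0)
    y = synth.generate_translocation_series(
        t, stim_window=(60.0, 180.0), noise_sd=0.02, seed=cfg.seed
    )
    fit = intens.fit_kinetics(t, y, stim_window=(60.0, 180.0))
    p = out / "kinetics.json"
    p.write_text(
        json.dumps(
            {
                "baseline": fit.baseline,
                "amplitude": fit.amplitude,
                "tau_on_s": fit.tau_on,
                "tau_off_s": fit.tau_off,
                "half_life_off_s": fit.half_life_off,
                "residual": fit.residual,
            },
            indent=2,
        )
    )
    return [p]


def _stage_pipeline(cfg: PipelineConfig, out: Path) -> list[Path]:
    paths = _stage_simulate(cfg, out)
    paths += _stage_segment(cfg, out)
    paths += _stage_measure(cfg, out)
    paths += _stage_model(cfg, out)
    return paths


__all__ = ["PipelineConfig", "TimelapseAnalysis", "analyze_timelapse", "run_stage", "STAGES"]
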