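"""End-to-end orchestration: simulate -> analyze -> report.

`analyze_movie` is the in-memory core used by scripts and tests: it
takes a rendered (or loaded) three-channel movie plus a channel
transform and correction factors and runs photon conversion, sum-image
registration, detection, tracking, brightness readout, the QC filter
chain, E/S computation, mixture fitting and force conversion.
`run_simulation` / `run_pipeline` are thin disk-based wrappers driven
by a YAML config; every random choice is derived from a single seed so
reruns are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd

from . import detect, qc
from .calibration import (CalibrationParams, DynamicRange, calibrate_linker,
                          default_params)
from .detect import DetectionConfig, SEARCH_RADIUS_NM
from .fret import CorrectionFactors, compute_es
from .image_prep import ChannelStack, LaserProfile, counts_to_photons
from .kinetics import add_forces
from .population import (MixtureFit, ForcePeakSummary, bootstrap_fit,
                         fit_es_mixture, summarize_force_peaks)
from .qc import CellMask, QCConfig, apply_qc_chain
from .registration import AffineTransform, fit_affine, pair_beads
from .simulate import CameraParams, Movie, TimingParams

__all__ = ["AnalysisResult", "analyze_movie", "register_from_fiducials",
           "run_simulation", "run_pipeline"]


@dataclass
class AnalysisResult:
    """Artifacts of one movie analysis."""

    records: pd.DataFrame              # QC'd records with E, S, force
    qc_report: pd.DataFrame
    fit: Optional[MixtureFit]
    force_peaks: List[ForcePeakSummary]
    transform: AffineTransform
    factors: CorrectionFactors
    params: CalibrationParams
    dyn_range: DynamicRange
    n_raw_records: int = 0

    def write(self, outdir: Union[str, Path]) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(outdir / "records.csv", index=False)
        self.qc_report.to_csv(outdir / "qc_report.csv", index=False)
        if self.fit is not None:
            (outdir / "mixture_fit.json").write_text(
                json.dumps(self.fit.to_dict(), indent=2))
        (outdir / "force_peaks.json").write_text(json.dumps(
            [dataclasses.asdict(p) for p in self.force_peaks], indent=2))
        self.transform.to_json(outdir / "channel_transform.json")
        self.factors.to_json(outdir / "correction_factors.json")
        return outdir


def register_from_fiducials(
    donor_image: np.ndarray,
    acceptor_image: np.ndarray,
    det_config: Optional[DetectionConfig] = None,
    max_pair_dist: float = 5.0,
) -> AffineTransform:
    """Channel transform from a fiducial-bead image pair.

    Beads are localized in both channels, paired by mutual nearest
    neighbor after coarse translation and fitted with a robust affine.
    """
    d = detect.detect_spots(donor_image, det_config)
    a = detect.detect_spots(acceptor_image, det_config)
    src, dst = pair_beads(d[["x", "y"]].to_numpy(), a[["x", "y"]].to_numpy(),
                          max_dist=max_pair_dist)
    return fit_affine(src, dst, robust=True)


def analyze_movie(
    movie: Movie,
    transform: Optional[AffineTransform] = None,
    factors: Optional[CorrectionFactors] = None,
    params: Optional[CalibrationParams] = None,
    e_max: float = 0.8,
    cell_mask: Optional[CellMask] = None,
    det_config: Optional[DetectionConfig] = None,
    qc_config: Optional[QCConfig] = None,
    fit_mixture: bool = True,
    n_boot: int = 0,
    seed: int = 0,
) -> AnalysisResult:
    """Full single-movie analysis from raw counts to force peaks.

    ``transform`` maps donor-channel to acceptor-channel coordinates
    (identity if omitted); ``factors`` are the ALEX corrections
    (pre-estimated from calibration samples); ``e_max`` bounds the
    interpretable FRET range for the mixture fallback rule.
    """
    transform = transform or AffineTransform.identity()
    factors = factors or CorrectionFactors()
    params = params or default_params()
    from .dynrange import assemble_dynamic_range
    dyn_range = assemble_dynamic_range(params, e_max)

    camera = movie.camera
    photons = {c: counts_to_photons(stack, camera)
               for c, stack in movie.stacks.items()}
    stacks = {
        "DD": ChannelStack(photons["DD"], "DD", movie.timing.green_times(), "green"),
        "DA": ChannelStack(photons["DA"], "DA", movie.timing.green_times() + 1e-6, "green"),
        "AA": ChannelStack(photons["AA"], "AA", movie.timing.red_times(), "red"),
    }
    warped_dd = np.array([transform.warp_image(f) for f in photons["DD"]])
    sum_stack = warped_dd + photons["DA"]

    locs = detect.detect_candidates(sum_stack, photons["AA"], det_config)
    radius_px = SEARCH_RADIUS_NM / camera.pixel_size_nm
    tracks = detect.link_trajectories(locs, search_radius_px=radius_px)
    profile_g = (LaserProfile(movie.profiles["g"], "green")
                 if movie.profiles.get("g") is not None else None)
    profile_r = (LaserProfile(movie.profiles["r"], "red")
                 if movie.profiles.get("r") is not None else None)
    records = detect.build_records(tracks, stacks, transform,
                                   profile_g, profile_r, det_config)
    n_raw = len(records)
    filtered, report = apply_qc_chain(records, factors, profile_g,
                                      cell_mask, qc_config)
    filtered = add_forces(filtered, params) if len(filtered) else filtered

    fit = None
    peaks: List[ForcePeakSummary] = []
    if fit_mixture and len(filtered) >= 100:
        fit = fit_es_mixture(filtered, seed=seed, e_max=e_max)
        se = (bootstrap_fit(filtered, n_boot=n_boot, seed=seed, e_max=e_max)
              if n_boot else None)
        peaks = summarize_force_peaks(fit, params, dyn_range, se)
    return AnalysisResult(
        records=filtered, qc_report=report, fit=fit, force_peaks=peaks,
        transform=transform, factors=factors, params=params,
        dyn_range=dyn_range, n_raw_records=n_raw)


# ---------------------------------------------------------------------------
# config-driven runs
# ---------------------------------------------------------------------------

_SIM_KEYS = {"n_molecules", "shape", "e_states", "state_fractions",
             "total_rate", "diffusion", "camera", "timing", "factors",
             "acceptor_bleach_window_s", "donor_bleach_window_s"}


def _load_config(config: Union[str, Path, dict]) -> dict:
    if isinstance(config, (str, Path)):
        import yaml
        config = yaml.safe_load(Path(config).read_text())
    if not isinstance(config, dict):
        raise ValueError("config must be a mapping")
    return config


def run_simulation(
    config: Union[str, Path, dict], outdir: Union[str, Path], seed: int = 0
) -> Path:
    """Render a synthetic movie dataset to disk from a config mapping.

    Recognized keys (all optional): n_molecules, shape, e_states,
    state_fractions, total_rate, diffusion, camera, timing, factors and
    the bleach windows; unknown keys raise before any computation.
    """
    from .simulate import random_scene, render_movie, write_movie

    cfg = _load_config(config).get("simulation", _load_config(config))
    unknown = set(cfg) - _SIM_KEYS
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    camera = CameraParams(**cfg.get("camera", {}))
    timing = TimingParams(**cfg.get("timing", {}))
    factors = CorrectionFactors(**cfg.get("factors", {}))
    shape = tuple(cfg.get("shape", (128, 128)))
    scene = random_scene(
        n_molecules=int(cfg.get("n_molecules", 40)),
        shape=shape, camera=camera,
        e_states=cfg.get("e_states", (0.87, 0.42)),
        state_fractions=cfg.get("state_fractions", (0.79, 0.21)),
        total_rate=float(cfg.get("total_rate", 1500.0)),
        diffusion=float(cfg.get("diffusion", 0.001)),
        acceptor_bleach_window_s=tuple(cfg.get("acceptor_bleach_window_s",
                                               (1.0, 2.8))),
        donor_bleach_window_s=tuple(cfg.get("donor_bleach_window_s",
                                            (4.0, 12.0))),
        seed=seed)
    movie = render_movie(scene, camera, timing, shape=shape,
                         factors=factors, seed=seed + 1)
    return write_movie(movie, outdir, scene=scene)


def run_pipeline(
    config: Union[str, Path, dict],
    outdir: Union[str, Path],
    seed: int = 0,
) -> AnalysisResult:
    """Disk-to-disk analysis run driven by a YAML config.

    Config keys: ``movie_dir`` (required, a directory written by
    :func:`run_simulation`), optional ``factors`` (mapping or JSON
    path), ``calibration`` (mapping with e0 / spring constants),
    ``e_max``, ``n_boot``.  Writes records.csv, qc_report.csv,
    mixture_fit.json, force_peaks.json and a run log into ``outdir``.
    """
    from .image_prep import load_movie_dir
    import tifffile

    cfg = _load_config(config)
    if "movie_dir" not in cfg:
        raise ValueError("config must name a movie_dir")
    movie_dir = Path(cfg["movie_dir"])
    if not movie_dir.exists():
        raise FileNotFoundError(movie_dir)

    import yaml
    sidecar = yaml.safe_load((movie_dir / "movie.yaml").read_text())
    camera = CameraParams(**sidecar["camera"])
    timing = TimingParams(**sidecar["timing"])
    raw = {c: tifffile.imread(movie_dir / f)
           for c, f in sidecar["channels"].items()}
    movie = Movie(stacks=raw, camera=camera, timing=timing, truth=None,
                  donor_transform=AffineTransform.identity(),
                  profiles={"g": None, "r": None})

    fcfg = cfg.get("factors", {})
    factors = (CorrectionFactors.from_json(fcfg) if isinstance(fcfg, str)
               else CorrectionFactors(**fcfg))
    ccfg = dict(cfg.get("calibration", {}))
    e0 = ccfg.pop("e0", 0.87)
    params = calibrate_linker(e0, CalibrationParams(**ccfg))

    result = analyze_movie(
        movie, factors=factors, params=params,
        e_max=float(cfg.get("e_max", 0.8)),
        n_boot=int(cfg.get("n_boot", 0)), seed=seed)
    outdir = Path(outdir)
    result.write(outdir)
    log = {
        "seed": seed,
        "movie_dir": str(movie_dir),
        "n_raw_records": result.n_raw_records,
        "n_qc_records": len(result.records),
        "factors": dataclasses.asdict(factors),
        "calibration": dataclasses.asdict(params),
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2))
    return result
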