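"""Synthetic ALEX movie generator with full ground truth.

Emulates the imaging physics of a two-color alternating-excitation
TIRF/EMCCD experiment on bilayer-anchored FRET tension sensors: for
every frame doublet a green-excitation exposure produces a donor-
emission image (DD) and an acceptor-emission image (DA), and the
subsequent red exposure an acceptor image (AA).  Molecules carry a FRET
efficiency schedule, diffuse in 2D, and photobleach in a single step.

Photon bookkeeping (per frame, at unit laser intensity) for a 1:1 pair
with donor-channel photon budget N and correction factors
(alpha, delta, gamma, beta):

    f_DD = N * (1 - E)
    f_DA = gamma * N * E + alpha * f_DD + delta * f_AA
    f_AA = beta * gamma * N

so the standard accurate-FRET formulas recover E and S = 0.5 exactly in
expectation.  Expected photons are spread on the pixel grid with an
integrated Gaussian PSF, shot noise is Poissonian per pixel, and the
EMCCD conversion is counts = photons * em_gain / photons_per_count plus
Gaussian read noise and a constant offset (the gain's excess noise is
not modelled; the conversion is treated as the deterministic scale used
for photon calibration).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import special

from .calibration import CalibrationParams, DynamicRange, force_to_fret
from .fret import CorrectionFactors
from .registration import AffineTransform

__all__ = [
    "CameraParams",
    "TimingParams",
    "MoleculeSpec",
    "GroundTruth",
    "Movie",
    "render_movie",
    "render_fiducial_pair",
    "render_cell_image",
    "sample_es_mixture",
    "simulate_force_ramp_trace",
    "sample_brightness_records",
    "random_scene",
    "write_movie",
]


@dataclass(frozen=True)
class CameraParams:
    """EMCCD acquisition settings.

    ``photons_per_count`` is the manufacturer-calibrated conversion at
    the chosen readout settings; detected photons relate to digital
    counts via counts = photons * em_gain / photons_per_count.
    """

    photons_per_count: float = 15.7
    em_gain: float = 300.0
    pixel_size_nm: float = 160.0
    read_noise_sd: float = 20.0   # counts
    offset: float = 100.0         # counts

    def __post_init__(self) -> None:
        if self.photons_per_count <= 0 or self.pixel_size_nm <= 0:
            raise ValueError("photons_per_count and pixel size must be positive")
        if self.em_gain < 1:
            raise ValueError("em_gain must be >= 1")

    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size_nm / 1000.0

    @property
    def counts_per_photon(self) -> float:
        return self.em_gain / self.photons_per_count


@dataclass(frozen=True)
class TimingParams:
    """Illumination timing of the alternating excitation sequence.

    Times in milliseconds.  ``t_ill`` is the exposure per image,
    ``t_gr`` the green-to-red delay inside a doublet and ``t_delay`` the
    doublet-to-doublet delay; the effective frame-pair interval used for
    kinetics is t_ill + t_delay.
    """

    t_ill: float = 5.0
    t_gr: float = 10.0
    t_delay: float = 15.0
    n_frame_pairs: int = 300

    def __post_init__(self) -> None:
        if min(self.t_ill, self.t_gr, self.t_delay) <= 0 or self.n_frame_pairs < 1:
            raise ValueError("timing values must be positive")

    @property
    def pair_interval_s(self) -> float:
        return (self.t_ill + self.t_delay) / 1000.0

    @property
    def frame_rate(self) -> float:
        return 1.0 / self.pair_interval_s

    def green_times(self) -> np.ndarray:
        return np.arange(self.n_frame_pairs) * self.pair_interval_s

    def red_times(self) -> np.ndarray:
        return self.green_times() + (self.t_ill + self.t_gr) / 1000.0


#: multiplicity of (donors, acceptors) per stoichiometry class
_KIND_MULTIPLICITY = {
    "pair": (1, 1),
    "donor_only": (1, 0),
    "acceptor_only": (0, 1),
    "double_donor": (2, 1),
    "double_acceptor": (1, 2),
}


@dataclass
class MoleculeSpec:
    """Ground-truth description of one simulated molecule.

    Positions in micrometers, times in seconds.  ``e_schedule`` is a
    list of (start_time_s, efficiency) pairs; the state active at time t
    is the last one whose start precedes t.  ``total_rate`` is the
    donor-channel photon budget N per frame at unit laser intensity.
    """

    x_um: float
    y_um: float
    diffusion: float = 0.0                     # um^2/s
    e_schedule: List[Tuple[float, float]] = field(
        default_factory=lambda: [(0.0, 0.87)])
    total_rate: float = 1500.0                 # photons/frame
    acceptor_bleach_s: float = math.inf
    donor_bleach_s: float = math.inf
    kind: str = "pair"

    def __post_init__(self) -> None:
        if self.kind not in _KIND_MULTIPLICITY:
            raise ValueError(f"unknown stoichiometry class {self.kind!r}")
        for _, e in self.e_schedule:
            if not (0.0 <= e <= 1.0):
                raise ValueError("scheduled E must lie in [0, 1]")
        if self.acceptor_bleach_s < 0 or self.donor_bleach_s < 0:
            raise ValueError("bleach times must be >= 0")

    def efficiency_at(self, t: float) -> float:
        e = self.e_schedule[0][1]
        for start, val in self.e_schedule:
            if start <= t:
                e = val
            else:
                break
        return e


@dataclass
class GroundTruth:
    """Per-frame-pair truth table plus per-molecule summary.

    ``records`` columns: pair, molecule, x, y (px, acceptor geometry),
    f_dd, f_da, f_aa (expected photons at unit laser intensity),
    E_true, S_true, donor_alive, acceptor_alive, profile_g, profile_r.
    """

    records: pd.DataFrame
    molecules: pd.DataFrame
    cell_mask: Optional[np.ndarray] = None


@dataclass
class Movie:
    """Rendered three-channel stack with its generating truth."""

    stacks: Dict[str, np.ndarray]      # 'DD','DA','AA': (n_pairs, H, W) counts
    camera: CameraParams
    timing: TimingParams
    truth: GroundTruth
    donor_transform: AffineTransform
    profiles: Dict[str, Optional[np.ndarray]]

    @property
    def shape(self) -> Tuple[int, int]:
        return self.stacks["AA"].shape[1:]


def _integrated_gaussian_patch(
    x: float, y: float, sigma: float, shape: Tuple[int, int], radius: int
) -> Tuple[slice, slice, np.ndarray]:
    """Fraction of a unit PSF landing on each pixel of a local window.

    Pixel (i, j) covers [j-0.5, j+0.5] x [i-0.5, i+0.5]; the Gaussian is
    integrated over each pixel with error functions, so sub-pixel
    positions are rendered exactly.
    """
    h, w = shape
    j0, j1 = max(int(x) - radius, 0), min(int(x) + radius + 1, w)
    i0, i1 = max(int(y) - radius, 0), min(int(y) + radius + 1, h)
    if j0 >= j1 or i0 >= i1:
        return slice(0, 0), slice(0, 0), np.zeros((0, 0))
    xs = np.arange(j0, j1)
    ys = np.arange(i0, i1)
    s = sigma * math.sqrt(2.0)
    fx = 0.5 * (special.erf((xs + 0.5 - x) / s) - special.erf((xs - 0.5 - x) / s))
    fy = 0.5 * (special.erf((ys + 0.5 - y) / s) - special.erf((ys - 0.5 - y) / s))
    return slice(i0, i1), slice(j0, j1), np.outer(fy, fx)


def _profile_at(profile: Optional[np.ndarray], x: float, y: float) -> float:
    if profile is None:
        return 1.0
    h, w = profile.shape
    return float(profile[min(max(int(round(y)), 0), h - 1),
                         min(max(int(round(x)), 0), w - 1)])


def _camera_image(
    photon_img: np.ndarray, camera: CameraParams, rng: np.random.Generator
) -> np.ndarray:
    counts = rng.poisson(photon_img).astype(float) * camera.counts_per_photon
    counts += rng.normal(camera.offset, camera.read_noise_sd, photon_img.shape)
    return counts


def _expected_triplet(
    spec: MoleculeSpec, t_green: float, t_red: float,
    factors: CorrectionFactors,
) -> Tuple[float, float, float, float, bool, bool]:
    """Expected (f_dd, f_da, f_aa, E, donor_alive, acceptor_alive) at
    unit laser intensity for one frame doublet."""
    n_d, n_a = _KIND_MULTIPLICITY[spec.kind]
    d_alive = t_green < spec.donor_bleach_s
    a_alive_g = t_green < spec.acceptor_bleach_s
    a_alive_r = t_red < spec.acceptor_bleach_s
    e = spec.efficiency_at(t_green) if (a_alive_g and n_a > 0) else 0.0
    n = spec.total_rate
    f_dd = n * n_d * (1.0 - e) if d_alive else 0.0
    f_aa = factors.beta * factors.gamma * n * n_a if a_alive_r else 0.0
    f_aa_g = factors.beta * factors.gamma * n * n_a if a_alive_g else 0.0
    fret = factors.gamma * n * n_d * e if d_alive else 0.0
    f_da = fret + factors.alpha * f_dd + factors.delta * f_aa_g
    return f_dd, f_da, f_aa, e, d_alive, a_alive_g


def render_movie(
    scene: Sequence[MoleculeSpec],
    camera: Optional[CameraParams] = None,
    timing: Optional[TimingParams] = None,
    shape: Tuple[int, int] = (128, 128),
    psf_sigma: float = 1.0,
    factors: Optional[CorrectionFactors] = None,
    laser_profile_g: Optional[np.ndarray] = None,
    laser_profile_r: Optional[np.ndarray] = None,
    donor_transform: Optional[AffineTransform] = None,
    background_photons: float = 3.0,
    cell_mask: Optional[np.ndarray] = None,
    seed: Union[int, np.random.Generator, None] = 0,
) -> Movie:
    """Render a three-channel alternating-excitation movie.

    Molecule positions live in the acceptor channel's pixel grid; the
    DD channel is rendered in donor geometry (positions mapped through
    the inverse of ``donor_transform``), emulating the chromatic offset
    that registration must undo.  Molecules drifting outside the field
    are clipped silently (their truth rows remain).  Fixing the seed
    reproduces the stacks bit-identically.
    """
    camera = camera or CameraParams()
    timing = timing or TimingParams()
    factors = factors or CorrectionFactors()
    donor_transform = donor_transform or AffineTransform.identity()
    rng = np.random.default_rng(seed)
    h, w = shape
    n_pairs = timing.n_frame_pairs
    px = camera.pixel_size_um
    radius = int(math.ceil(5 * psf_sigma)) + 1
    t_inv = donor_transform.inverse()

    # diffusion paths, one green and one red position per pair
    t_green = timing.green_times()
    t_red = timing.red_times()
    dt_gr = (timing.t_ill + timing.t_gr) / 1000.0
    dt_rg = timing.pair_interval_s - dt_gr
    pos_g = np.empty((len(scene), n_pairs, 2))
    pos_r = np.empty((len(scene), n_pairs, 2))
    for m, spec in enumerate(scene):
        p = np.array([spec.x_um, spec.y_um]) / px
        step_gr = math.sqrt(2 * spec.diffusion * dt_gr) / px
        step_rg = math.sqrt(2 * spec.diffusion * dt_rg) / px
        for k in range(n_pairs):
            pos_g[m, k] = p
            p = p + rng.normal(0.0, step_gr, 2) if step_gr > 0 else p
            pos_r[m, k] = p
            p = p + rng.normal(0.0, step_rg, 2) if step_rg > 0 else p

    stacks = {c: np.empty((n_pairs, h, w), dtype=np.float32) for c in ("DD", "DA", "AA")}
    rows = []
    for k in range(n_pairs):
        img_dd = np.zeros(shape)
        img_da = np.zeros(shape)
        img_aa = np.zeros(shape)
        for m, spec in enumerate(scene):
            f_dd, f_da, f_aa, e, d_alive, a_alive = _expected_triplet(
                spec, float(t_green[k]), float(t_red[k]), factors)
            xg, yg = pos_g[m, k]
            xr, yr = pos_r[m, k]
            pg = _profile_at(laser_profile_g, xg, yg)
            pr = _profile_at(laser_profile_r, xr, yr)
            if f_dd > 0:
                xd, yd = t_inv.apply([xg, yg])
                sl_y, sl_x, patch = _integrated_gaussian_patch(xd, yd, psf_sigma, shape, radius)
                img_dd[sl_y, sl_x] += f_dd * pg * patch
            if f_da > 0:
                sl_y, sl_x, patch = _integrated_gaussian_patch(xg, yg, psf_sigma, shape, radius)
                img_da[sl_y, sl_x] += f_da * pg * patch
            if f_aa > 0:
                sl_y, sl_x, patch = _integrated_gaussian_patch(xr, yr, psf_sigma, shape, radius)
                img_aa[sl_y, sl_x] += f_aa * pr * patch
            s_true = np.nan
            denom = factors.gamma * f_dd + f_da - factors.alpha * f_dd - factors.delta * f_aa
            if denom + f_aa / factors.beta > 0:
                s_true = denom / (denom + f_aa / factors.beta)
            rows.append((k, m, xg, yg, f_dd, f_da, f_aa, e, s_true,
                         d_alive, a_alive, pg, pr))
        for name, img in (("DD", img_dd), ("DA", img_da), ("AA", img_aa)):
            stacks[name][k] = _camera_image(img + background_photons, camera, rng)

    records = pd.DataFrame(rows, columns=[
        "pair", "molecule", "x", "y", "f_dd", "f_da", "f_aa",
        "E_true", "S_true", "donor_alive", "acceptor_alive",
        "profile_g", "profile_r"])
    molecules = pd.DataFrame([
        {"molecule": m, "kind": s.kind, "x_um": s.x_um, "y_um": s.y_um,
         "diffusion": s.diffusion, "total_rate": s.total_rate,
         "acceptor_bleach_s": s.acceptor_bleach_s,
         "donor_bleach_s": s.donor_bleach_s,
         "acceptor_bleach_pair": int(np.searchsorted(t_green, s.acceptor_bleach_s))
         if np.isfinite(s.acceptor_bleach_s) else -1,
         "donor_bleach_pair": int(np.searchsorted(t_green, s.donor_bleach_s))
         if np.isfinite(s.donor_bleach_s) else -1}
        for m, s in enumerate(scene)])
    truth = GroundTruth(records=records, molecules=molecules, cell_mask=cell_mask)
    return Movie(stacks=stacks, camera=camera, timing=timing, truth=truth,
                 donor_transform=donor_transform,
                 profiles={"g": laser_profile_g, "r": laser_profile_r})


def random_scene(
    n_molecules: int,
    shape: Tuple[int, int] = (128, 128),
    camera: Optional[CameraParams] = None,
    e_states: Sequence[float] = (0.87, 0.42),
    state_fractions: Sequence[float] = (0.79, 0.21),
    total_rate: float = 1500.0,
    diffusion: float = 0.001,
    acceptor_bleach_window_s: Tuple[float, float] = (1.0, 2.8),
    donor_bleach_window_s: Tuple[float, float] = (4.0, 12.0),
    min_separation_px: float = 12.0,
    margin_px: float = 10.0,
    seed: Union[int, np.random.Generator, None] = 0,
) -> List[MoleculeSpec]:
    """Scene of immobile-ish sensor molecules with two FRET states.

    State membership is assigned deterministically in proportion to
    ``state_fractions`` (rounded), then shuffled, so the realized state
    weight does not carry binomial sampling noise.  Positions are drawn
    with a minimum pairwise separation to keep foreground circles
    disjoint; bleach times are uniform in the given windows.
    """
    camera = camera or CameraParams()
    rng = np.random.default_rng(seed)
    h, w = shape
    px = camera.pixel_size_um
    counts = np.floor(np.asarray(state_fractions) * n_molecules).astype(int)
    while counts.sum() < n_molecules:
        counts[int(np.argmax(np.asarray(state_fractions) * n_molecules - counts))] += 1
    states = np.repeat(np.asarray(e_states, dtype=float), counts)
    rng.shuffle(states)

    positions: List[Tuple[float, float]] = []
    attempts = 0
    while len(positions) < n_molecules and attempts < 200 * n_molecules:
        attempts += 1
        x = rng.uniform(margin_px, w - 1 - margin_px)
        y = rng.uniform(margin_px, h - 1 - margin_px)
        if all((x - a) ** 2 + (y - b) ** 2 >= min_separation_px ** 2
               for a, b in positions):
            positions.append((x, y))
    if len(positions) < n_molecules:
        raise ValueError("could not place molecules at requested density")

    scene = []
    for (x, y), e in zip(positions, states):
        scene.append(MoleculeSpec(
            x_um=x * px, y_um=y * px, diffusion=diffusion,
            e_schedule=[(0.0, float(e))], total_rate=total_rate,
            acceptor_bleach_s=rng.uniform(*acceptor_bleach_window_s),
            donor_bleach_s=rng.uniform(*donor_bleach_window_s),
            kind="pair"))
    return scene


def render_fiducial_pair(
    n_beads: int,
    true_affine: AffineTransform,
    shape: Tuple[int, int] = (128, 128),
    camera: Optional[CameraParams] = None,
    photons: float = 20000.0,
    psf_sigma: float = 1.0,
    min_separation_px: float = 10.0,
    background_photons: float = 5.0,
    seed: Union[int, np.random.Generator, None] = 0,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Donor/acceptor images of multicolor fiducial beads.

    Bead positions are defined in acceptor geometry; donor-image
    positions are the inverse affine applied to them, so registering the
    rendered pair should recover ``true_affine``.  Returns
    (donor_image, acceptor_image, donor_xy, acceptor_xy) with images in
    counts and coordinates in pixels.
    """
    if n_beads < 3:
        raise ValueError("need at least 3 beads")
    camera = camera or CameraParams()
    rng = np.random.default_rng(seed)
    h, w = shape
    acc = []
    attempts = 0
    while len(acc) < n_beads and attempts < 500 * n_beads:
        attempts += 1
        p = rng.uniform([8, 8], [w - 9, h - 9])
        if all(np.hypot(*(p - q)) >= min_separation_px for q in acc):
            acc.append(p)
    acceptor_xy = np.array(acc)
    donor_xy = true_affine.inverse().apply(acceptor_xy)

    def render(points: np.ndarray) -> np.ndarray:
        img = np.zeros(shape)
        for x, y in points:
            sl_y, sl_x, patch = _integrated_gaussian_patch(
                x, y, psf_sigma, shape, int(math.ceil(5 * psf_sigma)) + 1)
            img[sl_y, sl_x] += photons * patch
        return _camera_image(img + background_photons, camera, rng)

    return render(donor_xy), render(acceptor_xy), donor_xy, acceptor_xy


def render_cell_image(
    cell_blobs: Sequence[Tuple[float, float, float, float]],
    shape: Tuple[int, int] = (128, 128),
    camera: Optional[CameraParams] = None,
    background_photons: float = 50.0,
    edge_sigma_px: float = 2.0,
    seed: Union[int, np.random.Generator, None] = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Cell-indicator image (e.g. a calcium dye) plus its true mask.

    ``cell_blobs`` is a list of (cx_px, cy_px, radius_px, intensity)
    tuples where intensity is the expected photon count per pixel above
    background inside the disc.  Discs are smoothed at the rim and the
    union of discs is returned as ground-truth mask.
    """
    from scipy import ndimage

    camera = camera or CameraParams()
    rng = np.random.default_rng(seed)
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    photon_img = np.full(shape, float(background_photons))
    mask = np.zeros(shape, dtype=bool)
    for cx, cy, r, intensity in cell_blobs:
        disc = (xx - cx) ** 2 + (yy - cy) ** 2 <= r ** 2
        mask |= disc
        photon_img += intensity * ndimage.gaussian_filter(
            disc.astype(float), edge_sigma_px)
    return _camera_image(photon_img, camera, rng), mask


def sample_es_mixture(
    n: int,
    components: Sequence[Tuple[float, float, float, float, float]],
    seed: Union[int, np.random.Generator, None] = 0,
) -> pd.DataFrame:
    """Draw (E, S) points from a 2D Gaussian mixture.

    ``components`` entries are (weight, mean_E, sd_E, mean_S, sd_S);
    weights must sum to one.  Returns a DataFrame with columns
    E, S, component.
    """
    weights = np.array([c[0] for c in components], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("component weights must sum to 1")
    rng = np.random.default_rng(seed)
    labels = rng.choice(len(components), size=n, p=weights)
    e = np.empty(n)
    s = np.empty(n)
    for i, (_, me, se, ms, ss) in enumerate(components):
        sel = labels == i
        e[sel] = rng.normal(me, se, sel.sum())
        s[sel] = rng.normal(ms, ss, sel.sum())
    return pd.DataFrame({"E": e, "S": s, "component": labels})


def simulate_force_ramp_trace(
    loading_rate: float,
    peak_force: float,
    frame_rate: float,
    noise_sd_e: float,
    params: CalibrationParams,
    dyn_range: Optional[DynamicRange] = None,
    tail_s: float = 1.0,
    seed: Union[int, np.random.Generator, None] = 0,
) -> pd.DataFrame:
    """FRET trace of a linear force ramp ending in step-wise release.

    Force rises at ``loading_rate`` (pN/s) to ``peak_force`` and then
    drops instantaneously to zero for ``tail_s`` seconds, emulating a
    load-fail event; the observed efficiency is the noiseless
    force-to-FRET conversion plus Gaussian noise, clipped to (0, 1).
    Returns a frame-sampled DataFrame with t_s, F_true, E columns.
    """
    if loading_rate <= 0:
        raise ValueError("loading_rate must be positive")
    if dyn_range is not None and peak_force > dyn_range.F_max:
        raise ValueError("peak force exceeds the sensor's dynamic range")
    rng = np.random.default_rng(seed)
    t_peak = peak_force / loading_rate
    t = np.arange(0.0, t_peak + tail_s, 1.0 / frame_rate)
    f = np.where(t <= t_peak, loading_rate * t, 0.0)
    e = np.asarray(force_to_fret(f, params), dtype=float)
    if noise_sd_e > 0:
        e = e + rng.normal(0.0, noise_sd_e, len(e))
    e = np.clip(e, 1e-4, 1.0 - 1e-4)
    return pd.DataFrame({"t_s": t, "F_true": f, "E": e})


def sample_brightness_records(
    n_pairs: int,
    efficiency: float,
    factors: Optional[CorrectionFactors] = None,
    total_rate: float = 1500.0,
    kind: str = "pair",
    acceptor_bleach_pair: Optional[int] = None,
    donor_bleach_pair: Optional[int] = None,
    measurement_noise_sd: float = 5.0,
    particle: int = 0,
    seed: Union[int, np.random.Generator, None] = 0,
) -> pd.DataFrame:
    """Record-level brightness triplets without image rendering.

    Each photon stream (donor emission, FRET transfer, bleedthrough,
    direct excitation, acceptor emission) is drawn Poisson around the
    expectation of the movie model and an optional Gaussian term stands
    in for background-subtraction noise.  Used to exercise correction-
    factor estimators, step detection and the bleach filter quickly.
    """
    factors = factors or CorrectionFactors()
    rng = np.random.default_rng(seed)
    n_d, n_a = _KIND_MULTIPLICITY[kind]
    rows = []
    for k in range(n_pairs):
        d_alive = donor_bleach_pair is None or k < donor_bleach_pair
        a_alive = acceptor_bleach_pair is None or k < acceptor_bleach_pair
        e = efficiency if (a_alive and n_a > 0) else 0.0
        lam_dd = total_rate * n_d * (1 - e) if d_alive else 0.0
        lam_fret = factors.gamma * total_rate * n_d * e if d_alive else 0.0
        lam_aa = factors.beta * factors.gamma * total_rate * n_a if a_alive else 0.0
        f_dd = rng.poisson(lam_dd)
        f_aa = rng.poisson(lam_aa)
        f_da = (rng.poisson(lam_fret)
                + rng.poisson(factors.alpha * lam_dd)
                + rng.poisson(factors.delta * lam_aa))
        triplet = np.array([f_dd, f_da, f_aa], dtype=float)
        if measurement_noise_sd > 0:
            triplet += rng.normal(0.0, measurement_noise_sd, 3)
        rows.append((particle, k, *triplet))
    return pd.DataFrame(rows, columns=["particle", "pair", "f_dd", "f_da", "f_aa"])


# ---------------------------------------------------------------------------
# disk I/O
# ---------------------------------------------------------------------------

def write_movie(
    movie: Movie,
    outdir: Union[str, Path],
    scene: Optional[Sequence[MoleculeSpec]] = None,
) -> Path:
    """Write a rendered movie as per-channel TIFF stacks plus sidecar.

    Layout: DD.tif / DA.tif / AA.tif (float32 counts), movie.yaml with
    camera, timing and channel metadata, truth_records.csv and
    truth_molecules.csv with the ground truth; when the generating
    ``scene`` is passed it is stored as scene.yaml.
    """
    import tifffile
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, stack in movie.stacks.items():
        tifffile.imwrite(outdir / f"{name}.tif", stack.astype(np.float32))
    sidecar = {
        "channels": {"DD": "DD.tif", "DA": "DA.tif", "AA": "AA.tif"},
        "excitation": {"DD": "green", "DA": "green", "AA": "red"},
        "camera": asdict(movie.camera),
        "timing": asdict(movie.timing),
    }
    (outdir / "movie.yaml").write_text(yaml.safe_dump(sidecar))
    movie.truth.records.to_csv(outdir / "truth_records.csv", index=False)
    movie.truth.molecules.to_csv(outdir / "truth_molecules.csv", index=False)
    if scene is not None:
        payload = [{**asdict(s),
                    "e_schedule": [[float(t), float(e)]
                                   for t, e in s.e_schedule]}
                   for s in scene]
        (outdir / "scene.yaml").write_text(yaml.safe_dump(payload))
    return outdir
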