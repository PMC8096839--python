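"""Single-molecule detection, trajectory linking and brightness readout.

Candidates are localized on the registered sum image T(Im_DD) + Im_DA
for the green exposures (so low- and high-FRET molecules are detected
with equal sensitivity) and on Im_AA for the red exposures; the two
localization streams are interlaced in recording order and linked into
trajectories by nearest-neighbor assignment with gap closing.  Gaps are
filled by linear position interpolation.  Brightness triplets are then
integrated in a fixed foreground circle over the blurred raw images,
with the local background taken from a surrounding annulus, and divided
by the laser profile at the molecule position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize
from skimage.feature import peak_local_max

from .image_prep import ChannelStack, LaserProfile, blur_for_detection
from .registration import AffineTransform

__all__ = [
    "DetectionConfig",
    "detect_spots",
    "detect_candidates",
    "link_trajectories",
    "measure_brightness",
    "build_records",
]

SEARCH_RADIUS_NM = 800.0     # max displacement between consecutive frames
LINK_MEMORY = 3              # frames a molecule may go dark
MIN_TRACK_LENGTH = 4         # observations


@dataclass(frozen=True)
class DetectionConfig:
    """Spot-finding and brightness-readout geometry."""

    threshold_k: float = 4.0        # amplitude > k * local noise sd
    min_distance_px: int = 3        # minimum peak separation
    psf_sigma: float = 1.0          # expected spot width (before blur)
    blur_sigma: float = 1.0         # detection blur
    fit_halfwidth: int = 4          # Gaussian-fit window half size
    fg_radius: float = 4.5          # foreground circle (9 px diameter)
    bg_outer: float = 7.5           # background annulus outer radius


def _robust_sd(img: np.ndarray) -> float:
    med = np.median(img)
    return float(1.4826 * np.median(np.abs(img - med)))


def _gauss2d(params, xx, yy):
    amp, x0, y0, sigma, bg = params
    return amp * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sigma ** 2)) + bg


def _fit_gaussian(img: np.ndarray, x0: int, y0: int, cfg: DetectionConfig):
    """Least-squares 2D Gaussian refinement around an integer peak.

    Returns (x, y, amplitude, sigma, ok); falls back to the intensity-
    weighted centroid when the fit runs away from the peak.
    """
    h, w = img.shape
    hw = cfg.fit_halfwidth
    x_lo, x_hi = max(x0 - hw, 0), min(x0 + hw + 1, w)
    y_lo, y_hi = max(y0 - hw, 0), min(y0 + hw + 1, h)
    win = img[y_lo:y_hi, x_lo:x_hi]
    yy, xx = np.mgrid[y_lo:y_hi, x_lo:x_hi]
    bg0 = float(win.min())
    amp0 = float(img[y0, x0] - bg0)
    p0 = np.array([max(amp0, 1e-3), x0, y0,
                   math.hypot(cfg.psf_sigma, cfg.blur_sigma), bg0])

    def resid(p):
        return (_gauss2d(p, xx, yy) - win).ravel()

    try:
        sol = optimize.least_squares(resid, p0, method="lm",
                                     xtol=1e-6, ftol=1e-6, max_nfev=100)
        amp, x, y, sigma, _ = sol.x
        sigma = abs(sigma)
        ok = (abs(x - x0) <= 2 and abs(y - y0) <= 2
              and 0.3 <= sigma <= 4.0 and amp > 0)
    except Exception:
        ok = False
    if not ok:
        wpos = np.clip(win - bg0, 0, None)
        tot = wpos.sum()
        if tot <= 0:
            return float(x0), float(y0), amp0, p0[3], False
        x = float((wpos * xx).sum() / tot)
        y = float((wpos * yy).sum() / tot)
        return x, y, amp0, p0[3], False
    return float(x), float(y), float(amp), float(sigma), True


def detect_spots(
    image: np.ndarray,
    config: Optional[DetectionConfig] = None,
) -> pd.DataFrame:
    """Detect diffraction-limited spots in one image.

    The image is blurred (sigma 1 px), local maxima exceeding the
    median by ``threshold_k`` noise standard deviations are refined by a
    2D Gaussian least-squares fit to sub-pixel accuracy.  Returns a
    DataFrame with x, y, amplitude, sigma, fit_ok columns (possibly
    empty).
    """
    cfg = config or DetectionConfig()
    blurred = blur_for_detection(image, cfg.blur_sigma)
    noise = _robust_sd(blurred)
    thresh = float(np.median(blurred)) + cfg.threshold_k * noise
    peaks = peak_local_max(blurred, min_distance=cfg.min_distance_px,
                           threshold_abs=thresh, exclude_border=2)
    rows = []
    for y0, x0 in peaks:
        x, y, amp, sigma, ok = _fit_gaussian(blurred, int(x0), int(y0), cfg)
        rows.append((x, y, amp, sigma, ok))
    return pd.DataFrame(rows, columns=["x", "y", "amplitude", "sigma", "fit_ok"])


def detect_candidates(
    sum_stack: np.ndarray,
    aa_stack: np.ndarray,
    config: Optional[DetectionConfig] = None,
) -> pd.DataFrame:
    """Localize candidates on sum (green) and AA (red) stacks, interlaced.

    Frame-pair k yields interlaced frame indices 2k (green) and 2k+1
    (red), preserving the recording sequence for the tracker.  All
    coordinates are in the acceptor channel's geometry.
    """
    if len(sum_stack) != len(aa_stack):
        raise ValueError("sum and AA stacks must have equal length")
    frames = []
    for k in range(len(sum_stack)):
        for offset, img in ((0, sum_stack[k]), (1, aa_stack[k])):
            locs = detect_spots(img, config)
            locs["frame"] = 2 * k + offset
            locs["pair"] = k
            locs["excitation"] = "green" if offset == 0 else "red"
            if len(locs):
                frames.append(locs)
    if not frames:
        return pd.DataFrame(columns=["x", "y", "amplitude", "sigma",
                                     "fit_ok", "frame", "pair", "excitation"])
    return pd.concat(frames, ignore_index=True)


def link_trajectories(
    localizations: pd.DataFrame,
    search_radius_px: float,
    memory: int = LINK_MEMORY,
    min_length: int = MIN_TRACK_LENGTH,
) -> pd.DataFrame:
    """Link localizations into trajectories with gap closing.

    Frame-by-frame globally optimal nearest-neighbor assignment
    (Hungarian algorithm) with a hard distance gate of
    ``search_radius_px`` between consecutive frames; molecules may go
    dark for up to ``memory`` frames (the gate grows with the square
    root of the gap length, as expected for Brownian motion).  Missed
    frames are filled by linear interpolation between the flanking
    detections and flagged ``interpolated``.  Trajectories with fewer
    than ``min_length`` true observations are discarded.

    Linking is permutation-invariant with respect to input row order.
    Returns a DataFrame with particle, frame, x, y, interpolated.
    """
    if localizations.empty:
        return pd.DataFrame(columns=["particle", "frame", "x", "y", "interpolated"])
    locs = localizations.sort_values(["frame", "x", "y"]).reset_index(drop=True)
    tracks: List[dict] = []     # {'frames': [...], 'xy': [...], 'last': int}
    active: List[int] = []
    big = 1e9
    for frame, group in locs.groupby("frame"):
        pts = group[["x", "y"]].to_numpy(float)
        frame = int(frame)
        active = [i for i in active if frame - tracks[i]["last"] <= memory + 1]
        if active and len(pts):
            cost = np.full((len(active), len(pts)), big)
            for r, ti in enumerate(active):
                tr = tracks[ti]
                gap = frame - tr["last"]
                gate = search_radius_px * math.sqrt(gap)
                d = np.hypot(*(pts - tr["xy"][-1]).T)
                cost[r, d <= gate] = d[d <= gate]
            rows, cols = optimize.linear_sum_assignment(cost)
            taken = set()
            for r, c in zip(rows, cols):
                if cost[r, c] < big:
                    ti = active[r]
                    tracks[ti]["frames"].append(frame)
                    tracks[ti]["xy"].append(pts[c])
                    tracks[ti]["last"] = frame
                    taken.add(c)
        else:
            taken = set()
        assigned_tracks = {active[r] for r, c in zip(rows, cols)
                           if cost[r, c] < big} if active and len(pts) else set()
        active = [i for i in active if i in assigned_tracks
                  or frame - tracks[i]["last"] <= memory]
        for c in range(len(pts)):
            if c not in taken:
                tracks.append({"frames": [frame], "xy": [pts[c]], "last": frame})
                active.append(len(tracks) - 1)

    out_rows = []
    pid = 0
    for tr in tracks:
        if len(tr["frames"]) < min_length:
            continue
        frames = np.asarray(tr["frames"])
        xy = np.asarray(tr["xy"])
        full = np.arange(frames[0], frames[-1] + 1)
        xi = np.interp(full, frames, xy[:, 0])
        yi = np.interp(full, frames, xy[:, 1])
        observed = np.isin(full, frames)
        for f, x, y, obs in zip(full, xi, yi, observed):
            out_rows.append((pid, int(f), float(x), float(y), not obs))
        pid += 1
    return pd.DataFrame(out_rows,
                        columns=["particle", "frame", "x", "y", "interpolated"])


# ---------------------------------------------------------------------------
# brightness
# ---------------------------------------------------------------------------

def _disk_offsets(radius: float) -> np.ndarray:
    r = int(math.floor(radius))
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    sel = dy ** 2 + dx ** 2 <= radius ** 2
    return np.column_stack([dy[sel], dx[sel]])


def _annulus_offsets(inner: float, outer: float) -> np.ndarray:
    r = int(math.floor(outer))
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    rr = dy ** 2 + dx ** 2
    sel = (rr > inner ** 2) & (rr <= outer ** 2)
    return np.column_stack([dy[sel], dx[sel]])


def measure_brightness(
    image: np.ndarray,
    x: float,
    y: float,
    neighbors: Optional[np.ndarray] = None,
    fg_radius: float = 4.5,
    bg_outer: float = 7.5,
) -> Tuple[float, bool, bool]:
    """Background-corrected integrated brightness at one position.

    Sums the pixels whose centers lie within ``fg_radius`` of the
    rounded position and subtracts the mean of an annulus
    (``fg_radius``..``bg_outer``); annulus pixels within ``fg_radius``
    of any neighbor position are excluded from the background estimate.
    Returns (photons, overlap_flag, edge_flag); ``overlap`` marks a
    neighbor closer than two foreground radii, ``edge`` a position too
    close to the border for the annulus.
    """
    h, w = image.shape
    cx, cy = int(round(x)), int(round(y))
    edge = not (bg_outer <= cx <= w - 1 - bg_outer
                and bg_outer <= cy <= h - 1 - bg_outer)
    fg = _disk_offsets(fg_radius) + (cy, cx)
    ring = _annulus_offsets(fg_radius, bg_outer) + (cy, cx)
    fg = fg[(fg[:, 0] >= 0) & (fg[:, 0] < h) & (fg[:, 1] >= 0) & (fg[:, 1] < w)]
    ring = ring[(ring[:, 0] >= 0) & (ring[:, 0] < h)
                & (ring[:, 1] >= 0) & (ring[:, 1] < w)]
    overlap = False
    if neighbors is not None and len(neighbors):
        nb = np.asarray(neighbors, dtype=float).reshape(-1, 2)
        d = np.hypot(nb[:, 0] - x, nb[:, 1] - y)
        nb = nb[d > 1e-6]
        d = d[d > 1e-6]
        overlap = bool(np.any(d < 2 * fg_radius))
        if len(nb):
            dist2 = ((ring[:, 1, None] - nb[None, :, 0]) ** 2
                     + (ring[:, 0, None] - nb[None, :, 1]) ** 2)
            ring = ring[np.all(dist2 > fg_radius ** 2, axis=1)]
    if len(ring):
        bg = float(image[ring[:, 0], ring[:, 1]].mean())
    else:
        bg = float(np.median(image))  # annulus fully occluded
    f = float(image[fg[:, 0], fg[:, 1]].sum() - len(fg) * bg)
    return f, overlap, edge


def build_records(
    tracks: pd.DataFrame,
    stacks: Dict[str, ChannelStack],
    transform: AffineTransform,
    profile_g: Optional[LaserProfile] = None,
    profile_r: Optional[LaserProfile] = None,
    config: Optional[DetectionConfig] = None,
) -> pd.DataFrame:
    """Assemble per-frame-pair brightness records for linked trajectories.

    For each pair the green-frame position provides f_DA (acceptor
    geometry) and, mapped through the inverse channel transform, f_DD
    (donor geometry); the red-frame position provides f_AA.  Brightness
    is integrated on the blurred raw images and divided by the laser
    profile at the position.  Records are flagged when built from
    interpolated positions, overlapping circles or edge-clipped annuli;
    edge records are dropped.
    """
    cfg = config or DetectionConfig()
    t_inv = transform.inverse()
    blurred = {c: np.array([blur_for_detection(f, cfg.blur_sigma)
                            for f in s.frames]) for c, s in stacks.items()}
    # positions per interlaced frame for neighbor exclusion
    by_frame = {f: g[["x", "y"]].to_numpy(float)
                for f, g in tracks.groupby("frame")}
    rows = []
    for pid, tr in tracks.groupby("particle"):
        tr = tr.set_index("frame")
        pairs = sorted({f // 2 for f in tr.index})
        for p in pairs:
            gf, rf = 2 * p, 2 * p + 1
            if gf not in tr.index or rf not in tr.index:
                continue
            g = tr.loc[gf]
            r = tr.loc[rf]
            xg, yg = float(g["x"]), float(g["y"])
            xr, yr = float(r["x"]), float(r["y"])
            xd, yd = t_inv.apply([xg, yg])
            nb_g = by_frame.get(gf)
            nb_r = by_frame.get(rf)
            f_da, ov1, e1 = measure_brightness(
                blurred["DA"][p], xg, yg, nb_g, cfg.fg_radius, cfg.bg_outer)
            f_dd, ov2, e2 = measure_brightness(
                blurred["DD"][p], xd, yd,
                t_inv.apply(nb_g) if nb_g is not None else None,
                cfg.fg_radius, cfg.bg_outer)
            f_aa, ov3, e3 = measure_brightness(
                blurred["AA"][p], xr, yr, nb_r, cfg.fg_radius, cfg.bg_outer)
            if e1 or e2 or e3:
                continue
            pg = float(profile_g.at(xg, yg)) if profile_g is not None else 1.0
            pr = float(profile_r.at(xr, yr)) if profile_r is not None else 1.0
            rows.append((int(pid), int(p), xg, yg,
                         f_dd / pg, f_da / pg, f_aa / pr,
                         bool(g["interpolated"] or r["interpolated"]),
                         ov1 or ov2 or ov3))
    return pd.DataFrame(rows, columns=[
        "particle", "pair", "x", "y", "f_dd", "f_da", "f_aa",
        "interpolated", "overlap"])
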