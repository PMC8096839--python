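"""Trajectory quality control for single-molecule FRET movies.

The filter chain mirrors standard smFRET practice for surface-tethered
sensors: discard signals from poorly illuminated regions, from
overlapping emitters, and from molecules not present at movie start;
demand single-step acceptor photobleaching (the fingerprint of a single
emitter); truncate traces at the first bleaching event; reject species
with aberrant stoichiometry (multiple donors or acceptors); and, for
cell experiments, keep only molecules underneath an adhered cell.

Step detection is a greedy piecewise-constant changepoint fit with a
BIC stopping rule plus an amplitude-significance filter; it is shared
by the bleach filter and the gamma-factor estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "StepDetectionResult",
    "detect_steps",
    "CellMask",
    "QCConfig",
    "filter_laser_region",
    "filter_overlap",
    "filter_first_frame",
    "bleach_filter",
    "filter_stoichiometry",
    "make_cell_mask",
    "select_in_mask",
    "apply_qc_chain",
]


# ---------------------------------------------------------------------------
# step detection
# ---------------------------------------------------------------------------

@dataclass
class StepDetectionResult:
    """Changepoints of a piecewise-constant intensity trace.

    ``step_frames[i]`` is the index of the first sample *after* step i;
    ``step_amplitudes[i]`` the level change (post minus pre, so bleaching
    steps are negative).  ``plateau_levels`` are the segment means.
    """

    step_frames: List[int]
    step_amplitudes: List[float]
    plateau_levels: List[float]
    noise_sd: float

    @property
    def n_steps(self) -> int:
        return len(self.step_frames)


def _best_split(y: np.ndarray, min_seg: int = 2) -> Tuple[int, float]:
    """Best single changepoint of a segment: (index, SSE reduction).

    Splits creating segments shorter than ``min_seg`` are not offered,
    which keeps single noise spikes at segment edges from being fitted
    as one-sample plateaus.
    """
    n = len(y)
    if n < 2 * min_seg:
        return -1, 0.0
    csum = np.cumsum(y)
    total = csum[-1]
    i = np.arange(min_seg, n - min_seg + 1)
    left = csum[i - 1] ** 2 / i
    right = (total - csum[i - 1]) ** 2 / (n - i)
    gain = left + right - total ** 2 / n
    k = int(np.argmax(gain))
    return int(i[k]), float(gain[k])


def robust_noise_sd(y: np.ndarray) -> float:
    """Noise scale from the MAD of first differences (step-insensitive)."""
    d = np.diff(np.asarray(y, dtype=float))
    if len(d) == 0:
        return 0.0
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0))


def detect_steps(
    trace: Sequence[float],
    min_step_sd: float = 3.0,
    max_steps: Optional[int] = None,
) -> StepDetectionResult:
    """Find discrete intensity steps in a photon time trace.

    Greedy binary segmentation: repeatedly insert the changepoint with
    the largest residual-sum-of-squares gain, stopping once the BIC
    (2 parameters per step) no longer improves.  Candidate steps whose
    amplitude is below ``min_step_sd`` times the trace noise are then
    discarded, which keeps the false-positive rate on step-free noise
    traces low without sacrificing sensitivity to bleaching steps.
    """
    y = np.asarray(trace, dtype=float)
    n = len(y)
    if n < 4:
        raise ValueError("trace must have at least 4 samples")
    noise = robust_noise_sd(y)

    boundaries = [0, n]
    sse = float(np.sum((y - y.mean()) ** 2))
    eps = 1e-12
    while max_steps is None or len(boundaries) - 2 < max_steps:
        best = None
        for a, b in zip(boundaries[:-1], boundaries[1:]):
            if b - a < 2:
                continue
            k, gain = _best_split(y[a:b])
            if k > 0 and (best is None or gain > best[2]):
                best = (a, a + k, gain)
        if best is None:
            break
        new_sse = max(sse - best[2], eps)
        # BIC: n*ln(SSE/n) + 2*ln(n) per changepoint (level + position)
        if n * np.log(new_sse / n + eps) + 2.0 * np.log(n) >= n * np.log(sse / n + eps):
            break
        boundaries = sorted(boundaries + [best[1]])
        sse = new_sse

    # significance filter on amplitudes, re-evaluated after each removal;
    # photon noise is heteroscedastic (shot noise scales with the level),
    # so each step is judged against the local noise of its two plateaus
    def _seg_noise(a: int, b: int) -> float:
        if b - a < 4:
            return noise
        return max(robust_noise_sd(y[a:b]), 1e-12)

    while True:
        levels = [float(y[a:b].mean())
                  for a, b in zip(boundaries[:-1], boundaries[1:])]
        amps = np.diff(levels)
        if len(amps) == 0:
            break
        local = [max(_seg_noise(boundaries[i], boundaries[i + 1]),
                     _seg_noise(boundaries[i + 1], boundaries[i + 2]))
                 for i in range(len(amps))]
        signif = [abs(a) / s if s > 0 else np.inf
                  for a, s in zip(amps, local)]
        weakest = int(np.argmin(signif))
        if signif[weakest] < min_step_sd or amps[weakest] == 0:
            boundaries.pop(weakest + 1)
            continue
        break

    levels = [float(y[a:b].mean())
              for a, b in zip(boundaries[:-1], boundaries[1:])]
    frames = boundaries[1:-1]
    amps = list(np.diff(levels))
    return StepDetectionResult(frames, amps, levels, noise)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

@dataclass
class QCConfig:
    """All thresholds of the trajectory filter chain (defaults as used
    throughout the package)."""

    laser_threshold: float = 0.5        # min relative laser intensity
    max_overlap_fraction: float = 0.25  # trajectory discarded above this
    max_bad_s_fraction: float = 0.25    # stoichiometry rule
    s_min: float = 0.35                 # below: >=2 acceptors per donor
    s_max: float = 0.6                  # above: >=2 donors per acceptor
    min_step_sd: float = 3.0
    baseline_sd: float = 3.0            # |level| below this*noise ~ background
    min_length: int = 4


@dataclass
class CellMask:
    """Binary cell footprint derived from an indicator image."""

    mask: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


def _profile_array(profile) -> np.ndarray:
    return np.asarray(getattr(profile, "profile", profile), dtype=float)


def filter_laser_region(
    records: pd.DataFrame, profile, threshold: float = 0.5
) -> pd.DataFrame:
    """Drop records where the donor laser falls below ``threshold`` of max."""
    prof = _profile_array(profile)
    iy = np.clip(np.rint(records["y"].to_numpy(float)).astype(int), 0, prof.shape[0] - 1)
    ix = np.clip(np.rint(records["x"].to_numpy(float)).astype(int), 0, prof.shape[1] - 1)
    return records[prof[iy, ix] >= threshold]


def filter_overlap(
    records: pd.DataFrame, max_fraction: float = 0.25
) -> pd.DataFrame:
    """Apply the overlapping-foreground rule.

    Trajectories where more than ``max_fraction`` of records carry the
    ``overlap`` flag are discarded entirely; in the remainder only the
    flagged records are removed.
    """
    if "overlap" not in records.columns:
        return records
    frac = records.groupby("particle")["overlap"].transform("mean")
    kept = records[frac <= max_fraction]
    return kept[~kept["overlap"].astype(bool)]


def filter_first_frame(records: pd.DataFrame) -> pd.DataFrame:
    """Keep only trajectories already present in frame-pair 0, so the
    full photobleaching history of each survivor is on record."""
    first = records.groupby("particle")["pair"].transform("min")
    return records[first == 0]


def bleach_filter(
    records: pd.DataFrame,
    min_step_sd: float = 3.0,
    baseline_sd: float = 3.0,
    min_length: int = 4,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Single-emitter selection by photobleaching analysis.

    Per trajectory, steps are detected independently in f_AA and in
    f_DD + f_DA.  A trajectory is accepted iff f_AA shows exactly one
    (downward) bleaching step and the donor-excitation total shows no
    partial bleaching, i.e. no downward step whose post-step plateau
    stays significantly above background (such steps indicate multiple
    donors).  A terminal drop of the total to background level is an
    ordinary donor bleach and merely truncates the trace.  Accepted
    trajectories are cut before the earliest bleaching event.

    Returns (truncated records of accepted trajectories, report frame
    with per-trajectory decision and truncation index).
    """
    kept = []
    report = []
    for pid, traj in records.groupby("particle"):
        traj = traj.sort_values("pair")
        f_aa = traj["f_aa"].to_numpy(float)
        total = (traj["f_dd"] + traj["f_da"]).to_numpy(float)
        if len(traj) < min_length:
            report.append((pid, False, "too_short", -1))
            continue
        aa = detect_steps(f_aa, min_step_sd)
        aa_down = [f for f, a in zip(aa.step_frames, aa.step_amplitudes) if a < 0]
        if aa.n_steps != 1 or len(aa_down) != 1:
            report.append((pid, False, "aa_not_single_step", -1))
            continue
        tot = detect_steps(total, min_step_sd)
        noise = max(tot.noise_sd, 1e-9)
        trunc = aa_down[0]
        partial = False
        for i, (f, a) in enumerate(zip(tot.step_frames, tot.step_amplitudes)):
            if a >= 0:
                continue  # e.g. the rise/fall bookkeeping around acceptor bleach
            post_level = tot.plateau_levels[i + 1]
            if abs(post_level) <= baseline_sd * noise:
                trunc = min(trunc, f)  # donor bleach to background
            else:
                partial = True
                break
        if partial:
            report.append((pid, False, "partial_donor_bleach", -1))
            continue
        if trunc < min_length:
            report.append((pid, False, "bleached_too_early", trunc))
            continue
        pairs = traj["pair"].to_numpy()
        kept.append(traj[traj["pair"] < pairs[trunc]])
        report.append((pid, True, "", trunc))
    out = (pd.concat(kept, ignore_index=True) if kept
           else records.iloc[0:0].copy())
    rep = pd.DataFrame(report, columns=["particle", "accepted", "reason",
                                        "truncation_index"])
    return out, rep


def filter_stoichiometry(
    records: pd.DataFrame,
    s_min: float = 0.35,
    s_max: float = 0.6,
    max_fraction: float = 0.25,
) -> pd.DataFrame:
    """Remove trajectories dominated by aberrant stoichiometry.

    S > s_max flags two or more donors per acceptor, S < s_min two or
    more acceptors per donor (mis-synthesized sensors or clusters); a
    trajectory is dropped when more than ``max_fraction`` of its records
    fall outside [s_min, s_max].
    """
    s = records["S"]
    bad = (s > s_max) | (s < s_min) | ~np.isfinite(s)
    frac = bad.groupby(records["particle"]).transform("mean")
    return records[frac <= max_fraction]


def make_cell_mask(
    indicator: np.ndarray,
    block_size: int = 51,
    offset: Optional[float] = None,
    min_size: int = 0,
    source: str = "",
) -> CellMask:
    """Adaptive-threshold segmentation of a cell-indicator image.

    Local-mean thresholding over ``block_size`` blocks; a pixel belongs
    to a cell when it exceeds its local mean by ``offset`` (default:
    three robust noise standard deviations, so a featureless image
    yields an empty mask).  Small specks below ``min_size`` pixels are
    removed.
    """
    from scipy import ndimage
    from skimage.filters import threshold_local

    img = np.asarray(indicator, dtype=float)
    if offset is None:
        mad = np.median(np.abs(img - np.median(img)))
        offset = 3.0 * 1.4826 * mad
    thresh = threshold_local(img, block_size=block_size, method="mean",
                             offset=-offset)
    mask = img > thresh
    if min_size > 0 and mask.any():
        labels, n = ndimage.label(mask)
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= min_size) + 1
        mask = np.isin(labels, keep)
    return CellMask(mask=mask, source=source)


def select_in_mask(records: pd.DataFrame, mask: CellMask) -> pd.DataFrame:
    """Keep records whose position lies inside the cell mask."""
    m = mask.mask
    iy = np.clip(np.rint(records["y"].to_numpy(float)).astype(int), 0, m.shape[0] - 1)
    ix = np.clip(np.rint(records["x"].to_numpy(float)).astype(int), 0, m.shape[1] - 1)
    return records[m[iy, ix]]


def apply_qc_chain(
    records: pd.DataFrame,
    factors,
    laser_profile=None,
    cell_mask: Optional[CellMask] = None,
    config: Optional[QCConfig] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full filter chain in its canonical order.

    laser -> overlap -> first frame -> bleach -> E/S -> stoichiometry ->
    cell mask.  ``factors`` are the ALEX correction factors used for the
    E/S computation between the bleach and stoichiometry stages.
    Returns the surviving records plus a per-trajectory report naming
    the stage that removed each casualty.  The chain is idempotent:
    survivors pass a second application unchanged.
    """
    from .fret import compute_es  # local import; fret uses detect_steps

    cfg = config or QCConfig()
    stage_of: dict = {}

    def note_removed(before: pd.DataFrame, after: pd.DataFrame, stage: str):
        gone = set(before["particle"].unique()) - set(after["particle"].unique())
        for pid in gone:
            stage_of.setdefault(pid, stage)

    cur = records
    if laser_profile is not None:
        nxt = filter_laser_region(cur, laser_profile, cfg.laser_threshold)
        note_removed(cur, nxt, "laser_region")
        cur = nxt
    nxt = filter_overlap(cur, cfg.max_overlap_fraction)
    note_removed(cur, nxt, "overlap")
    cur = nxt
    nxt = filter_first_frame(cur)
    note_removed(cur, nxt, "first_frame")
    cur = nxt
    nxt, _ = bleach_filter(cur, cfg.min_step_sd, cfg.baseline_sd, cfg.min_length)
    note_removed(cur, nxt, "bleach")
    cur = nxt
    cur = compute_es(cur, factors)
    cur = cur[~cur["es_invalid"]]
    nxt = filter_stoichiometry(cur, cfg.s_min, cfg.s_max, cfg.max_bad_s_fraction)
    note_removed(cur, nxt, "stoichiometry")
    cur = nxt
    if cell_mask is not None:
        nxt = select_in_mask(cur, cell_mask)
        note_removed(cur, nxt, "cell_mask")
        cur = nxt
    report = pd.DataFrame(
        [(pid, stage) for pid, stage in sorted(stage_of.items())],
        columns=["particle", "removed_by"],
    )
    return cur.reset_index(drop=True), report
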