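"""Corrected single-molecule FRET efficiency and stoichiometry (ALEX).

Alternating laser excitation yields, per molecule and frame doublet,
three background-corrected brightness values: donor emission under donor
excitation (f_DD), acceptor emission under donor excitation (f_DA) and
acceptor emission under acceptor excitation (f_AA).  Four correction
factors enter the accurate-FRET formulas:

* alpha — donor emission bleeding into the acceptor detection channel,
* delta — direct excitation of the acceptor by the donor laser,
* gamma — acceptor/donor detection-efficiency ratio,
* beta  — acceptor/donor excitation-efficiency ratio (scales f_AA).

With F_fret = f_DA - alpha*f_DD - delta*f_AA,

    E = F_fret / (gamma*f_DD + F_fret)
    S = (gamma*f_DD + F_fret) / (gamma*f_DD + F_fret + f_AA/beta)

S ~ 0.5 marks intact 1:1 donor/acceptor pairs; S near 1 donor-only and
S near 0 acceptor-only species.  alpha and delta are estimated from
donor-only and acceptor-only samples, gamma globally from acceptor
photobleaching events of a high-FRET control sensor, and beta by
requiring the median S of a known 1:1 sample to be 0.5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import optimize

from .qc import detect_steps

__all__ = [
    "CorrectionFactors",
    "estimate_alpha",
    "estimate_delta",
    "estimate_gamma",
    "estimate_beta",
    "compute_es",
]

MIN_RECORDS = 50


@dataclass(frozen=True)
class CorrectionFactors:
    """ALEX correction factors; the identity element is all-trivial."""

    alpha: float = 0.0
    delta: float = 0.0
    gamma: float = 1.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.beta <= 0:
            raise ValueError("gamma and beta must be positive")
        if self.alpha < 0 or self.delta < 0:
            raise ValueError("alpha and delta must be >= 0")

    def to_json(self, path: Union[str, Path], **provenance) -> None:
        payload = {**asdict(self), "provenance": provenance}
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "CorrectionFactors":
        payload = json.loads(Path(path).read_text())
        payload.pop("provenance", None)
        return cls(**payload)


def _require(records: pd.DataFrame, n: int = MIN_RECORDS) -> None:
    if len(records) < n:
        raise ValueError(f"need at least {n} records, got {len(records)}")


def estimate_alpha(donor_only: pd.DataFrame) -> float:
    """Donor bleedthrough: median f_DA/f_DD over donor-only records.

    The ratio estimator is invariant to intensity scaling; the median
    keeps single outlier records (aggregates, cosmic rays) from biasing
    the factor.
    """
    _require(donor_only)
    f_dd = donor_only["f_dd"].to_numpy(float)
    f_da = donor_only["f_da"].to_numpy(float)
    ok = f_dd > 0
    return float(np.median(f_da[ok] / f_dd[ok]))


def estimate_delta(acceptor_only: pd.DataFrame) -> float:
    """Direct acceptor excitation: median f_DA/f_AA over acceptor-only records."""
    _require(acceptor_only)
    f_aa = acceptor_only["f_aa"].to_numpy(float)
    f_da = acceptor_only["f_da"].to_numpy(float)
    ok = f_aa > 0
    return float(np.median(f_da[ok] / f_aa[ok]))


def estimate_gamma(
    control_records: pd.DataFrame,
    alpha: float,
    delta: float,
    min_plateau: int = 5,
    guard_frames: int = 1,
) -> float:
    """Detection-efficiency ratio from acceptor photobleaching events.

    For every trajectory of a (high-FRET) control dataset whose f_AA
    trace shows a single bleaching step, the correlated drop in the
    alpha/delta-corrected FRET channel and rise in the donor channel
    across that step measure gamma = -d(f_DA_corr)/d(f_DD).  Plateaus of
    at least ``min_plateau`` frames on each side are averaged, excluding
    ``guard_frames`` frames around the step; the per-event ratios are
    aggregated by their median.  High-FRET controls are preferred since
    they maximize both intensity differences.
    """
    gammas = []
    for _, traj in control_records.groupby("particle"):
        traj = traj.sort_values("pair")
        f_aa = traj["f_aa"].to_numpy(float)
        res = detect_steps(f_aa)
        down = [i for i, a in zip(res.step_frames, res.step_amplitudes) if a < 0]
        if res.n_steps != 1 or len(down) != 1:
            continue
        k = down[0]
        lo, hi = k - guard_frames, k + guard_frames
        if lo < min_plateau or len(traj) - hi < min_plateau:
            continue
        f_dd = traj["f_dd"].to_numpy(float)
        f_da = traj["f_da"].to_numpy(float)
        da_corr = f_da - alpha * f_dd - delta * f_aa
        d_da = np.mean(da_corr[:lo]) - np.mean(da_corr[hi:])
        d_dd = np.mean(f_dd[hi:]) - np.mean(f_dd[:lo])
        if d_dd > 0:
            gammas.append(d_da / d_dd)
    if not gammas:
        raise ValueError("no usable acceptor-bleach events for gamma")
    return float(np.median(gammas))


def estimate_beta(
    calib_records: pd.DataFrame,
    alpha: float,
    delta: float,
    gamma: float,
    bracket=(1e-3, 1e3),
) -> float:
    """Excitation-efficiency ratio from a known 1:1 calibration sample.

    Solves median S(beta) = 0.5 by a monotone 1D root find; S is
    strictly increasing in beta, so the root is unique when it exists.
    """
    _require(calib_records)
    f_dd = calib_records["f_dd"].to_numpy(float)
    f_da = calib_records["f_da"].to_numpy(float)
    f_aa = calib_records["f_aa"].to_numpy(float)
    num = gamma * f_dd + f_da - alpha * f_dd - delta * f_aa

    def median_s_minus_half(beta: float) -> float:
        s = num / (num + f_aa / beta)
        return float(np.median(s)) - 0.5

    lo, hi = bracket
    if median_s_minus_half(lo) * median_s_minus_half(hi) > 0:
        raise ValueError("no beta root in bracket; check calibration data")
    return float(optimize.brentq(median_s_minus_half, lo, hi, xtol=1e-10))


def compute_es(
    records: pd.DataFrame,
    factors: CorrectionFactors,
    copy: bool = True,
) -> pd.DataFrame:
    """Append corrected E and S columns to a brightness-record table.

    Rows whose corrected-total denominator is not positive cannot yield
    a meaningful efficiency; they receive NaN and ``es_invalid=True`` so
    downstream filters can drop them.
    """
    out = records.copy() if copy else records
    f_dd = out["f_dd"].to_numpy(float)
    f_da = out["f_da"].to_numpy(float)
    f_aa = out["f_aa"].to_numpy(float)
    fret = f_da - factors.alpha * f_dd - factors.delta * f_aa
    total = factors.gamma * f_dd + fret
    denom_s = total + f_aa / factors.beta
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(total > 0, fret / total, np.nan)
        s = np.where(denom_s > 0, total / denom_s, np.nan)
    out["E"] = e
    out["S"] = s
    out["es_invalid"] = ~(np.isfinite(e) & np.isfinite(s))
    return out
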