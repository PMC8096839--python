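"""Simulation-based dynamic range of the tension sensor.

The lower FRET bound E_min follows from the spring model: the sensor is
trusted to respond linearly up to 10 pN, and force_to_fret(10 pN) gives
E_min (~0.11 for the default calibration).  The upper bound E_max is
statistical: a stretched (low-FRET) population can only be reported if
it is distinguishable from the collapsed peak at (mean 0.87, sd 0.12).
Detectability is probed by drawing mixture samples (n = 2300, stretched
weight 0.15 or 0.25) against pure collapsed samples and applying a
two-sample Kolmogorov-Smirnov test over a grid of stretched-peak means
and widths; E_max is the largest stretched mean that still tests
significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import (CalibrationParams, DynamicRange,
                          compute_dynamic_range, force_to_fret)

__all__ = [
    "KSDetectability",
    "ks_detectability",
    "pvalue_map",
    "e_max_threshold",
    "assemble_dynamic_range",
]

HIGH_PEAK = (0.87, 0.12)        # collapsed-population mean and sd
DEFAULT_N = 2300                # sample size per draw
DEFAULT_WEIGHT = 0.15           # conservative stretched-peak weight
LINEAR_FORCE_LIMIT_PN = 10.0    # upper end of the spring's linear regime


@dataclass
class KSDetectability:
    low_mean: float
    low_sd: float
    weight: float
    n: int
    p_values: np.ndarray

    @property
    def median_p(self) -> float:
        return float(np.median(self.p_values))


def _draw_mixture(rng, n, weight, low_mean, low_sd, high) -> np.ndarray:
    n_low = rng.binomial(n, weight)
    lo = rng.normal(low_mean, low_sd, n_low)
    hi = rng.normal(high[0], high[1], n - n_low)
    return np.concatenate([lo, hi])


def ks_detectability(
    low_mean: float,
    low_sd: float,
    weight: float = DEFAULT_WEIGHT,
    n: int = DEFAULT_N,
    high: Tuple[float, float] = HIGH_PEAK,
    n_reps: int = 50,
    seed: Union[int, np.random.Generator, None] = 0,
) -> KSDetectability:
    """KS p-values for one stretched-peak parameter setting.

    Each repetition draws one mixture sample (stretched + collapsed)
    and one pure collapsed sample of equal size and applies a
    two-sample Kolmogorov-Smirnov test; small p-values mean the
    stretched peak is detectable.  ``weight=0`` reproduces the null
    (p uniformly distributed).
    """
    if not (0.0 <= weight < 1.0):
        raise ValueError("weight must lie in [0, 1)")
    if n < 100:
        raise ValueError("n must be >= 100")
    rng = np.random.default_rng(seed)
    ps = np.empty(n_reps)
    for i in range(n_reps):
        mix = _draw_mixture(rng, n, weight, low_mean, low_sd, high)
        pure = rng.normal(high[0], high[1], n)
        ps[i] = stats.ks_2samp(mix, pure).pvalue
    return KSDetectability(low_mean, low_sd, weight, n, ps)


def pvalue_map(
    low_means: Sequence[float],
    low_sds: Sequence[float],
    weight: float = DEFAULT_WEIGHT,
    n: int = DEFAULT_N,
    n_reps: int = 50,
    seed: Union[int, None] = 0,
) -> pd.DataFrame:
    """Median KS p-value over a (stretched mean x sd) grid."""
    rng = np.random.default_rng(seed)
    rows = []
    for m in low_means:
        for s in low_sds:
            det = ks_detectability(m, s, weight, n, n_reps=n_reps,
                                   seed=rng.integers(0, 2 ** 31 - 1))
            rows.append((m, s, weight, det.median_p))
    return pd.DataFrame(rows, columns=["low_mean", "low_sd", "weight",
                                       "median_p"])


def e_max_threshold(
    weight: float = DEFAULT_WEIGHT,
    low_means: Optional[Sequence[float]] = None,
    low_sd: float = 0.12,
    alpha: float = 0.05,
    n: int = DEFAULT_N,
    n_reps: int = 50,
    seed: Union[int, None] = 0,
) -> float:
    """Largest detectable stretched-peak efficiency E_max.

    Scans stretched means (default 0.10..0.85 in steps of 0.05) at the
    representative width ``low_sd`` and returns the largest mean whose
    median KS p-value stays below ``alpha``.  Detectability decreases
    monotonically as the stretched peak approaches the collapsed peak,
    so the scan front is well defined up to Monte-Carlo noise.
    """
    if low_means is None:
        low_means = np.round(np.arange(0.10, 0.851, 0.05), 10)
    grid = pvalue_map(low_means, [low_sd], weight, n, n_reps, seed)
    detectable = grid[grid["median_p"] < alpha]
    if detectable.empty:
        raise ValueError("no grid point detectable at this alpha")
    return float(detectable["low_mean"].max())


def assemble_dynamic_range(
    params: CalibrationParams,
    e_max: float,
    f_linear_limit: float = LINEAR_FORCE_LIMIT_PN,
) -> DynamicRange:
    """Dynamic range from the linear-regime bound and the KS threshold.

    E_min is the efficiency at the largest trusted force
    (``f_linear_limit``); the force bounds follow from the calibration,
    F_min = fret_to_force(E_max) and F_max = fret_to_force(E_min).
    """
    e_min = float(force_to_fret(f_linear_limit, params))
    return compute_dynamic_range(params, e_min, e_max)
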