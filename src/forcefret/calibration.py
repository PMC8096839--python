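"""Force calibration of the flagelliform-spring FRET tension sensor.

The sensor is a spider-silk derived elastic peptide flanked by a FRET
donor/acceptor pair.  Within its linear-elasticity regime the fluorophore
separation ``r`` responds to tensile force ``F`` as

    F = (r - b*n - c) / (a*n)

with ``a`` the compliance per amino acid (nm/pN), ``b`` the collapsed
length per amino acid (nm), ``n`` the number of amino acids between the
fluorophores and ``c`` a constant linker length (nm).  The separation is
read out through the FRET efficiency

    E = 1 / (1 + (r/R0)**6)

where ``R0`` is the Foerster distance of the dye pair.  Composing the two
relations converts measured FRET efficiencies into piconewton forces.

The linker constant ``c`` is not known a priori; it is inferred from a
zero-force measurement (sensor on a bilayer with no cells) via
:func:`calibrate_linker`.  All conversion functions are vectorized over
numpy arrays.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path
from typing import Union

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationParams",
    "DynamicRange",
    "ForcePeak",
    "fret_to_distance",
    "distance_to_force",
    "fret_to_force",
    "force_to_fret",
    "calibrate_linker",
    "compute_dynamic_range",
    "propagate_peak_to_force",
    "conversion_table",
]

#: Defaults for the AF555/AF647-labelled 29-residue flagelliform sensor.
DEFAULT_A = 0.0122   # nm/pN compliance per amino acid
DEFAULT_B = 0.044    # nm collapsed length per amino acid
DEFAULT_N = 29       # amino acids between the fluorophores
DEFAULT_R0 = 5.1     # nm Foerster distance
#: Zero-force FRET efficiency of the collapsed sensor on cell-free bilayers.
DEFAULT_E0 = 0.87


@dataclass(frozen=True)
class CalibrationParams:
    """Spring constants and Foerster radius of the tension sensor.

    Attributes
    ----------
    a : float
        Compliance per amino acid (nm/pN).
    b : float
        Collapsed length per amino acid (nm).
    n : int
        Number of amino acids between the fluorophores.
    c : float
        Constant linker length (nm); inferred from a zero-force
        measurement, see :func:`calibrate_linker`.
    R0 : float
        Foerster distance of the FRET pair (nm).
    """

    a: float = DEFAULT_A
    b: float = DEFAULT_B
    n: int = DEFAULT_N
    c: float = 0.0
    R0: float = DEFAULT_R0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0 or self.R0 <= 0:
            raise ValueError("a, b and R0 must be positive")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.c < 0:
            raise ValueError("linker length c must be >= 0")

    @property
    def collapsed_length(self) -> float:
        """Fluorophore separation at zero force, b*n + c (nm)."""
        return self.b * self.n + self.c

    @property
    def stiffness(self) -> float:
        """dF/dr of the linear spring, 1/(a*n) (pN/nm)."""
        return 1.0 / (self.a * self.n)

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "CalibrationParams":
        return cls(**json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class DynamicRange:
    """FRET and force bounds within which the sensor reports faithfully.

    ``E_min`` is set by the upper end of the spring's linear regime
    (largest detectable force ``F_max``), ``E_max`` by the statistical
    detectability of a low-FRET population against the collapsed peak
    (smallest resolvable force ``F_min``).
    """

    E_min: float
    E_max: float
    F_min: float
    F_max: float

    def __post_init__(self) -> None:
        if not (0.0 < self.E_min < self.E_max < 1.0):
            raise ValueError("need 0 < E_min < E_max < 1")
        if not (0.0 <= self.F_min < self.F_max):
            raise ValueError("need 0 <= F_min < F_max")

    def contains_e(self, E) -> np.ndarray:
        E = np.asarray(E)
        return (E >= self.E_min) & (E <= self.E_max)

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "DynamicRange":
        return cls(**json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class ForcePeak:
    """Summary of a FRET population propagated into force units."""

    mean_pn: float
    sd_pn: float
    clipped: bool = False


def _check_efficiency(E) -> np.ndarray:
    E = np.asarray(E, dtype=float)
    if np.any(E <= 0.0) or np.any(E >= 1.0):
        raise ValueError("FRET efficiency must lie strictly in (0, 1)")
    return E


def fret_to_distance(E, R0: float = DEFAULT_R0):
    """Fluorophore separation r (nm) from FRET efficiency.

    Inverts E = 1/(1 + (r/R0)^6):  r = R0 * ((1-E)/E)^(1/6).
    Strictly decreasing in E; E=0.5 gives r=R0 by definition of R0.
    """
    E = _check_efficiency(E)
    return R0 * ((1.0 - E) / E) ** (1.0 / 6.0)


def distance_to_fret(r, R0: float = DEFAULT_R0):
    """FRET efficiency from separation r (nm)."""
    r = np.asarray(r, dtype=float)
    return 1.0 / (1.0 + (r / R0) ** 6)


def distance_to_force(r, params: CalibrationParams):
    """Tensile force (pN) from fluorophore separation (nm).

    Linear spring F = (r - b*n - c)/(a*n).  Values of r below the
    collapsed length yield negative forces; they are returned as-is so
    that zero-force measurement noise stays symmetric (callers decide
    whether to clamp or flag).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("separation r must be >= 0")
    return (r - params.b * params.n - params.c) / (params.a * params.n)


def fret_to_force(E, params: CalibrationParams):
    """Force (pN) from FRET efficiency; strictly decreasing in E."""
    return distance_to_force(fret_to_distance(E, params.R0), params)


def force_to_fret(F, params: CalibrationParams):
    """FRET efficiency from force (pN); exact inverse of fret_to_force."""
    F = np.asarray(F, dtype=float)
    r = params.a * params.n * F + params.b * params.n + params.c
    if np.any(r <= 0):
        raise ValueError("force implies non-positive separation")
    return distance_to_fret(r, params.R0)


def calibrate_linker(E0: float, params: CalibrationParams) -> CalibrationParams:
    """Infer the constant linker length c from a zero-force measurement.

    At F = 0 the spring sits at its collapsed length b*n + c, so
    c = r(E0) - b*n with r from :func:`fret_to_distance`.  ``E0`` is the
    FRET efficiency of the unloaded sensor (measured on bilayers without
    cells).  Returns a copy of ``params`` with c set; the copy satisfies
    fret_to_force(E0) == 0.
    """
    r0 = float(fret_to_distance(E0, params.R0))
    c = r0 - params.b * params.n
    if c < 0:
        raise ValueError(
            f"E0={E0} implies a negative linker length ({c:.3f} nm); "
            "inconsistent with b and n"
        )
    return replace(params, c=c)


def default_params(E0: float = DEFAULT_E0) -> CalibrationParams:
    """Default sensor constants with the linker calibrated at ``E0``."""
    return calibrate_linker(E0, CalibrationParams())


def compute_dynamic_range(
    params: CalibrationParams, E_min: float, E_max: float
) -> DynamicRange:
    """Force bounds corresponding to FRET efficiency bounds.

    Because force decreases with E, the smallest detectable force F_min
    corresponds to E_max and the largest, F_max, to E_min.
    """
    if not (0.0 < E_min < E_max < 1.0):
        raise ValueError("need 0 < E_min < E_max < 1")
    F_min = float(fret_to_force(E_max, params))
    F_max = float(fret_to_force(E_min, params))
    if abs(F_min) < 1e-9:
        F_min = 0.0    # E_max at the zero-force efficiency
    return DynamicRange(E_min=E_min, E_max=E_max, F_min=F_min, F_max=F_max)


def propagate_peak_to_force(
    peak_mean: float,
    peak_sd: float,
    params: CalibrationParams,
    dyn_range: DynamicRange,
    n_nodes: int = 4001,
) -> ForcePeak:
    """Mean and sd of the force distribution behind a fitted FRET peak.

    Models the population as a Gaussian in E truncated to the sensor's
    dynamic range and pushes it through the (nonlinear) E->F conversion
    by deterministic quadrature on an equidistant grid.  Because F is a
    convex, decreasing function of E, the transformed mean generally
    exceeds the point conversion fret_to_force(peak_mean).

    A ``clipped`` flag is set when the peak mean lies outside the
    dynamic range (integration then still runs over the clamped range).
    """
    if not (0.0 < peak_mean < 1.0):
        raise ValueError("peak_mean must lie in (0, 1)")
    if peak_sd < 0:
        raise ValueError("peak_sd must be >= 0")
    if n_nodes < 2001:
        raise ValueError("use at least 2001 quadrature nodes")
    clipped = not (dyn_range.E_min <= peak_mean <= dyn_range.E_max)
    if peak_sd == 0.0:
        return ForcePeak(float(fret_to_force(peak_mean, params)), 0.0, clipped)
    grid = np.linspace(dyn_range.E_min, dyn_range.E_max, n_nodes)
    w = stats.norm.pdf(grid, loc=peak_mean, scale=peak_sd)
    w = w / w.sum()
    f = fret_to_force(grid, params)
    mean = float(np.sum(w * f))
    sd = float(np.sqrt(np.sum(w * (f - mean) ** 2)))
    return ForcePeak(mean_pn=mean, sd_pn=sd, clipped=clipped)


def conversion_table(params: CalibrationParams, e_grid=None) -> "np.ndarray":
    """(E, r, F) conversion table as a structured record array."""
    import pandas as pd

    if e_grid is None:
        e_grid = np.round(np.arange(0.05, 1.0, 0.05), 10)
    e_grid = _check_efficiency(e_grid)
    r = fret_to_distance(e_grid, params.R0)
    f = distance_to_force(r, params)
    return pd.DataFrame({"E": e_grid, "r_nm": r, "F_pN": f})
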