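"""Gaussian-mixture fitting of (E, S) point clouds and force summaries.

The filtered single-molecule data form a 2D cloud in stoichiometry/
efficiency space with a collapsed high-FRET population (unloaded
sensors) and, under force, a stretched low-FRET population.  The cloud
is fitted with a variational Bayesian Gaussian mixture (maximum two
components).  When the putative stretched component is not credible —
its mean lies above the largest detectable efficiency E_max, or its
weight falls below 0.1 — a single-Gaussian fallback is reported
instead.  Fitted low-FRET peaks are converted to force distributions
through the spring calibration; standard errors come from a
nonparametric bootstrap (resampling records with replacement).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.mixture import BayesianGaussianMixture, GaussianMixture

from .calibration import (CalibrationParams, DynamicRange, ForcePeak,
                          fret_to_force, propagate_peak_to_force)

__all__ = [
    "MixtureComponent",
    "MixtureFit",
    "ForcePeakSummary",
    "fit_es_mixture",
    "bootstrap_fit",
    "summarize_force_peaks",
]

FALLBACK_MIN_WEIGHT = 0.1


@dataclass
class MixtureComponent:
    weight: float
    mean_e: float
    mean_s: float
    sd_e: float
    sd_s: float
    cov: np.ndarray            # 2x2, (E, S) order

    @property
    def role(self) -> str:
        """Set by MixtureFit: 'collapsed' (highest E) or 'stretched'."""
        return getattr(self, "_role", "")


@dataclass
class MixtureFit:
    components: List[MixtureComponent]
    n_points: int
    fallback: bool             # single-Gaussian fallback applied
    converged: bool

    @property
    def collapsed(self) -> MixtureComponent:
        return max(self.components, key=lambda c: c.mean_e)

    @property
    def stretched(self) -> Optional[MixtureComponent]:
        if len(self.components) < 2:
            return None
        return min(self.components, key=lambda c: c.mean_e)

    def to_dict(self) -> dict:
        return {
            "n_points": self.n_points,
            "fallback": self.fallback,
            "converged": self.converged,
            "components": [
                {"weight": c.weight, "mean_e": c.mean_e, "mean_s": c.mean_s,
                 "sd_e": c.sd_e, "sd_s": c.sd_s, "cov": c.cov.tolist()}
                for c in self.components],
        }


@dataclass
class ForcePeakSummary:
    mean_pn: float
    sd_pn: float
    weight: float
    component: str                       # 'stretched' | 'collapsed'
    bootstrap_se_pn: Optional[float] = None
    flagged: bool = False


def _as_matrix(points: Union[pd.DataFrame, np.ndarray]) -> np.ndarray:
    if isinstance(points, pd.DataFrame):
        x = points[["E", "S"]].to_numpy(float)
    else:
        x = np.asarray(points, dtype=float).reshape(-1, 2)
    return x[np.all(np.isfinite(x), axis=1)]


def _components_from(weights, means, covs) -> List[MixtureComponent]:
    out = []
    for w, m, c in zip(weights, means, covs):
        out.append(MixtureComponent(
            weight=float(w), mean_e=float(m[0]), mean_s=float(m[1]),
            sd_e=float(np.sqrt(c[0, 0])), sd_s=float(np.sqrt(c[1, 1])),
            cov=np.asarray(c, dtype=float)))
    return out


def _single_gaussian(x: np.ndarray) -> List[MixtureComponent]:
    mean = x.mean(axis=0)
    cov = np.cov(x.T)
    return _components_from([1.0], [mean], [cov])


def fit_es_mixture(
    points: Union[pd.DataFrame, np.ndarray],
    max_components: int = 2,
    seed: Union[int, None] = 0,
    e_max: Optional[float] = None,
    min_weight: float = FALLBACK_MIN_WEIGHT,
    n_init: int = 10,
    reg_covar: float = 1e-6,
) -> MixtureFit:
    """Variational Bayesian Gaussian mixture fit of (E, S) points.

    Uses a weight concentration prior of 1/max_components, 10 restarts
    and tolerance 1e-4.  The fallback to a single Gaussian triggers
    when the low-FRET component's mean exceeds ``e_max`` (a stretched
    peak outside the sensor's dynamic range is not interpretable) or
    when its relative weight is below ``min_weight``.  A degenerate
    covariance triggers a ridge-regularized refit.
    """
    x = _as_matrix(points)
    if len(x) < 100:
        raise ValueError("need at least 100 points for a mixture fit")
    kwargs = dict(
        n_components=max_components,
        weight_concentration_prior=1.0 / max_components,
        covariance_type="full",
        n_init=n_init,
        tol=1e-4,
        max_iter=500,
        reg_covar=reg_covar,
        random_state=None if seed is None else int(seed),
    )
    gmm = BayesianGaussianMixture(**kwargs)
    try:
        gmm.fit(x)
    except Exception:
        kwargs["reg_covar"] = 1e-4
        gmm = BayesianGaussianMixture(**kwargs)
        gmm.fit(x)

    comps = _components_from(gmm.weights_, gmm.means_, gmm.covariances_)
    comps.sort(key=lambda c: -c.mean_e)
    fallback = False
    if len(comps) >= 2:
        stretched = comps[-1]
        if stretched.weight < min_weight:
            fallback = True
        if e_max is not None and stretched.mean_e > e_max:
            fallback = True
    else:
        fallback = True
    if fallback:
        comps = _single_gaussian(x)
    return MixtureFit(components=comps, n_points=len(x),
                      fallback=fallback, converged=bool(gmm.converged_))


def bootstrap_fit(
    points: Union[pd.DataFrame, np.ndarray],
    n_boot: int = 100,
    seed: Union[int, None] = 0,
    n_init: int = 2,
    **fit_kwargs,
) -> Dict[str, float]:
    """Bootstrap standard errors of the mixture-fit parameters.

    Draws ``n_boot`` resamples of the same size with replacement, refits
    each, matches components to the full-data fit by proximity of the E
    means (resolving label switching) and reports the standard
    deviation over resamples for each parameter of each component,
    keyed like ``stretched_mean_e`` / ``collapsed_weight``.
    """
    x = _as_matrix(points)
    rng = np.random.default_rng(seed)
    reference = fit_es_mixture(x, seed=seed, n_init=n_init, **fit_kwargs)
    ref_means = [c.mean_e for c in reference.components]
    names = (["collapsed"] if len(ref_means) == 1
             else ["collapsed", "stretched"])
    samples: Dict[str, List[float]] = {}
    for _ in range(n_boot):
        xb = x[rng.integers(0, len(x), len(x))]
        fit = fit_es_mixture(xb, seed=int(rng.integers(0, 2 ** 31 - 1)),
                             n_init=n_init, **fit_kwargs)
        comps = fit.components
        for name, ref_m in zip(names, ref_means):
            comp = min(comps, key=lambda c: abs(c.mean_e - ref_m))
            for attr in ("weight", "mean_e", "mean_s", "sd_e", "sd_s"):
                samples.setdefault(f"{name}_{attr}", []).append(
                    getattr(comp, attr))
    return {k: float(np.std(v, ddof=1)) for k, v in samples.items()}


def export_force_histogram(
    records: pd.DataFrame,
    fit: MixtureFit,
    params: CalibrationParams,
    dyn_range: DynamicRange,
    png_path=None,
    csv_path=None,
    bins: int = 60,
):
    """Publication-style force histogram of the filtered records.

    Each record's efficiency is point-converted to force for display
    only (inference always uses the fitted mixture); the stretched
    component's propagated force distribution is overlaid.  Writes a
    PNG and/or a CSV of the binned counts; returns the bin table.
    """
    e = np.clip(records["E"].to_numpy(float), dyn_range.E_min,
                dyn_range.E_max)
    f = np.asarray(fret_to_force(e, params), dtype=float)
    counts, edges = np.histogram(f, bins=bins,
                                 range=(0.0, dyn_range.F_max))
    centers = 0.5 * (edges[:-1] + edges[1:])
    table = pd.DataFrame({"force_pn": centers, "count": counts})
    if csv_path is not None:
        table.to_csv(csv_path, index=False)
    if png_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 3))
        ax.bar(centers, counts, width=edges[1] - edges[0],
               color="0.7", edgecolor="none")
        stretched = fit.stretched
        if stretched is not None:
            peak = propagate_peak_to_force(stretched.mean_e,
                                           stretched.sd_e, params,
                                           dyn_range)
            ax.axvline(peak.mean_pn, color="C1",
                       label=f"stretched: {peak.mean_pn:.1f} pN")
            ax.legend(frameon=False, fontsize=8)
        ax.set_xlabel("force (pN)")
        ax.set_ylabel("records")
        fig.tight_layout()
        fig.savefig(png_path, dpi=150)
        plt.close(fig)
    return table


def summarize_force_peaks(
    fit: MixtureFit,
    params: CalibrationParams,
    dyn_range: DynamicRange,
    bootstrap_se: Optional[Dict[str, float]] = None,
) -> List[ForcePeakSummary]:
    """Convert fitted FRET components into force-distribution summaries.

    The stretched component's E marginal (Gaussian, truncated to the
    dynamic range) is propagated through the spring calibration by
    quadrature; the collapsed component is reported as the zero-force
    reference via point conversion.  When a bootstrap se for the
    stretched mean efficiency is supplied it is propagated to force
    units through the local slope of the conversion.
    """
    out: List[ForcePeakSummary] = []
    for comp in fit.components:
        is_collapsed = comp is fit.collapsed and len(fit.components) > 1
        role = "collapsed" if (is_collapsed or len(fit.components) == 1) \
            else "stretched"
        flagged = not (0.0 < comp.mean_e < 1.0)
        if role == "stretched" and not flagged:
            peak: ForcePeak = propagate_peak_to_force(
                comp.mean_e, comp.sd_e, params, dyn_range)
            se = None
            if bootstrap_se and "stretched_mean_e" in bootstrap_se:
                de = 1e-4
                e0 = np.clip(comp.mean_e, dyn_range.E_min + de,
                             dyn_range.E_max - de)
                slope = (fret_to_force(e0 + de, params)
                         - fret_to_force(e0 - de, params)) / (2 * de)
                se = float(abs(slope) * bootstrap_se["stretched_mean_e"])
            out.append(ForcePeakSummary(
                mean_pn=peak.mean_pn, sd_pn=peak.sd_pn, weight=comp.weight,
                component="stretched", bootstrap_se_pn=se,
                flagged=peak.clipped))
        else:
            e0 = min(max(comp.mean_e, 1e-4), 1 - 1e-4)
            out.append(ForcePeakSummary(
                mean_pn=float(fret_to_force(e0, params)), sd_pn=0.0,
                weight=comp.weight, component="collapsed", flagged=flagged))
    return out
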