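"""Ensemble FRET via donor recovery after acceptor photobleaching (DRAAP).

Complete photodestruction of the acceptor removes the FRET de-excitation
pathway, so the donor brightens by exactly the transferred fraction:
with ROI-averaged donor signals f_pre (before) and f_post (after),

    E_bulk = (f_post - f_pre) / f_post.

The force readout is the difference between matched regions under a
cell and on cell-free bilayer, Delta E_bulk = E_bulk^cell -
E_bulk^no_cell; group differences are assessed with a two-sample
Mann-Whitney U test (significance at p < 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "DraapMeasurement",
    "GroupComparison",
    "e_bulk",
    "delta_e_bulk",
    "compare_groups",
]


@dataclass
class DraapMeasurement:
    f_pre: float
    f_post: float
    e_bulk: float
    roi_id: str = ""
    condition: str = ""        # 'cell' | 'no_cell'
    valid: bool = True


@dataclass
class GroupComparison:
    statistic: float           # Mann-Whitney U
    p_value: float
    n_a: int
    n_b: int

    @property
    def significant(self) -> bool:
        return self.p_value < 0.01


def e_bulk(
    pre_image: np.ndarray,
    post_image: np.ndarray,
    roi: Optional[np.ndarray] = None,
    background: float = 0.0,
    roi_id: str = "",
    condition: str = "",
) -> DraapMeasurement:
    """Ensemble FRET efficiency of one ROI from a DRAAP image pair.

    ``roi`` is a boolean mask (whole image if omitted); ``background``
    is subtracted from both pixel averages before forming the ratio.
    A non-positive post-bleach signal invalidates the measurement.
    """
    pre = np.asarray(pre_image, dtype=float)
    post = np.asarray(post_image, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post images must match in shape")
    if roi is None:
        roi = np.ones(pre.shape, dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("empty ROI")
    f_pre = float(pre[roi].mean() - background)
    f_post = float(post[roi].mean() - background)
    if f_post <= 0:
        return DraapMeasurement(f_pre, f_post, np.nan, roi_id, condition,
                                valid=False)
    return DraapMeasurement(f_pre, f_post, (f_post - f_pre) / f_post,
                            roi_id, condition)


def delta_e_bulk(
    cell: DraapMeasurement, no_cell: DraapMeasurement
) -> float:
    """Difference E_bulk^cell - E_bulk^no_cell for matched ROIs.

    Negative values indicate force-induced sensor elongation under the
    cell (reduced FRET)."""
    if not (cell.valid and no_cell.valid):
        raise ValueError("cannot difference invalid measurements")
    return cell.e_bulk - no_cell.e_bulk


def compare_groups(
    values_a: Sequence[float], values_b: Sequence[float]
) -> GroupComparison:
    """Two-sample Mann-Whitney U test (two-sided, tie-corrected).

    Rank-based and therefore invariant under monotone transforms of the
    pooled data; each group needs at least three values.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs n >= 3")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return GroupComparison(statistic=float(res.statistic),
                           p_value=float(res.pvalue), n_a=len(a), n_b=len(b))
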