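"""Affine registration of the donor emission channel onto the acceptor channel.

Dual-view/dual-camera smFRET detection images the donor and acceptor
emission paths onto different detector regions with a small relative
shift, scale and rotation (chromatic aberration included).  The mapping
is calibrated from multicolor fiducial beads visible in both channels
and modelled as a 2D affine transform, fitted by least squares to the
localization pairs.  By convention the donor channel is warped onto the
acceptor channel's geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage


@dataclass
class AffineTransform:
    """2D affine map y = A @ x + t, coordinates as (x, y) pixel pairs.

    ``matrix`` is the 2x2 linear part, ``offset`` the translation.
    Pixel coordinates are 0-based with positions at pixel centers.
    """

    matrix: np.ndarray = field(default_factory=lambda: np.eye(2))
    offset: np.ndarray = field(default_factory=lambda: np.zeros(2))
    rms_residual: Optional[float] = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(2, 2)
        self.offset = np.asarray(self.offset, dtype=float).reshape(2)
        if abs(np.linalg.det(self.matrix)) < 1e-6:
            raise ValueError("affine linear part is (near-)singular")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls()

    def apply(self, xy) -> np.ndarray:
        """Transform coordinates, shape (..., 2)."""
        xy = np.asarray(xy, dtype=float)
        return xy @ self.matrix.T + self.offset

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(inv, -inv @ self.offset)

    def warp_image(self, image: np.ndarray, order: int = 1) -> np.ndarray:
        """Resample ``image`` into the target geometry (bilinear default).

        The output pixel at (x, y) samples the input at T^{-1}(x, y).
        ndimage uses (row, col) = (y, x) ordering, hence the flips.
        """
        inv = self.inverse()
        m_rc = inv.matrix[::-1, ::-1]       # swap x/y axes
        off_rc = inv.offset[::-1]
        return ndimage.affine_transform(
            np.asarray(image, dtype=float), m_rc, offset=off_rc, order=order,
            mode="constant", cval=float(np.median(image)),
        )

    def to_json(self, path: Union[str, Path]) -> None:
        m23 = np.column_stack([self.matrix, self.offset])
        payload = {"matrix_2x3_row_major": m23.tolist(),
                   "rms_residual": self.rms_residual,
                   "convention": "0-based pixel centers, (x, y) order"}
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "AffineTransform":
        payload = json.loads(Path(path).read_text())
        m23 = np.asarray(payload["matrix_2x3_row_major"], dtype=float)
        return cls(m23[:, :2], m23[:, 2], payload.get("rms_residual"))


def fit_affine(
    src_xy: Sequence, dst_xy: Sequence, robust: bool = False,
    n_robust_iter: int = 3, outlier_sigma: float = 3.0,
) -> AffineTransform:
    """Least-squares affine from matched point pairs (src -> dst).

    Requires at least three non-collinear pairs.  With ``robust=True``
    the fit is repeated after discarding pairs whose residual exceeds
    ``outlier_sigma`` times the robust residual scale, which suppresses
    mis-paired beads.
    """
    src = np.asarray(src_xy, dtype=float).reshape(-1, 2)
    dst = np.asarray(dst_xy, dtype=float).reshape(-1, 2)
    if src.shape != dst.shape:
        raise ValueError("src and dst must have matching shapes")
    if len(src) < 3:
        raise ValueError("need at least 3 point pairs for an affine fit")
    if _collinear(src):
        raise ValueError("source points are (near-)collinear")

    keep = np.ones(len(src), dtype=bool)
    tform = _lstsq_affine(src, dst)
    if robust:
        for _ in range(n_robust_iter):
            resid = np.linalg.norm(tform.apply(src) - dst, axis=1)
            scale = 1.4826 * np.median(np.abs(resid - np.median(resid))) + 1e-12
            new_keep = resid <= np.median(resid) + outlier_sigma * scale
            if new_keep.sum() < 3 or np.array_equal(new_keep, keep):
                break
            keep = new_keep
            tform = _lstsq_affine(src[keep], dst[keep])
    resid = np.linalg.norm(tform.apply(src[keep]) - dst[keep], axis=1)
    tform.rms_residual = float(np.sqrt(np.mean(resid ** 2)))
    return tform


def _lstsq_affine(src: np.ndarray, dst: np.ndarray) -> AffineTransform:
    design = np.column_stack([src, np.ones(len(src))])
    coef, *_ = np.linalg.lstsq(design, dst, rcond=None)
    return AffineTransform(coef[:2].T, coef[2])


def _collinear(pts: np.ndarray, tol: float = 1e-6) -> bool:
    centered = pts - pts.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    return s[1] < tol * max(s[0], 1.0)


def pair_beads(
    donor_xy, acceptor_xy, max_dist: float = 5.0
) -> Tuple[np.ndarray, np.ndarray]:
    """Match bead localizations across channels by mutual nearest neighbor.

    A coarse translation (median offset of all nearest-neighbor vectors)
    is removed before matching, so channel shifts larger than
    ``max_dist`` are still handled.
    """
    donor = np.asarray(donor_xy, dtype=float).reshape(-1, 2)
    acceptor = np.asarray(acceptor_xy, dtype=float).reshape(-1, 2)
    if len(donor) == 0 or len(acceptor) == 0:
        raise ValueError("empty localization set")
    from scipy.spatial import cKDTree

    tree = cKDTree(acceptor)
    _, idx = tree.query(donor)
    shift = np.median(acceptor[idx] - donor, axis=0)
    shifted = donor + shift

    tree_a = cKDTree(acceptor)
    d_da, nn_da = tree_a.query(shifted)
    tree_d = cKDTree(shifted)
    _, nn_ad = tree_d.query(acceptor)
    mutual = (nn_ad[nn_da] == np.arange(len(donor))) & (d_da <= max_dist)
    return donor[mutual], acceptor[nn_da[mutual]]
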