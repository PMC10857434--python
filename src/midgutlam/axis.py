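"""Piecewise-median axis fitting, projection and binning.

A curved midgut is linearized by fitting a piecewise median polyline (the
"vector") through the nucleus point cloud: centroids are rotated so the first
principal axis is the abscissa, the abscissa range is cut into equal-width
slices, and each non-empty slice contributes one control point at
(slice midpoint, median ordinate). The polyline ordinates are smoothed with a
3-point moving average and arc length is accumulated along the result.

Every object is then projected onto the nearest point of the polyline
(checked over every segment), giving an arc-length position ``s``, a
normalized anterior→posterior position ``u = s / L`` in [0, 1], and an
unsigned radial offset ``d`` measured in the rotated xy-plane. Positions
beyond the termini clamp to the nearest endpoint rather than erroring, since
segmentation commonly includes cardia / hindgut fringe objects. ``u`` is
finally cut into half-open bins ``[i/n, (i+1)/n)``, the last bin closed at 1.

The axis is fitted in 2D (xy after PCA rotation): the organ is imaged lying
roughly flat, so curvature lives in the xy-plane; z is retained only for 3D
nearest-neighbor distances downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["MidgutAxis", "AxisLinearizer", "fit_axis", "project", "bin_positions"]

logger = logging.getLogger(__name__)


@dataclass
class MidgutAxis:
    """A fitted piecewise-median axis.

    Attributes
    ----------
    points : ndarray (m, 2)
        Control points in the PCA-rotated frame, ordered by strictly
        increasing abscissa.
    cum_s : ndarray (m,)
        Cumulative arc length (µm) at each control point.
    length : float
        Total arc length L (µm).
    rotation : ndarray (2, 2)
        Rotation applied to centered raw xy coordinates.
    center : ndarray (2,)
        Mean of the raw xy coordinates subtracted before rotation.
    """

    points: np.ndarray
    cum_s: np.ndarray
    length: float
    rotation: np.ndarray
    center: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, float)
        self.cum_s = np.asarray(self.cum_s, float)
        if self.points.ndim != 2 or self.points.shape[1] != 2 or len(self.points) < 2:
            raise ValueError("axis needs >= 2 control points in 2D")
        if np.any(np.diff(self.points[:, 0]) <= 0):
            raise ValueError("control points must have strictly increasing abscissa")
        if np.any(np.diff(self.cum_s) <= 0) or self.length <= 0:
            raise ValueError("arc length must be strictly increasing and positive")

    def to_rotated(self, xy: np.ndarray) -> np.ndarray:
        """Map raw xy coordinates into the rotated axis frame."""
        return (np.asarray(xy, float) - self.center) @ self.rotation.T


def _as_xy(records) -> np.ndarray:
    """Extract an (n, 2) float array from a DataFrame or array-like."""
    if isinstance(records, pd.DataFrame):
        return records[["x_um", "y_um"]].to_numpy(float)
    arr = np.asarray(records, float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("expected an (n, >=2) coordinate array")
    return arr[:, :2]


def fit_axis(records, slice_count: int = 30) -> MidgutAxis:
    """Fit the piecewise-median axis through a nucleus point cloud.

    Parameters
    ----------
    records : DataFrame with x_um / y_um columns, or (n, >=2) array
        Centroids in µm; only x and y are used.
    slice_count : int
        Number of equal-width slices along the first principal axis.
        Requires ``slice_count >= 4`` and at least ``10 * slice_count``
        records.

    Returns
    -------
    MidgutAxis

    Notes
    -----
    The rotated abscissa is oriented to correlate positively with the raw x
    coordinate, so for data acquired anterior-at-left the arc length runs
    anterior → posterior. For the opposite acquisition orientation project
    with ``flip=True``.
    """
    xy = _as_xy(records)
    if slice_count < 4:
        raise ValueError(f"slice_count must be >= 4, got {slice_count}")
    if len(xy) < 10 * slice_count:
        raise ValueError(
            f"need >= {10 * slice_count} records for slice_count={slice_count}, "
            f"got {len(xy)}"
        )
    if not np.all(np.isfinite(xy)):
        raise ValueError("coordinates must be finite")

    center = xy.mean(axis=0)
    centered = xy - center
    cov = np.cov(centered.T)
    evals, evecs = np.linalg.eigh(cov)
    # principal axis = eigenvector of the largest eigenvalue
    pc1 = evecs[:, np.argmax(evals)]
    pc2 = np.array([-pc1[1], pc1[0]])
    rotation = np.vstack([pc1, pc2])
    rot = centered @ rotation.T
    # orient the abscissa along increasing raw x (anterior at x-minimum)
    if np.dot(rot[:, 0], xy[:, 0] - center[0]) < 0:
        rotation = -rotation
        rot = -rot

    a_min, a_max = rot[:, 0].min(), rot[:, 0].max()
    span = a_max - a_min
    if span <= 0:
        logger.warning("degenerate abscissa span; falling back to straight axis")
        return _straight_axis(rot, rotation, center)

    edges = np.linspace(a_min, a_max, slice_count + 1)
    idx = np.clip(np.searchsorted(edges, rot[:, 0], side="right") - 1,
                  0, slice_count - 1)
    abscissa, ordinate = [], []
    for i in range(slice_count):
        in_slice = idx == i
        if not np.any(in_slice):
            continue  # adjacent empty slices simply drop out (merged)
        abscissa.append(0.5 * (edges[i] + edges[i + 1]))
        ordinate.append(np.median(rot[in_slice, 1]))
    if len(abscissa) < 2:
        logger.warning("fewer than 2 occupied slices; falling back to straight axis")
        return _straight_axis(rot, rotation, center)

    abscissa = np.asarray(abscissa)
    ordinate = np.asarray(ordinate)
    # 3-point moving average on ordinates, window clipped at the ends
    smoothed = ordinate.copy()
    if len(ordinate) >= 3:
        smoothed[1:-1] = (ordinate[:-2] + ordinate[1:-1] + ordinate[2:]) / 3.0
        smoothed[0] = (ordinate[0] + ordinate[1]) / 2.0
        smoothed[-1] = (ordinate[-2] + ordinate[-1]) / 2.0

    points = np.column_stack([abscissa, smoothed])
    # extend the terminal segments to the data range: control points sit at
    # slice midpoints, so without extension the axis would stop half a slice
    # short of each end and fringe objects would clamp into the end bins
    slope0 = (points[1, 1] - points[0, 1]) / (points[1, 0] - points[0, 0])
    slope1 = (points[-1, 1] - points[-2, 1]) / (points[-1, 0] - points[-2, 0])
    first = np.array([a_min, points[0, 1] - slope0 * (points[0, 0] - a_min)])
    last = np.array([a_max, points[-1, 1] + slope1 * (a_max - points[-1, 0])])
    points = np.vstack([first, points, last])
    seg = np.hypot(np.diff(points[:, 0]), np.diff(points[:, 1]))
    cum_s = np.concatenate([[0.0], np.cumsum(seg)])
    return MidgutAxis(points=points, cum_s=cum_s, length=float(cum_s[-1]),
                      rotation=rotation, center=center)


def _straight_axis(rot, rotation, center) -> MidgutAxis:
    a_min, a_max = rot[:, 0].min(), rot[:, 0].max()
    if a_max <= a_min:
        a_max = a_min + 1.0
    points = np.array([[a_min, 0.0], [a_max, 0.0]])
    cum_s = np.array([0.0, a_max - a_min])
    return MidgutAxis(points=points, cum_s=cum_s, length=float(cum_s[-1]),
                      rotation=rotation, center=center)


def project(records, axis: MidgutAxis, flip: bool = False) -> pd.DataFrame:
    """Project records onto the axis polyline.

    Each point is assigned the nearest point over *every* polyline segment
    (feet clamped to segment ends, so positions beyond the termini clamp to
    u = 0 or u = 1).

    Returns
    -------
    DataFrame with columns ``s_um`` (arc length at the foot), ``u``
    (normalized position, clipped to [0, 1]) and ``d_um`` (unsigned distance
    from the foot in the rotated xy-plane). If ``records`` is a DataFrame the
    columns are appended to a copy of it.
    """
    xy = _as_xy(records)
    rot = axis.to_rotated(xy)

    p0 = axis.points[:-1]                      # (m-1, 2)
    vec = np.diff(axis.points, axis=0)         # (m-1, 2)
    seg_len2 = np.einsum("ij,ij->i", vec, vec)
    diff = rot[:, None, :] - p0[None, :, :]    # (n, m-1, 2)
    t = np.einsum("nmj,mj->nm", diff, vec) / seg_len2
    t = np.clip(t, 0.0, 1.0)
    foot = p0[None, :, :] + t[:, :, None] * vec[None, :, :]
    dist2 = np.sum((rot[:, None, :] - foot) ** 2, axis=2)
    best = np.argmin(dist2, axis=1)
    n = len(rot)
    rows = np.arange(n)
    t_best = t[rows, best]
    d = np.sqrt(dist2[rows, best])
    s = axis.cum_s[best] + t_best * np.sqrt(seg_len2[best])
    u = np.clip(s / axis.length, 0.0, 1.0)
    if flip:
        u = 1.0 - u
        s = axis.length - s

    if isinstance(records, pd.DataFrame):
        out = records.copy()
        out["s_um"] = s
        out["u"] = u
        out["d_um"] = d
        return out
    return pd.DataFrame({"s_um": s, "u": u, "d_um": d})


def bin_positions(projected, n_bins: int = 100):
    """Assign half-open bins over u: bin i covers [i/n, (i+1)/n), last closed.

    Accepts a DataFrame with a ``u`` column (returns a copy with a ``bin``
    column) or an array of u values (returns the bin indices).
    """
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    if isinstance(projected, pd.DataFrame):
        u = projected["u"].to_numpy(float)
    else:
        u = np.asarray(projected, float)
    if np.any((u < 0) | (u > 1)):
        raise ValueError("u values must lie in [0, 1]")
    idx = np.minimum((u * n_bins).astype(int), n_bins - 1)
    if isinstance(projected, pd.DataFrame):
        out = projected.copy()
        out["bin"] = idx
        return out
    return idx


class AxisLinearizer(BaseEstimator, TransformerMixin):
    """Fit a piecewise-median axis and linearize nucleus tables.

    Parameters
    ----------
    slice_count : int, default 30
        Number of abscissa slices used to build the median polyline.
    n_bins : int, default 100
        Number of bins along the normalized axis.
    flip : bool, default False
        Reverse the anterior→posterior orientation (for data acquired with
        the anterior end at the x-maximum).

    Attributes
    ----------
    axis_ : MidgutAxis
        The fitted polyline.

    Examples
    --------
    >>> lin = AxisLinearizer(slice_count=30, n_bins=100).fit(table)
    >>> projected = lin.transform(table)   # adds s_um, u, d_um, bin
    """

    def __init__(self, slice_count: int = 30, n_bins: int = 100,
                 flip: bool = False):
        self.slice_count = slice_count
        self.n_bins = n_bins
        self.flip = flip

    def fit(self, X, y=None):
        self.axis_ = fit_axis(X, slice_count=self.slice_count)
        return self

    def transform(self, X):
        if not hasattr(self, "axis_"):
            raise ValueError("AxisLinearizer is not fitted yet")
        out = project(X, self.axis_, flip=self.flip)
        return bin_positions(out, n_bins=self.n_bins)

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X).transform(X)
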