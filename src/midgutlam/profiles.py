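"""Per-bin feature tracks along the normalized midgut axis.

Turns projected, binned nucleus records into a :class:`BinnedProfile`: total
and type-specific counts, polyploid ("large") nucleus area, nearest-neighbor
distance among large nuclei, and midgut width, one value per axis bin.

Conventions
-----------
* Ploidy is gated on the bimodal log-area histogram (valley between the
  diploid and polyploid modes); polyploid = above threshold.
* Width of a bin = 2 × median radial offset ``d`` of its records — the
  epithelium is a monolayer tube, so the typical wall offset estimates the
  radius. Robust to stray objects; switch to an extreme-value estimate by
  aggregating ``d`` yourself if needed.
* Nearest-neighbor distances between polyploid nuclei are 3D and computed
  sample-wide before per-bin averaging, so a bin boundary never splits true
  neighbors.
* Bins with fewer than ``min_count`` records carry NaN (a missing-value
  marker), never 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator

from ._bimodal import UnimodalError, log_valley_threshold

__all__ = [
    "BinnedProfile",
    "PloidyGate",
    "classify_ploidy",
    "nearest_distance_large",
    "compute_width",
    "build_profile",
    "UnimodalError",
]

#: profile feature columns always present
CORE_FEATURES = ("total_count", "width", "large_area", "large_area_mean",
                 "nn_distance")


class PloidyGate(BaseEstimator):
    """Gate nuclei into diploid / polyploid on the log-area histogram.

    Parameters
    ----------
    threshold : float, optional
        Manual area threshold (µm²). When given, no histogram analysis runs.
    min_mode_separation : float, default 0.2
        Minimum distance (log-units) between the valley and each mode;
        closer modes raise :class:`UnimodalError`.

    Attributes
    ----------
    threshold_ : float
        Area threshold in µm²; areas strictly above it are polyploid.
    """

    def __init__(self, threshold: float | None = None,
                 min_mode_separation: float = 0.2):
        self.threshold = threshold
        self.min_mode_separation = min_mode_separation

    def fit(self, areas, y=None):
        areas = _as_areas(areas)
        if self.threshold is not None:
            self.threshold_ = float(self.threshold)
            return self
        if len(areas) < 50:
            raise ValueError("need >= 50 positive areas to fit the ploidy gate")
        self.threshold_ = log_valley_threshold(
            areas, min_mode_separation=self.min_mode_separation
        )
        return self

    def predict(self, areas) -> np.ndarray:
        """Boolean array: True = polyploid (area > threshold)."""
        if not hasattr(self, "threshold_"):
            raise ValueError("PloidyGate is not fitted yet")
        return _as_areas(areas) > self.threshold_


def _as_areas(areas) -> np.ndarray:
    if isinstance(areas, pd.DataFrame):
        areas = areas["area_um2"]
    arr = np.asarray(areas, float)
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ValueError("areas must be finite and strictly positive")
    return arr


def classify_ploidy(records, threshold: float | None = None):
    """Label records diploid / polyploid.

    Returns ``(labels, threshold)`` where ``labels`` is an object array of
    ``"diploid"`` / ``"polyploid"`` and ``threshold`` the area cut (µm²)
    actually used. With no manual ``threshold`` the cut is placed at the
    minimum of the smoothed log-area histogram between the two largest
    modes; a unimodal distribution raises :class:`UnimodalError` advising a
    manual threshold.
    """
    gate = PloidyGate(threshold=threshold).fit(records)
    poly = gate.predict(records)
    labels = np.where(poly, "polyploid", "diploid").astype(object)
    return labels, gate.threshold_


def nearest_distance_large(coords) -> np.ndarray:
    """3D nearest-neighbor distance for each (polyploid) nucleus.

    ``coords`` is an (n, 3) array or a DataFrame with x_um/y_um/z_um. The
    distance is to the closest *other* nucleus of the set, so duplicated
    coordinates yield 0 for both members. Requires n >= 2.
    """
    if isinstance(coords, pd.DataFrame):
        coords = coords[["x_um", "y_um", "z_um"]].to_numpy(float)
    pts = np.asarray(coords, float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("expected an (n, 3) coordinate array")
    if len(pts) < 2:
        raise ValueError("need >= 2 polyploid records for nearest distances")
    tree = cKDTree(pts)
    dist, _ = tree.query(pts, k=2)
    return dist[:, 1]


def compute_width(projected, n_bins: int, min_count: int = 5) -> np.ndarray:
    """Per-bin midgut width: 2 × median radial offset of the bin's records.

    ``projected`` needs ``d_um`` and ``bin`` columns (or pass a tuple of
    arrays ``(d, bin)``). Bins with fewer than ``min_count`` records are NaN
    — the median of a handful of wall offsets is unstable.
    """
    if isinstance(projected, pd.DataFrame):
        d = projected["d_um"].to_numpy(float)
        b = projected["bin"].to_numpy(int)
    else:
        d, b = (np.asarray(a) for a in projected)
    width = np.full(n_bins, np.nan)
    order = np.argsort(b, kind="stable")
    d, b = d[order], b[order]
    starts = np.searchsorted(b, np.arange(n_bins), side="left")
    stops = np.searchsorted(b, np.arange(n_bins), side="right")
    for i in range(n_bins):
        if stops[i] - starts[i] >= min_count:
            width[i] = 2.0 * np.median(d[starts[i]:stops[i]])
    return width


@dataclass
class BinnedProfile:
    """Per-bin feature tracks of one sample.

    ``table`` is indexed by bin (0..n_bins-1) with columns
    ``total_count``, ``width``, ``large_area`` (median polyploid area),
    ``large_area_mean``, ``nn_distance`` (mean 3D NN distance among
    polyploid nuclei), plus ``count_<type>`` and ``area_<type>`` per cell
    type when type labels were supplied. Missing bins hold NaN, never 0
    (except counts, where an empty bin genuinely holds 0).
    """

    sample_id: str
    n_bins: int
    table: pd.DataFrame
    ploidy_threshold: float
    record_ids: list = field(default_factory=list, repr=False)

    def feature(self, name: str) -> np.ndarray:
        if name not in self.table.columns:
            raise KeyError(
                f"unknown feature {name!r}; available: {list(self.table.columns)}"
            )
        return self.table[name].to_numpy(float)


def build_profile(
    projected: pd.DataFrame,
    n_bins: int = 100,
    type_col: str | None = None,
    allowed_types: tuple[str, ...] | None = None,
    ploidy_threshold: float | None = None,
    min_count: int = 5,
    sample_id: str | None = None,
) -> BinnedProfile:
    """Assemble all per-bin tracks for one projected, binned sample.

    Parameters
    ----------
    projected : DataFrame
        Needs ``bin``, ``d_um``, ``area_um2``, ``x_um``/``y_um``/``z_um``
        (for NN distances) and ``object_id``.
    type_col : str, optional
        Column of cell-type labels; adds ``count_<type>`` and
        ``area_<type>`` (mean area) tracks per label value.
    allowed_types : tuple of str, optional
        When given, label values outside this set raise an error listing
        them.
    ploidy_threshold : float, optional
        Manual polyploid area cut; by default fitted on the sample.
    min_count : int
        Minimum records per bin for the width / area summaries.
    """
    required = {"bin", "d_um", "area_um2"}
    missing = required - set(projected.columns)
    if missing:
        raise ValueError(f"projected table missing columns: {sorted(missing)}")
    if sample_id is None:
        sample_id = (str(projected["sample_id"].iloc[0])
                     if "sample_id" in projected.columns else "sample")

    bins = projected["bin"].to_numpy(int)
    if np.any((bins < 0) | (bins >= n_bins)):
        raise ValueError("bin indices out of range for n_bins")

    poly_labels, thr = classify_ploidy(projected, threshold=ploidy_threshold)
    poly = poly_labels == "polyploid"

    table = pd.DataFrame(index=pd.RangeIndex(n_bins, name="bin"))
    table["total_count"] = np.bincount(bins, minlength=n_bins)
    table["width"] = compute_width(projected, n_bins, min_count=min_count)

    areas = projected["area_um2"].to_numpy(float)
    table["large_area"] = _agg_per_bin(areas[poly], bins[poly], n_bins,
                                       np.median, min_count)
    table["large_area_mean"] = _agg_per_bin(areas[poly], bins[poly], n_bins,
                                            np.mean, min_count)

    nn = np.full(len(projected), np.nan)
    if poly.sum() >= 2:
        nn[poly] = nearest_distance_large(projected.loc[poly])
    table["nn_distance"] = _agg_per_bin(nn[poly], bins[poly], n_bins,
                                        np.mean, min_count=1)

    if type_col is not None:
        labels = projected[type_col].to_numpy(object)
        uniq = pd.unique(labels)
        if allowed_types is not None:
            unknown = sorted(set(uniq) - set(allowed_types))
            if unknown:
                raise ValueError(f"unknown {type_col} label values: {unknown}")
        for t in sorted(map(str, uniq)):
            m = labels == t
            table[f"count_{t}"] = np.bincount(bins[m], minlength=n_bins)
            table[f"area_{t}"] = _agg_per_bin(areas[m], bins[m], n_bins,
                                              np.mean, min_count=2)

    record_ids = _ids_per_bin(projected, bins, n_bins)
    return BinnedProfile(sample_id=sample_id, n_bins=n_bins, table=table,
                         ploidy_threshold=thr, record_ids=record_ids)


def _agg_per_bin(values, bins, n_bins, func, min_count):
    out = np.full(n_bins, np.nan)
    if len(values) == 0:
        return out
    order = np.argsort(bins, kind="stable")
    v, b = np.asarray(values, float)[order], np.asarray(bins)[order]
    starts = np.searchsorted(b, np.arange(n_bins), side="left")
    stops = np.searchsorted(b, np.arange(n_bins), side="right")
    for i in range(n_bins):
        if stops[i] - starts[i] >= min_count:
            out[i] = func(v[starts[i]:stops[i]])
    return out


def _ids_per_bin(projected, bins, n_bins):
    ids = (projected["object_id"].to_numpy()
           if "object_id" in projected.columns
           else np.arange(len(projected)))
    out = [np.empty(0, dtype=ids.dtype)] * n_bins
    order = np.argsort(bins, kind="stable")
    ids_s, b = ids[order], bins[order]
    starts = np.searchsorted(b, np.arange(n_bins), side="left")
    stops = np.searchsorted(b, np.arange(n_bins), side="right")
    for i in range(n_bins):
        out[i] = ids_s[starts[i]:stops[i]]
    return out
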