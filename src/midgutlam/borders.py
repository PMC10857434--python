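"""Multivariate region-border detection along the linearized midgut.

The border score aggregates localized changes of several per-bin tracks
(midgut width, polyploid nucleus area, nearest distances, total counts):
each track is median-normalized per sample, averaged across samples, and its
contribution at bin b is the absolute difference between the mean over the
trailing window (b-w, b] and the leading window (b, b+w], z-scored across
bins. The score is the weighted sum of contributions; bins whose windows
overrun a terminus are unscorable (NaN). Borders B1..Bk are the k highest
score peaks after greedy non-maximum suppression, and delimit the main
regions R1..R(k+1).

A score peak at bin b marks a change between bins <= b and bins > b, so the
border's normalized position is (b + 1) / n_bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks
from sklearn.base import BaseEstimator

from .axis import MidgutAxis
from .profiles import BinnedProfile

__all__ = [
    "BorderScore",
    "BorderSet",
    "BorderDetector",
    "border_score",
    "call_borders",
    "region_lengths",
    "align_samples",
    "DEFAULT_WEIGHTS",
]

#: default score variables and weights; the total-count track is noisier
#: than the geometry tracks and gets half weight.
DEFAULT_WEIGHTS: dict[str, float] = {
    "width": 1.0,
    "large_area": 1.0,
    "nn_distance": 1.0,
    "total_count": 0.5,
}


@dataclass
class BorderScore:
    """Per-bin multivariate border score and per-variable contributions."""

    score: np.ndarray                      # (n_bins,), NaN where unscorable
    contributions: dict[str, np.ndarray]   # z-scored per variable
    window: int
    weights: dict[str, float]
    n_bins: int

    def scorable(self) -> np.ndarray:
        return ~np.isnan(self.score)


@dataclass
class BorderSet:
    """Called borders B1..Bk and the region intervals they delimit."""

    bins: np.ndarray        # (k,) border bins, strictly increasing
    u: np.ndarray           # (k,) normalized positions (bin + 1) / n_bins
    n_bins: int
    labels: tuple[str, ...] = field(default=())
    region_labels: tuple[str, ...] = field(default=())

    def __post_init__(self):
        self.bins = np.asarray(self.bins, int)
        self.u = np.asarray(self.u, float)
        if np.any(np.diff(self.bins) <= 0):
            raise ValueError("borders must be strictly increasing")
        k = len(self.bins)
        if not self.labels:
            self.labels = tuple(f"B{i + 1}" for i in range(k))
        if not self.region_labels:
            self.region_labels = tuple(f"R{i + 1}" for i in range(k + 1))

    @property
    def region_intervals(self) -> list[tuple[float, float]]:
        """Region intervals in normalized units, termini included."""
        edges = np.concatenate([[0.0], self.u, [1.0]])
        return list(zip(edges[:-1], edges[1:]))


def _stack_tracks(profiles: Sequence[BinnedProfile], variable: str) -> np.ndarray:
    mats = []
    for p in profiles:
        mats.append(p.feature(variable))
    mat = np.vstack(mats).astype(float)
    if np.all(np.isnan(mat)):
        raise ValueError(f"variable {variable!r} is all-missing across samples")
    return mat


def border_score(
    profiles: Sequence[BinnedProfile],
    variables: Sequence[str] | None = None,
    weights: dict[str, float] | None = None,
    window: int = 5,
    edge_exclude: int = 4,
) -> BorderScore:
    """Compute the multivariate border score over binned profiles.

    Parameters
    ----------
    profiles : sequence of BinnedProfile
        One or more samples with identical ``n_bins``.
    variables : sequence of str, optional
        Profile features to aggregate; defaults to width, polyploid nucleus
        area, nearest-neighbor distance and total count.
    weights : dict, optional
        Weight per variable; missing variables get weight 1.
    window : int
        Half-width w (bins) of the trailing/leading comparison windows;
        must be >= 2.
    edge_exclude : int
        Number of outermost bins per terminus excluded from all windows.
        The first/last bins of a linearized organ are corrupted by the
        tube end caps (wall objects overhang the centerline termini by
        roughly one tube radius, about 3-4 bins of 100 at typical midgut
        geometry) and must not feed the change windows.
    """
    if len(profiles) < 1:
        raise ValueError("need at least one profile")
    if window < 2:
        raise ValueError(f"window must be >= 2, got {window}")
    n_bins = profiles[0].n_bins
    if any(p.n_bins != n_bins for p in profiles):
        raise ValueError("profiles disagree on n_bins")
    if variables is None:
        variables = tuple(DEFAULT_WEIGHTS)
    if weights is None:
        weights = DEFAULT_WEIGHTS
    if edge_exclude < 0:
        raise ValueError("edge_exclude must be >= 0")
    w = window
    trim = edge_exclude

    contributions: dict[str, np.ndarray] = {}
    for var in variables:
        mat = _stack_tracks(profiles, var)
        # per-sample median normalization removes sample-scale differences
        med = np.nanmedian(mat, axis=1, keepdims=True)
        med[med == 0] = 1.0
        mat = mat / med
        with warnings.catch_warnings():
            # bins missing in every sample legitimately average to NaN
            warnings.simplefilter("ignore", RuntimeWarning)
            track = np.nanmean(mat, axis=0)
        contrib = np.full(n_bins, np.nan)
        # scorable edges need full windows clear of the excluded edge
        # margin; the set [trim+w, n-2-w-trim] is invariant under A/P
        # reversal (which maps edge b to n-2-b), keeping the score track
        # exactly symmetric under orientation reversal.
        for b in range(trim + w, n_bins - w - trim - 1):
            left = track[b - w + 1 : b + 1]
            right = track[b + 1 : b + w + 1]
            if np.all(np.isnan(left)) or np.all(np.isnan(right)):
                continue
            contrib[b] = abs(np.nanmean(left) - np.nanmean(right))
        valid = ~np.isnan(contrib)
        if not np.any(valid):
            raise ValueError(f"variable {var!r} produced no scorable bins")
        mu = contrib[valid].mean()
        sd = contrib[valid].std()
        z = np.full(n_bins, np.nan)
        # degenerate-variance rule: a constant track contributes 0 everywhere
        z[valid] = (contrib[valid] - mu) / sd if sd > 0 else 0.0
        contributions[var] = z

    score = np.full(n_bins, np.nan)
    scorable = np.zeros(n_bins, dtype=bool)
    acc = np.zeros(n_bins)
    for var in variables:
        z = contributions[var]
        valid = ~np.isnan(z)
        acc[valid] += weights.get(var, 1.0) * z[valid]
        scorable |= valid
    score[scorable] = acc[scorable]
    return BorderScore(score=score, contributions=contributions, window=w,
                       weights={v: weights.get(v, 1.0) for v in variables},
                       n_bins=n_bins)


def call_borders(score: BorderScore, k: int = 4,
                 min_separation: int = 5) -> BorderSet:
    """Call the k highest score peaks as borders, with non-max suppression.

    Peaks are local maxima of the score track; they are accepted greedily in
    decreasing height, skipping any peak within ``min_separation`` bins of
    an already accepted one. Fewer than k acceptable peaks raise an error
    reporting how many were found.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if min_separation < 1:
        raise ValueError("min_separation must be >= 1")
    s = np.where(np.isnan(score.score), -np.inf, score.score)
    peaks, _ = find_peaks(s)
    peaks = peaks[np.isfinite(s[peaks])]
    if len(peaks) == 0:
        raise ValueError(f"found 0 peaks, cannot call {k} borders")
    order = peaks[np.argsort(s[peaks])[::-1]]
    accepted: list[int] = []
    for b in order:
        if all(abs(b - a) >= min_separation for a in accepted):
            accepted.append(int(b))
        if len(accepted) == k:
            break
    if len(accepted) < k:
        raise ValueError(
            f"found only {len(accepted)} peaks separated by >= "
            f"{min_separation} bins, cannot call {k} borders"
        )
    bins = np.sort(accepted)
    u = (bins + 1) / score.n_bins
    return BorderSet(bins=bins, u=u, n_bins=score.n_bins)


def region_lengths(borders: BorderSet, axis: MidgutAxis | float) -> dict:
    """Region lengths in bins, normalized units and µm.

    ``axis`` may be a fitted :class:`MidgutAxis` or the total length L in
    µm. Lengths sum to L by construction.
    """
    L = axis.length if isinstance(axis, MidgutAxis) else float(axis)
    edges_u = np.concatenate([[0.0], borders.u, [1.0]])
    edges_b = np.concatenate([[0], borders.bins + 1, [borders.n_bins]])
    out = {}
    for i, name in enumerate(borders.region_labels):
        out[name] = {
            "bins": int(edges_b[i + 1] - edges_b[i]),
            "u": float(edges_u[i + 1] - edges_u[i]),
            "um": float((edges_u[i + 1] - edges_u[i]) * L),
        }
    return out


@dataclass
class SampleWarp:
    """Monotone piecewise-linear re-mapping of u onto reference borders."""

    knots_from: np.ndarray
    knots_to: np.ndarray

    def __call__(self, u: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(u, float), self.knots_from, self.knots_to)


def align_samples(border_sets: Sequence[BorderSet],
                  sample_ids: Sequence[str] | None = None) -> list[SampleWarp]:
    """Warp each sample's u so its borders land on the cross-sample medians.

    All samples must carry the same number of borders. The reference
    position of each border is the median across samples; each sample gets
    a monotone piecewise-linear map sending (0, its borders, 1) to
    (0, reference borders, 1). The warp is strictly increasing on [0, 1].
    """
    if len(border_sets) == 0:
        raise ValueError("need at least one border set")
    ks = {len(b.u) for b in border_sets}
    if len(ks) != 1:
        raise ValueError("samples disagree on the number of borders")
    if sample_ids is None:
        sample_ids = [f"sample_{i}" for i in range(len(border_sets))]
    mat = np.vstack([b.u for b in border_sets])
    for sid, row in zip(sample_ids, mat):
        if np.any(np.diff(row) <= 0) or row[0] <= 0 or row[-1] >= 1:
            raise ValueError(f"non-monotone borders in sample {sid}")
    ref = np.median(mat, axis=0)
    warps = []
    for row in mat:
        warps.append(SampleWarp(
            knots_from=np.concatenate([[0.0], row, [1.0]]),
            knots_to=np.concatenate([[0.0], ref, [1.0]]),
        ))
    return warps


class BorderDetector(BaseEstimator):
    """Estimate region borders from a cohort of binned profiles.

    Parameters mirror :func:`border_score` and :func:`call_borders`; after
    ``fit`` the score track is in ``score_`` and the called borders in
    ``borders_``.
    """

    def __init__(self, variables: tuple[str, ...] | None = None,
                 weights: dict[str, float] | None = None,
                 window: int = 5, k: int = 4, min_separation: int = 5,
                 edge_exclude: int = 4):
        self.variables = variables
        self.weights = weights
        self.window = window
        self.k = k
        self.min_separation = min_separation
        self.edge_exclude = edge_exclude

    def fit(self, profiles: Sequence[BinnedProfile], y=None):
        self.score_ = border_score(profiles, variables=self.variables,
                                   weights=self.weights, window=self.window,
                                   edge_exclude=self.edge_exclude)
        self.borders_ = call_borders(self.score_, k=self.k,
                                     min_separation=self.min_separation)
        return self
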