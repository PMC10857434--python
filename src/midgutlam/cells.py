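"""Per-cell calls: marker positivity, FUCCI phase gating, progenitor doublets.

FUCCI gating follows the two-reporter logic of the fly cell-cycle indicator:
the E2F1 degron reporter is present in G1 and G2-M, the CycB degron reporter
in S and G2-M, so (E2F1+, CycB-) = G1, (E2F1-, CycB+) = S, (+, +) = G2-M and
(-, -) is reported as unclassified (never silently dropped).

Progenitor doublets are mutual nearest neighbors among esg+ cells within a
pairing radius; a candidate pair is rejected when either member has a third
progenitor within the exclusion radius, so clusters/nests are not scored as
doublets. Doublet symmetry follows the Delta / Prospero status of the two
members: Delta+/Delta+ (both Pros-) is a symmetric ISC-ISC pair,
Delta+/Delta- (both Pros-) an asymmetric ISC-EB pair, and any member that is
Delta+Pros+ marks an ISC-preEE pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator

from ._bimodal import UnimodalError, log_valley_threshold

__all__ = [
    "MarkerGate",
    "threshold_marker",
    "call_phase",
    "PhaseCall",
    "Doublet",
    "pair_doublets",
    "classify_doublet",
    "doublet_summary",
    "UnimodalError",
]

PHASE_TABLE = {
    (True, False): "G1",
    (False, True): "S",
    (True, True): "G2M",
    (False, False): "unclassified",
}

DOUBLET_CLASSES = ("symmetric_ISC_ISC", "asymmetric_ISC_EB", "ISC_preEE",
                   "other")


class MarkerGate(BaseEstimator):
    """Threshold a marker channel into positive / negative.

    Parameters
    ----------
    method : str, default "bimodal-valley"
        ``"bimodal-valley"`` places the threshold at the valley of the
        smoothed log-intensity histogram between the two largest modes (and
        errors, suggesting the quantile method, when no valley exists);
        ``"quantile:q"`` places it at quantile q of the values.

    Attributes
    ----------
    threshold_ : float
        Values >= threshold are positive.
    """

    def __init__(self, method: str = "bimodal-valley"):
        self.method = method

    def fit(self, values, y=None):
        v = np.asarray(values, float)
        if len(v) == 0:
            raise ValueError("no values to fit a marker gate")
        if self.method == "bimodal-valley":
            # the histogram-valley estimate needs a real sample
            if len(v) < 20:
                raise ValueError(
                    "need >= 20 values for the bimodal-valley method"
                )
            try:
                self.threshold_ = log_valley_threshold(v)
            except UnimodalError as err:
                raise UnimodalError(
                    f"{err}; consider method='quantile:q'"
                ) from err
        elif self.method.startswith("quantile:"):
            q = float(self.method.split(":", 1)[1])
            if not 0.0 < q < 1.0:
                raise ValueError("quantile must lie in (0, 1)")
            self.threshold_ = float(np.quantile(v, q))
        else:
            raise ValueError(f"unknown method {self.method!r}")
        return self

    def predict(self, values) -> np.ndarray:
        if not hasattr(self, "threshold_"):
            raise ValueError("MarkerGate is not fitted yet")
        return np.asarray(values, float) >= self.threshold_


def threshold_marker(intensities, method: str = "bimodal-valley"):
    """Call each record positive/negative for a marker.

    Returns ``(positive, threshold)`` where ``positive`` is a boolean array
    (value >= threshold) and ``threshold`` the cut used.
    """
    gate = MarkerGate(method=method).fit(intensities)
    return gate.predict(intensities), gate.threshold_


@dataclass(frozen=True)
class PhaseCall:
    """FUCCI phase of one cell plus the reporter states behind the call."""

    phase: str
    e2f1_positive: bool
    cycb_positive: bool


def call_phase(e2f1_state, cycb_state):
    """Gate FUCCI reporter states into G1 / S / G2M / unclassified.

    Scalars return a :class:`PhaseCall`; arrays return an object array of
    phase names. The call is a pure function of the two boolean states.
    """
    e = np.asarray(e2f1_state)
    c = np.asarray(cycb_state)
    if e.shape != c.shape:
        raise ValueError("reporter state arrays must have the same shape")
    if e.ndim == 0:
        phase = PHASE_TABLE[(bool(e), bool(c))]
        return PhaseCall(phase=phase, e2f1_positive=bool(e),
                         cycb_positive=bool(c))
    out = np.empty(e.shape, dtype=object)
    eb, cb = e.astype(bool), c.astype(bool)
    out[eb & ~cb] = "G1"
    out[~eb & cb] = "S"
    out[eb & cb] = "G2M"
    out[~eb & ~cb] = "unclassified"
    return out


@dataclass
class Doublet:
    """A mutually-nearest progenitor pair."""

    id_a: int
    id_b: int
    distance_um: float
    cls: str | None = None
    area_a: float | None = None
    area_b: float | None = None
    delta_a: bool | None = None
    delta_b: bool | None = None
    pros_a: bool | None = None
    pros_b: bool | None = None


def pair_doublets(
    progenitors: pd.DataFrame,
    pairing_radius_um: float = 10.0,
    exclusion_radius_um: float = 15.0,
) -> list[Doublet]:
    """Pair progenitor (esg+) records into doublets.

    A doublet is a mutual nearest-neighbor pair at 3D distance <= the
    pairing radius; the pair is rejected when either member has another
    progenitor within the exclusion radius (clusters are not doublets).
    Mutual nearest-neighborhood guarantees each cell joins at most one
    doublet. Doublets are returned ordered by the smaller member id, with
    ``id_a < id_b``.
    """
    if pairing_radius_um <= 0 or exclusion_radius_um <= 0:
        raise ValueError("pairing and exclusion radii must be positive")
    pts = progenitors[["x_um", "y_um", "z_um"]].to_numpy(float)
    ids = (progenitors["object_id"].to_numpy(int)
           if "object_id" in progenitors.columns
           else np.arange(len(progenitors)))
    areas = (progenitors["area_um2"].to_numpy(float)
             if "area_um2" in progenitors.columns else None)
    n = len(pts)
    if n < 2:
        return []
    tree = cKDTree(pts)
    dist, nn = tree.query(pts, k=min(3, n))
    nn1 = nn[:, 1]
    d1 = dist[:, 1]
    mutual = (nn1[nn1] == np.arange(n)) & (d1 <= pairing_radius_um)
    doublets: list[Doublet] = []
    for i in np.flatnonzero(mutual):
        j = nn1[i]
        if i >= j:
            continue
        # third-progenitor exclusion around either member
        reject = False
        for m in (i, j):
            others = tree.query_ball_point(pts[m], exclusion_radius_um)
            if any(o not in (i, j) for o in others):
                reject = True
                break
        if reject:
            continue
        doublets.append(
            Doublet(
                id_a=int(ids[i]), id_b=int(ids[j]), distance_um=float(d1[i]),
                area_a=None if areas is None else float(areas[i]),
                area_b=None if areas is None else float(areas[j]),
            )
        )
    doublets.sort(key=lambda d: (d.id_a, d.id_b))
    return doublets


def classify_doublet(doublet: Doublet, delta_status, pros_status) -> str:
    """Symmetry class from the members' Delta / Prospero status.

    ``delta_status`` / ``pros_status`` are (status_a, status_b) booleans.
    Delta+/Delta+ with both Pros- is symmetric ISC-ISC; Delta+/Delta- with
    both Pros- is asymmetric ISC-EB; any Delta+Pros+ member marks an
    ISC-preEE pair; anything else is "other". The class is stored on the
    doublet and returned.
    """
    da, db = delta_status
    pa, pb = pros_status
    for v in (da, db, pa, pb):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValueError("missing Delta/Prospero status for doublet member")
    da, db, pa, pb = bool(da), bool(db), bool(pa), bool(pb)
    if (da and pa) or (db and pb):
        cls = "ISC_preEE"
    elif da and db and not pa and not pb:
        cls = "symmetric_ISC_ISC"
    elif (da != db) and not pa and not pb:
        cls = "asymmetric_ISC_EB"
    else:
        cls = "other"
    doublet.cls = cls
    doublet.delta_a, doublet.delta_b = da, db
    doublet.pros_a, doublet.pros_b = pa, pb
    return cls


def doublet_summary(doublets, group_labels=None) -> pd.DataFrame:
    """Counts, fractions and size asymmetry per doublet class per group.

    Parameters
    ----------
    doublets : sequence of classified :class:`Doublet`
    group_labels : sequence of str, optional
        One group label per doublet (e.g. the sample's condition); a single
        pooled group by default.

    Returns
    -------
    DataFrame indexed by group with columns ``n_<class>`` (0 for an empty
    class, never missing), ``n_total``, ``symmetric_fraction`` and
    ``asym_area_diff`` — the mean nucleus-area difference (Delta- member
    minus Delta+ member) within asymmetric pairs.
    """
    if len(doublets) < 1:
        raise ValueError("need at least one doublet")
    if group_labels is None:
        group_labels = ["all"] * len(doublets)
    rows = {}
    for g in pd.unique(np.asarray(group_labels, dtype=object)):
        sel = [d for d, gl in zip(doublets, group_labels) if gl == g]
        row = {f"n_{c}": 0 for c in DOUBLET_CLASSES}
        asym_diffs = []
        for d in sel:
            if d.cls is None:
                raise ValueError("doublets must be classified before summary")
            row[f"n_{d.cls}"] += 1
            if (d.cls == "asymmetric_ISC_EB" and d.area_a is not None
                    and d.area_b is not None):
                # Delta- (prospective EB) minus Delta+ (ISC) area
                if d.delta_a and not d.delta_b:
                    asym_diffs.append(d.area_b - d.area_a)
                elif d.delta_b and not d.delta_a:
                    asym_diffs.append(d.area_a - d.area_b)
        n_total = len(sel)
        row["n_total"] = n_total
        row["symmetric_fraction"] = (
            row["n_symmetric_ISC_ISC"] / n_total if n_total else 0.0
        )
        row["asym_area_diff"] = (
            float(np.mean(asym_diffs)) if asym_diffs else np.nan
        )
        rows[g] = row
    return pd.DataFrame.from_dict(rows, orient="index")
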