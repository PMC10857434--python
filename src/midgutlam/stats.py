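"""Nonparametric and parametric tests for regional midgut comparisons.

The workhorse is the two-sided Wilcoxon rank-sum (Mann-Whitney U) test. For
small problems (combined n <= 10) the p-value is exact, by enumeration of
all C(n, n_a) group labelings of the pooled midranks — ties included; larger
problems use the normal approximation with tie-corrected variance and a
±0.5 continuity correction. Bin-wise group comparisons apply the test per
axis bin and control the false discovery rate with Benjamini-Hochberg
step-up across the scorable bins of one feature (per-panel FDR, not pooled
across features).

Kruskal-Wallis (tie-corrected, chi-square reference) provides the omnibus
test for >= 3 groups with rank-sum pairwise follow-up; the paired t test and
two-factor ANOVA with Tukey HSD cover the parametric comparisons.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import MultiComparison

__all__ = [
    "rank_sum_test",
    "bh_adjust",
    "per_bin_compare",
    "kruskal_pairwise",
    "paired_t",
    "two_way_anova_tukey",
    "EXACT_MAX_N",
]

#: combined sample size at or below which the rank-sum p is exact
EXACT_MAX_N = 10


@lru_cache(maxsize=64)
def _labelings(n_total: int, n_a: int) -> np.ndarray:
    """All C(n_total, n_a) index sets for group A, as an array."""
    return np.array(list(combinations(range(n_total), n_a)), dtype=int)


def _u_statistic(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2.0)


def rank_sum_test(a, b, continuity: bool = True, method: str = "auto"):
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Parameters
    ----------
    a, b : array-like
        The two groups; both must be non-empty.
    continuity : bool
        Apply the ±0.5 continuity correction in the normal approximation.
    method : {"auto", "exact", "normal"}
        ``auto`` uses exact enumeration when the combined size is at most
        10 and the normal approximation otherwise.

    Returns
    -------
    (U, p) : U statistic of group ``a`` and the two-sided p-value.

    Notes
    -----
    Midranks are used for ties in both modes. The exact two-sided p is
    ``P(|U - n_a n_b / 2| >= |U_obs - n_a n_b / 2|)`` under uniform random
    labeling of the pooled values; the normal mode uses the tie-corrected
    variance.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = len(a), len(b)
    n = n_a + n_b
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)          # midranks
    u_obs = _u_statistic(ranks[:n_a], n_a)

    if method not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown method {method!r}")
    exact = method == "exact" or (method == "auto" and n <= EXACT_MAX_N)
    if exact:
        if n > 16:
            raise ValueError("exact enumeration limited to combined n <= 16")
        idx = _labelings(n, n_a)
        u_all = ranks[idx].sum(axis=1) - n_a * (n_a + 1) / 2.0
        mu = n_a * n_b / 2.0
        p = float(np.mean(np.abs(u_all - mu) >= abs(u_obs - mu) - 1e-12))
        return u_obs, min(p, 1.0)

    mu = n_a * n_b / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return u_obs, 1.0
    diff = u_obs - mu
    if continuity:
        diff = np.sign(diff) * max(abs(diff) - 0.5, 0.0)
    z = diff / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return u_obs, float(min(p, 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    ``q_i = min_{j >= i} (m / j) p_(j)``, capped at 1.
    """
    p = np.asarray(p_values, float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def per_bin_compare(
    group_a,
    group_b,
    feature: str | None = None,
    alpha: float = 0.05,
    continuity: bool = True,
) -> pd.DataFrame:
    """Bin-wise rank-sum comparison of two sample groups with BH-FDR.

    Parameters
    ----------
    group_a, group_b
        Either lists of :class:`~midgutlam.profiles.BinnedProfile` (then
        ``feature`` selects the track) or 2D arrays of shape
        (n_samples, n_bins).
    feature : str
        Profile feature to compare when profiles are given.
    alpha : float
        FDR level for the ``significant`` flag.

    Returns
    -------
    DataFrame with one row per bin: ``bin``, ``u`` (bin center), ``n_a``,
    ``n_b``, ``U``, ``p_raw``, ``p_adj`` and ``significant``. Bins missing
    in more than half of either group are unscorable (NaN p, not
    significant); adjustment runs across scorable bins only.
    """
    mat_a = _as_matrix(group_a, feature)
    mat_b = _as_matrix(group_b, feature)
    if mat_a.shape[1] != mat_b.shape[1]:
        raise ValueError("groups disagree on the number of bins")
    if mat_a.shape[0] < 3 or mat_b.shape[0] < 3:
        raise ValueError("need >= 3 samples per group")
    n_bins = mat_a.shape[1]

    u_stat = np.full(n_bins, np.nan)
    p_raw = np.full(n_bins, np.nan)
    n_a_arr = np.zeros(n_bins, int)
    n_b_arr = np.zeros(n_bins, int)
    for i in range(n_bins):
        va = mat_a[:, i]
        vb = mat_b[:, i]
        va = va[~np.isnan(va)]
        vb = vb[~np.isnan(vb)]
        n_a_arr[i], n_b_arr[i] = len(va), len(vb)
        # unscorable when missing in more than half of either group
        if (len(va) < mat_a.shape[0] / 2.0) or (len(vb) < mat_b.shape[0] / 2.0):
            continue
        u_stat[i], p_raw[i] = rank_sum_test(va, vb, continuity=continuity)

    scorable = ~np.isnan(p_raw)
    p_adj = np.full(n_bins, np.nan)
    if np.any(scorable):
        p_adj[scorable] = bh_adjust(p_raw[scorable])
    significant = np.zeros(n_bins, bool)
    significant[scorable] = p_adj[scorable] < alpha
    return pd.DataFrame(
        {
            "bin": np.arange(n_bins),
            "u": (np.arange(n_bins) + 0.5) / n_bins,
            "n_a": n_a_arr,
            "n_b": n_b_arr,
            "U": u_stat,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "significant": significant,
        }
    )


def _as_matrix(group, feature):
    if hasattr(group[0], "feature"):
        if feature is None:
            raise ValueError("feature name required when passing profiles")
        return np.vstack([p.feature(feature) for p in group]).astype(float)
    return np.atleast_2d(np.asarray(group, float))


def kruskal_pairwise(groups: Sequence) -> dict:
    """Kruskal-Wallis omnibus over >= 3 groups with rank-sum follow-up.

    Returns a dict with ``H``, ``p`` (chi-square reference, k-1 df,
    tie-corrected) and ``pairwise`` — a DataFrame of all group pairs with
    raw and BH-adjusted rank-sum p-values.
    """
    if len(groups) < 3:
        raise ValueError("need >= 3 groups for the omnibus test")
    arrays = [np.asarray(g, float) for g in groups]
    if any(len(g) == 0 for g in arrays):
        raise ValueError("empty group")
    h, p = sps.kruskal(*arrays)
    pairs = list(combinations(range(len(arrays)), 2))
    raw = []
    u_vals = []
    for i, j in pairs:
        u, pij = rank_sum_test(arrays[i], arrays[j])
        u_vals.append(u)
        raw.append(pij)
    adj = bh_adjust(raw)
    pairwise = pd.DataFrame(
        {
            "group_a": [i for i, _ in pairs],
            "group_b": [j for _, j in pairs],
            "U": u_vals,
            "p_raw": raw,
            "p_adj": adj,
        }
    )
    return {"H": float(h), "p": float(p), "pairwise": pairwise}


def paired_t(x, y):
    """Classic paired t test on the within-pair differences.

    Requires equal lengths >= 2 and non-degenerate differences (constant
    differences have zero variance and no defined t).
    Returns ``(t, two-sided p)`` with n-1 degrees of freedom.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if len(x) < 2:
        raise ValueError("need >= 2 pairs")
    d = x - y
    if np.std(d, ddof=1) == 0:
        raise ValueError("differences have zero variance; t is undefined")
    res = sps.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


def two_way_anova_tukey(values, factor_a, factor_b):
    """Two-factor ANOVA with interaction plus Tukey HSD over the cells.

    Balanced designs use classical sequential sums of squares (equal to the
    unique/partial SS when balanced); unbalanced designs use Type II. Tukey
    HSD compares all factor-level cell means against the studentized-range
    reference.

    Returns
    -------
    (anova, tukey) : the ANOVA table (DataFrame with sum_sq, df, F, PR(>F)
    for A, B, A:B and Residual) and the Tukey HSD results DataFrame.
    """
    values = np.asarray(values, float)
    fa = np.asarray(factor_a, dtype=object)
    fb = np.asarray(factor_b, dtype=object)
    if not (len(values) == len(fa) == len(fb)):
        raise ValueError("values and factors must have equal length")
    df = pd.DataFrame({"y": values, "A": fa.astype(str), "B": fb.astype(str)})
    cells = df.groupby(["A", "B"], observed=True).size()
    n_cells = df["A"].nunique() * df["B"].nunique()
    if len(cells) < n_cells:
        raise ValueError("empty factor cell; no imputation is performed")
    if (cells < 2).any():
        raise ValueError(
            "every factor cell needs >= 2 replicates for the interaction term"
        )
    model = smf.ols("y ~ C(A) * C(B)", data=df).fit()
    balanced = cells.nunique() == 1
    anova = sm.stats.anova_lm(model, typ=1 if balanced else 2)
    anova = anova.rename(index={
        "C(A)": "A", "C(B)": "B", "C(A):C(B)": "A:B"
    })
    cell_label = (df["A"] + ":" + df["B"]).to_numpy()
    tukey = MultiComparison(df["y"].to_numpy(), cell_label).tukeyhsd()
    tukey_df = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    return anova, tukey_df
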