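"""Area-weighted summaries, group comparisons, and stratified statistics.

Triangles vary in size, so every per-surface summary of a per-triangle
quantity is *area-weighted*: the per-surface thickness statistic is the
area-weighted median over its (converged, non-edge-excluded) faces.
Between-group comparisons then treat surfaces — not triangles, which are
spatially correlated within a surface — as the observations: groups are
summarised as mean ± 1.96·SE across their per-surface medians and compared
with the Mann–Whitney U test.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "weighted_median",
    "weighted_histogram",
    "mann_whitney_u",
    "quantile_partition",
    "SurfaceSummary",
    "summarize_surface",
    "GroupComparison",
    "group_compare",
    "QuantileAnalysis",
    "thickness_by_quantile",
    "hist2d_thickness_curvedness",
    "DEFAULT_QUANTILE_EDGES",
]

DEFAULT_QUANTILE_EDGES = (0.0, 0.5, 0.9, 0.95, 0.99, 1.0)


def weighted_median(values, weights) -> float:
    """Smallest value whose cumulative weight reaches half the total.

    Values are sorted; equal values share their summed weight.  With equal
    weights this reduces to the ordinary (lower) median.
    """
    v = np.asarray(values, dtype=np.float64)
    w = np.asarray(weights, dtype=np.float64)
    if v.size == 0:
        raise ValueError("weighted_median of empty input")
    if np.any(w <= 0):
        raise ValueError("weights must be > 0")
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    cum = np.cumsum(w)
    return float(v[np.searchsorted(cum, 0.5 * cum[-1])])


def weighted_histogram(values, weights, bins) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin summed weight, normalised to total mass 1.

    Bins are half-open ``[lo, hi)`` with the last bin closed, so every
    in-range value lands in exactly one bin (numpy's convention).
    """
    counts, edges = np.histogram(np.asarray(values, dtype=np.float64),
                                 bins=np.asarray(bins, dtype=np.float64),
                                 weights=np.asarray(weights, dtype=np.float64))
    total = counts.sum()
    return (counts / total if total > 0 else counts), edges


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test (U statistic of the first sample).

    Exact p by enumeration of the rank distribution when one sample is
    small (<= 8) or the total is small (<= 12) and there are no ties;
    otherwise the normal approximation with midrank tie correction and
    continuity correction.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    small = (len(a) + len(b) <= 12) or (min(len(a), len(b)) <= 8)
    method = "exact" if (no_ties and small) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def quantile_partition(values,
                       quantile_edges=DEFAULT_QUANTILE_EDGES) -> np.ndarray:
    """Assign each value to a quantile bin by its empirical (midrank) rank.

    Bin ``k`` covers quantile ranks in ``(q_k, q_{k+1}]`` (lowest bin
    closed below), so with 100 distinct values and the default edges the
    bin counts are forced to 50/40/5/4/1.  Rank-based assignment makes
    the partition invariant under monotone transforms of the values.
    """
    edges = np.asarray(quantile_edges, dtype=np.float64)
    if (np.any(np.diff(edges) <= 0) or edges[0] != 0.0 or edges[-1] != 1.0):
        raise ValueError("quantile_edges must increase from 0 to 1")
    v = np.asarray(values, dtype=np.float64)
    q = sps.rankdata(v, method="average") / len(v)
    bins = np.searchsorted(edges, q, side="left") - 1
    return np.clip(bins, 0, len(edges) - 2)


# -- per-surface summaries and group comparison -----------------------------


@dataclass
class SurfaceSummary:
    """One surface's area-weighted thickness summary."""

    surface_id: str
    label: str
    n_faces: int
    median_thickness_nm: float
    convergence_fraction: float


def summarize_surface(thickness: np.ndarray, areas: np.ndarray,
                      surface_id: str = "", label: str = "",
                      convergence_fraction: float | None = None,
                      ) -> SurfaceSummary:
    """Area-weighted median thickness over the faces with a defined value."""
    t = np.asarray(thickness, dtype=np.float64)
    a = np.asarray(areas, dtype=np.float64)
    ok = np.isfinite(t)
    if not ok.any():
        raise ValueError(f"surface {surface_id!r}: no defined thickness values")
    if convergence_fraction is None:
        convergence_fraction = float(ok.mean())
    return SurfaceSummary(
        surface_id=surface_id, label=label, n_faces=int(ok.sum()),
        median_thickness_nm=weighted_median(t[ok], a[ok]),
        convergence_fraction=convergence_fraction,
    )


@dataclass
class GroupComparison:
    """Across-surface group statistics and pairwise tests.

    ``groups`` has one row per group label: number of surfaces, mean of
    the per-surface medians, and the SE-based 95% CI (NaN for groups with
    a single surface).  ``pairwise`` has one row per group pair with the
    U statistic and two-sided p-value.
    """

    groups: pd.DataFrame
    pairwise: pd.DataFrame
    per_surface: dict[str, np.ndarray] = field(default_factory=dict)


def group_compare(summaries: list[SurfaceSummary],
                  bonferroni: bool = False) -> GroupComparison:
    """Compare per-surface median thicknesses between labelled groups.

    Surfaces are the observations.  Each group is reported as
    mean ± 1.96·sd/√n over its per-surface medians; every group pair gets
    a two-sided Mann–Whitney U test (raw p-values by default; set
    ``bonferroni=True`` to multiply by the number of pairs).
    """
    by_label: dict[str, list[float]] = {}
    for s in summaries:
        by_label.setdefault(s.label, []).append(s.median_thickness_nm)
    if len(by_label) < 2:
        raise ValueError("group_compare needs at least two groups")
    rows = []
    per_surface = {}
    for label, vals in by_label.items():
        v = np.asarray(vals, dtype=np.float64)
        per_surface[label] = v
        mean = v.mean()
        if len(v) >= 2:
            half = 1.96 * v.std(ddof=1) / np.sqrt(len(v))
            lo, hi = mean - half, mean + half
        else:
            lo = hi = float("nan")
        rows.append({"label": label, "n_surfaces": len(v), "mean_nm": mean,
                     "ci95_lo_nm": lo, "ci95_hi_nm": hi})
    pairs = list(itertools.combinations(sorted(by_label), 2))
    prows = []
    for la, lb in pairs:
        u, p = mann_whitney_u(per_surface[la], per_surface[lb])
        if bonferroni:
            p = min(1.0, p * len(pairs))
        prows.append({"group_a": la, "group_b": lb, "U": u, "p": p})
    return GroupComparison(groups=pd.DataFrame(rows),
                           pairwise=pd.DataFrame(prows),
                           per_surface=per_surface)


# -- curvature-quantile stratification --------------------------------------


@dataclass
class QuantileAnalysis:
    """Thickness distributions stratified by curvedness quantile."""

    bin_index: np.ndarray          # per included face
    face_index: np.ndarray         # indices of the included faces
    summary: pd.DataFrame          # per-bin area-weighted stats
    pairwise: pd.DataFrame         # bin-vs-bin Mann–Whitney tests
    top_vs_rest: tuple[float, float]  # U, p of the top bin against all others


def thickness_by_quantile(thickness, curvedness, areas,
                          quantile_edges=DEFAULT_QUANTILE_EDGES,
                          min_faces: int = 100) -> QuantileAnalysis:
    """Stratify per-face thickness by curvedness quantile bins.

    Faces need both attributes defined; the curvedness values are
    partitioned with :func:`quantile_partition` and each bin is summarised
    by its area-weighted median/mean thickness.  Pairwise Mann–Whitney
    tests compare the per-face thicknesses between bins; ``top_vs_rest``
    tests the highest-curvature bin against everything else (the contrast
    of interest: are the most curved triangles thicker?).
    """
    t = np.asarray(thickness, dtype=np.float64)
    c = np.asarray(curvedness, dtype=np.float64)
    a = np.asarray(areas, dtype=np.float64)
    ok = np.isfinite(t) & np.isfinite(c)
    if ok.sum() < min_faces:
        raise ValueError(f"need >= {min_faces} faces with thickness and "
                         f"curvedness, got {int(ok.sum())}")
    face_index = np.flatnonzero(ok)
    t, c, a = t[ok], c[ok], a[ok]
    bins = quantile_partition(c, quantile_edges)
    n_bins = len(quantile_edges) - 1
    rows = []
    for k in range(n_bins):
        m = bins == k
        rows.append({
            "bin": k,
            "quantile_range": f"{quantile_edges[k]}-{quantile_edges[k + 1]}",
            "n_faces": int(m.sum()),
            "median_thickness_nm": weighted_median(t[m], a[m]) if m.any() else np.nan,
            "mean_thickness_nm": float(np.average(t[m], weights=a[m])) if m.any() else np.nan,
        })
    prows = []
    for i, j in itertools.combinations(range(n_bins), 2):
        mi, mj = bins == i, bins == j
        if mi.any() and mj.any():
            u, p = mann_whitney_u(t[mi], t[mj])
            prows.append({"bin_a": i, "bin_b": j, "U": u, "p": p})
    top = bins == (n_bins - 1)
    top_vs_rest = (mann_whitney_u(t[top], t[~top])
                   if top.any() and (~top).any() else (np.nan, np.nan))
    return QuantileAnalysis(bin_index=bins, face_index=face_index,
                            summary=pd.DataFrame(rows),
                            pairwise=pd.DataFrame(prows),
                            top_vs_rest=top_vs_rest)


def hist2d_thickness_curvedness(mean_thickness, mean_curvedness,
                                bins=20) -> tuple[np.ndarray, np.ndarray,
                                                  np.ndarray, int]:
    """2D histogram of per-patch mean thickness vs log10 mean curvedness.

    Pairs with non-positive curvedness (log undefined) are dropped with a
    logged count.  Returns ``(counts, thickness_edges, log10c_edges,
    n_dropped)``.
    """
    t = np.asarray(mean_thickness, dtype=np.float64)
    c = np.asarray(mean_curvedness, dtype=np.float64)
    ok = np.isfinite(t) & np.isfinite(c) & (c > 0)
    n_dropped = int(len(t) - ok.sum())
    if n_dropped:
        logger.info("hist2d: dropped %d pairs with non-positive or undefined "
                    "curvedness", n_dropped)
    counts, te, ce = np.histogram2d(t[ok], np.log10(c[ok]), bins=bins)
    return counts, te, ce, n_dropped
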