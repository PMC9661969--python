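"""Group-difference statistics: PERMANOVA, Kruskal-Wallis, Dunn, haversine.

PERMANOVA follows Anderson's one-way partition of a distance matrix:

    F = (SS_among / (a - 1)) / (SS_within / (N - a))

with SS_total = sum of squared distances over all pairs / N and
SS_within summed per group; significance comes from unrestricted
random relabelling with the add-one convention
p = (1 + #{F_perm >= F_obs}) / (1 + n_perm), so p is never zero.

Kruskal-Wallis uses scipy's tie-corrected H with a chi-squared
reference (a - 1 df).  The Dunn post-hoc compares mean ranks with the
pooled tie correction; pairwise p-values are Benjamini-Hochberg
adjusted, as are pairwise PERMANOVA p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from .containers import SampleMetadata

__all__ = [
    "permanova",
    "pairwise_permanova",
    "kruskal_wallis",
    "dunn_test",
    "geographic_distances",
    "bh_adjust",
    "PermanovaResult",
    "GroupTestResult",
]

EARTH_RADIUS_KM = 6371.0


@dataclass
class PermanovaResult:
    pseudo_F: float
    r_squared: float
    p_value: float
    n_permutations: int


@dataclass
class GroupTestResult:
    """One (possibly pairwise) test: statistic, raw and adjusted p."""

    comparison: str
    statistic: float
    p_value: float
    p_adjusted: float | None = None


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


def _permanova_f(d2: np.ndarray, labels: np.ndarray) -> float:
    """Pseudo-F from a squared-distance matrix and integer group labels."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    groups = np.unique(labels)
    for g in groups:
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    ss_among = ss_total - ss_within
    a = groups.size
    return (ss_among / (a - 1)) / (ss_within / (n - a))


def permanova(
    dist: DistanceMatrix,
    groups: Sequence[str],
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-way PERMANOVA of a distance matrix against a grouping factor."""
    d = dist.data
    labels, counts = np.unique(np.asarray(groups), return_counts=True)
    if labels.size < 2:
        raise ValueError("need at least 2 groups")
    if np.any(counts < 2):
        small = [str(l) for l, c in zip(labels, counts) if c < 2]
        raise ValueError(f"groups with fewer than 2 members: {small}")
    if len(groups) != d.shape[0]:
        raise ValueError("groups not aligned to distance matrix")
    codes = np.searchsorted(labels, np.asarray(groups))
    d2 = d**2
    n = d.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    f_obs = _permanova_f(d2, codes)
    a = labels.size
    ss_within = 0.0
    for g in range(a):
        idx = np.flatnonzero(codes == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    r2 = (ss_total - ss_within) / ss_total if ss_total > 0 else 0.0

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if _permanova_f(d2, rng.permutation(codes)) >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermanovaResult(float(f_obs), float(r2), float(p), n_perm)


def pairwise_permanova(
    dist: DistanceMatrix,
    groups: Sequence[str],
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """PERMANOVA on every group pair, BH-adjusted across the pairs."""
    groups = np.asarray(groups)
    ids = np.asarray(dist.ids)
    labels = np.unique(groups)
    if labels.size < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    for k, (g1, g2) in enumerate(combinations(labels, 2)):
        keep = np.isin(groups, [g1, g2])
        sub = dist.filter(ids[keep])
        res = permanova(sub, groups[keep], n_perm=n_perm, seed=seed + k)
        rows.append(
            {
                "group_a": g1,
                "group_b": g2,
                "pseudo_F": res.pseudo_F,
                "r_squared": res.r_squared,
                "p_value": res.p_value,
            }
        )
    df = pd.DataFrame(rows)
    df["p_adjusted"] = bh_adjust(df["p_value"])
    return df


def kruskal_wallis(values: Sequence[float], groups: Sequence[str]) -> GroupTestResult:
    """Tie-corrected Kruskal-Wallis H with chi-squared p (a-1 df)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == g] for g in labels]
    if any(s.size < 1 for s in samples):
        raise ValueError("every group needs at least one value")
    if np.ptp(values) == 0:
        # all observations identical: no evidence of any difference
        return GroupTestResult("all", 0.0, 1.0)
    h, p = stats.kruskal(*samples)
    return GroupTestResult("all", float(h), float(p))


def dunn_test(values: Sequence[float], groups: Sequence[str]) -> pd.DataFrame:
    """Dunn's post-hoc z tests on mean ranks, BH-adjusted.

    z_ij = (Rbar_i - Rbar_j) / sqrt( (N(N+1)/12 - T/(12(N-1))) * (1/n_i + 1/n_j) )

    where T = sum over tied groups of (t^3 - t).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size < 2:
        raise ValueError("need at least 2 groups")
    n_total = values.size
    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    variance_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))

    mean_ranks = {g: ranks[groups == g].mean() for g in labels}
    sizes = {g: int(np.sum(groups == g)) for g in labels}
    rows = []
    for g1, g2 in combinations(labels, 2):
        se = np.sqrt(variance_base * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": g1, "group_b": g2, "z": z, "p_value": min(p, 1.0)})
    df = pd.DataFrame(rows)
    df["p_adjusted"] = bh_adjust(df["p_value"])
    return df


def geographic_distances(metadata: Sequence[SampleMetadata]) -> DistanceMatrix:
    """Great-circle (haversine) distances between lakes, in kilometres."""
    ids = [m.sample_id for m in metadata]
    lat = np.radians([m.latitude for m in metadata])
    lon = np.radians([m.longitude for m in metadata])
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        dlat = lat - lat[i]
        dlon = lon - lon[i]
        h = np.sin(dlat / 2) ** 2 + np.cos(lat[i]) * np.cos(lat) * np.sin(dlon / 2) ** 2
        out[i] = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    np.fill_diagonal(out, 0.0)
    # enforce exact symmetry against floating-point asymmetry
    out = (out + out.T) / 2
    return DistanceMatrix(out, ids=ids)
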