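"""Environmental screening, imputation, distance, and distance-decay.

Environmental variables are screened for near-zero variance and
pairwise co-correlation, missing cells are imputed by k-nearest
neighbours in z-scored space, each retained variable is centred and
scaled, and pairwise Euclidean distances over the scaled variables
give the environmental distance matrix.  Community similarity
(1 - Bray-Curtis) is then regressed on environmental distance by
ordinary least squares over all sample pairs.

The lake/catchment variable roster used by the study this pipeline
was built around ships as :data:`LAKE_VARIABLE_PRESET`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from sklearn.impute import KNNImputer

from .containers import EnvironmentalMatrix

__all__ = [
    "screen_variables",
    "impute_missing",
    "env_distance",
    "distance_decay_regression",
    "DecayRegression",
    "ScreenReport",
    "LAKE_VARIABLE_PRESET",
]

#: Nine lake variables plus five catchment land-cover proportions.
LAKE_VARIABLE_PRESET = [
    "TOC",
    "TN",
    "TP",
    "chlorophyll_a",
    "secchi_depth",
    "near_bed_temperature",
    "near_bed_dissolved_oxygen",
    "altitude",
    "max_depth",
    "catchment_forestry",
    "catchment_native_vegetation",
    "catchment_nonindigenous_vegetation",
    "catchment_low_producing_grassland",
    "catchment_other",
]


@dataclass
class ScreenReport:
    removed_near_zero_variance: list[str] = field(default_factory=list)
    removed_correlated: list[str] = field(default_factory=list)


def _near_zero_variance(col: np.ndarray, freq_ratio: float, unique_pct: float) -> bool:
    """caret-style nzv: ratio of two most common values AND % unique."""
    col = col[~np.isnan(col)]
    if col.size == 0:
        return True
    values, counts = np.unique(col, return_counts=True)
    if values.size == 1:
        return True
    counts = np.sort(counts)[::-1]
    ratio = counts[0] / counts[1]
    pct_unique = 100.0 * values.size / col.size
    return ratio > freq_ratio and pct_unique < unique_pct


def screen_variables(
    env: EnvironmentalMatrix,
    corr_threshold: float = 0.9,
    nzv_freq_ratio: float = 19.0,
    nzv_unique_pct: float = 10.0,
) -> tuple[EnvironmentalMatrix, ScreenReport]:
    """Drop near-zero-variance and highly co-correlated variables.

    After the variance filter, variable pairs with |Pearson r| above
    ``corr_threshold`` are resolved iteratively: the member with the
    larger mean absolute correlation against all remaining variables
    is removed, highest-|r| pair first.
    """
    if len(env.variables) < 2:
        raise ValueError("need at least 2 variables to screen")
    report = ScreenReport()
    keep = []
    for j, name in enumerate(env.variables):
        if _near_zero_variance(env.values[:, j], nzv_freq_ratio, nzv_unique_pct):
            report.removed_near_zero_variance.append(name)
        else:
            keep.append(name)
    if not keep:
        raise ValueError("all variables removed by near-zero-variance screen")
    current = env.select_variables(keep)

    while len(current.variables) >= 2:
        df = current.to_dataframe()
        corr = df.corr().to_numpy()
        np.fill_diagonal(corr, 0.0)
        abs_corr = np.abs(corr)
        i, j = np.unravel_index(np.nanargmax(abs_corr), abs_corr.shape)
        if abs_corr[i, j] <= corr_threshold:
            break
        mean_abs = np.nanmean(abs_corr, axis=1)
        drop = i if mean_abs[i] >= mean_abs[j] else j
        report.removed_correlated.append(current.variables[drop])
        remaining = [v for k, v in enumerate(current.variables) if k != drop]
        current = current.select_variables(remaining)
    if not current.variables:
        raise ValueError("all variables removed by screening")
    return current, report


def impute_missing(
    env: EnvironmentalMatrix, k: int = 5, seed: int = 0
) -> tuple[EnvironmentalMatrix, list[tuple[str, str]]]:
    """Fill missing cells by k-nearest-neighbour mean in z-scored space.

    Neighbour distances use the variables both rows share; the
    procedure is deterministic, the ``seed`` argument is kept for
    interface symmetry.  Returns the filled matrix and the
    (sample, variable) cells that were imputed.
    """
    values = env.values
    if not np.isnan(values).any():
        return env, []
    if np.isnan(values).all(axis=1).any():
        bad = [s for s, row in zip(env.sample_ids, values) if np.isnan(row).all()]
        raise ValueError(f"rows missing all variables: {bad}")
    complete = np.sum(~np.isnan(values), axis=0)
    if np.any(complete < k):
        short = [v for v, c in zip(env.variables, complete) if c < k]
        raise ValueError(f"variables with fewer than k={k} complete rows: {short}")

    mean = np.nanmean(values, axis=0)
    sd = np.nanstd(values, axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    z = (values - mean) / sd
    filled_z = KNNImputer(n_neighbors=k, weights="uniform").fit_transform(z)
    filled = filled_z * sd + mean

    logged = [
        (env.sample_ids[i], env.variables[j])
        for i, j in np.argwhere(np.isnan(values))
    ]
    out = EnvironmentalMatrix(list(env.sample_ids), list(env.variables), filled)
    return out, logged


def env_distance(env: EnvironmentalMatrix) -> DistanceMatrix:
    """Euclidean distance over centred-and-scaled variables.

    Each variable is z-scored with the n-1 standard deviation; a
    zero-variance variable (which screening should have removed) is an
    error, as is any remaining missing value.
    """
    values = env.values
    if np.isnan(values).any():
        raise ValueError("environmental matrix still has missing values")
    sd = values.std(axis=0, ddof=1)
    zero = [v for v, s in zip(env.variables, sd) if s == 0]
    if zero:
        raise ValueError(f"zero-variance variables: {zero}")
    z = (values - values.mean(axis=0)) / sd
    return DistanceMatrix(squareform(pdist(z, metric="euclidean")), ids=env.sample_ids)


@dataclass
class DecayRegression:
    """OLS fit of community similarity on environmental distance."""

    component: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_pairs: int


def distance_decay_regression(
    community_similarity: DistanceMatrix,
    env_dist: DistanceMatrix,
    component: str = "",
) -> DecayRegression:
    """Regress pairwise community similarity on environmental distance.

    Both matrices must carry the same ids; the n(n-1)/2 upper-triangle
    pairs are treated as independent observations (a Mantel-style
    permutation p is available separately via ``mantel_p``).
    """
    if set(community_similarity.ids) != set(env_dist.ids):
        raise ValueError("matrices do not share sample ids")
    if len(env_dist.ids) < 3:
        raise ValueError("need at least 3 samples")
    env_dist = env_dist.filter(community_similarity.ids)
    iu = np.triu_indices(len(env_dist.ids), k=1)
    y = community_similarity.data[iu]
    x = env_dist.data[iu]
    if np.ptp(x) == 0:
        raise ValueError("environmental distances are constant")
    fit = stats.linregress(x, y)
    return DecayRegression(
        component=component,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n_pairs=int(x.size),
    )


def mantel_p(
    community_similarity: DistanceMatrix,
    env_dist: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
) -> float:
    """Permutation (Mantel-style) p-value for the decay slope.

    Rows/columns of the environmental matrix are permuted jointly;
    the two-sided p uses the add-one convention.
    """
    env_dist = env_dist.filter(community_similarity.ids)
    n = len(env_dist.ids)
    iu = np.triu_indices(n, k=1)
    y = community_similarity.data[iu]
    x = env_dist.data[iu]
    obs = abs(stats.pearsonr(x, y).statistic)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        xp = env_dist.data[np.ix_(perm, perm)][iu]
        if abs(stats.pearsonr(xp, y).statistic) >= obs:
            hits += 1
    return (1 + hits) / (1 + n_perm)
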