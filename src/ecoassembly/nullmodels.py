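"""Bray-Curtis dissimilarity and the abundance-weighted Raup-Crick null.

For sample pairs where the phylogenetic stage finds no dominant
selection signal (|betaNTI| <= 2), compositional turnover is compared
against a stochastic null that probabilistically reassembles each
community while preserving its observed richness and total reads:

1. draw the observed number of taxa without replacement, with
   probability proportional to regional occupancy (the number of
   samples each taxon occurs in);
2. seed each drawn taxon with one read, then allocate the remaining
   reads with replacement proportional to regional relative abundance;
3. Bray-Curtis between the two null communities is one null value.

With ``n_lt`` null values below the observed Bray-Curtis and ``n_eq``
tied (within an absolute tolerance of 1e-12), the standardised metric

    RC_Bray = 2 * ((n_lt + 0.5 * n_eq) / reps) - 1

lies in [-1, 1]; RC_Bray > 0.95 indicates dispersal limitation and
RC_Bray < -0.95 homogenizing dispersal.

The regional pool must be built from the same (control-subtracted,
rarefied) table the observed comparisons use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import CountTable

__all__ = [
    "bray_curtis",
    "bray_curtis_matrix",
    "RegionalPool",
    "regional_pool",
    "rc_null_pair",
    "rc_bray",
    "rc_score",
    "RCResult",
]

#: Absolute tolerance for counting a null value as tied with the observed.
TIE_TOL = 1e-12


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Bray-Curtis dissimilarity: 1 - 2*sum(min(x,y)) / (sum x + sum y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must be aligned")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("abundances must be non-negative")
    sx, sy = x.sum(), y.sum()
    if sx <= 0 or sy <= 0:
        raise ValueError("zero-total abundance vector")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / (sx + sy))


def bray_curtis_matrix(table: CountTable) -> np.ndarray:
    """Dense samples x samples Bray-Curtis matrix."""
    n = table.n_samples
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = bray_curtis(table.counts[i], table.counts[j])
    return out


def bray_curtis_similarity(table: CountTable) -> np.ndarray:
    """Community similarity (1 - Bray-Curtis) with a zero diagonal.

    The zero diagonal lets the matrix ride in a distance-matrix
    container; only off-diagonal pairs are ever consumed.
    """
    sim = 1.0 - bray_curtis_matrix(table)
    np.fill_diagonal(sim, 0.0)
    return sim


@dataclass
class RegionalPool:
    """Occupancy and regional relative abundance of every taxon."""

    taxon_ids: list[str]
    occupancy: np.ndarray
    regional_relative_abundance: np.ndarray

    @property
    def size(self) -> int:
        """Number of taxa available to the null (nonzero occupancy)."""
        return int(np.count_nonzero(self.occupancy))


def regional_pool(table: CountTable) -> RegionalPool:
    """Build the regional species pool from a component's count table."""
    if table.n_samples == 0 or table.n_taxa == 0:
        raise ValueError("empty count table")
    occupancy = (table.counts > 0).sum(axis=0)
    totals = table.counts.sum(axis=0).astype(float)
    grand = totals.sum()
    rel = totals / grand if grand > 0 else totals
    return RegionalPool(list(table.taxon_ids), occupancy, rel)


def _null_community(
    pool: RegionalPool, richness: int, total: int, rng: np.random.Generator
) -> np.ndarray:
    """One probabilistically reassembled community (counts over pool taxa)."""
    occ = pool.occupancy.astype(float)
    candidates = np.flatnonzero(occ > 0)
    if richness > candidates.size:
        raise ValueError(
            f"richness {richness} exceeds regional pool size {candidates.size}"
        )
    if total < richness:
        raise ValueError("total reads below richness")
    # weighted draw without replacement via Gumbel top-k on log-occupancy
    keys = np.log(occ[candidates]) + rng.gumbel(size=candidates.size)
    drawn = candidates[np.argpartition(-keys, richness - 1)[:richness]]
    counts = np.zeros(len(pool.taxon_ids), dtype=np.int64)
    counts[drawn] = 1  # each drawn taxon seeded with one read
    remaining = total - richness
    if remaining > 0:
        probs = pool.regional_relative_abundance[drawn]
        probs = probs / probs.sum() if probs.sum() > 0 else np.full(richness, 1.0 / richness)
        counts[drawn] += rng.multinomial(remaining, probs)
    return counts


def rc_null_pair(
    pool: RegionalPool,
    richness_a: int,
    abund_total_a: int,
    richness_b: int,
    abund_total_b: int,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> float:
    """One null Bray-Curtis value for a pair's observed richness/totals."""
    if rng is None:
        rng = np.random.default_rng(seed)
    x = _null_community(pool, richness_a, abund_total_a, rng)
    y = _null_community(pool, richness_b, abund_total_b, rng)
    return bray_curtis(x, y)


def rc_score(observed: float, null_values: np.ndarray) -> float:
    """Standardise an observed Bray-Curtis against null values to [-1, 1].

    Counts nulls below the observed value, with ties (within
    :data:`TIE_TOL`) contributing one half each.
    """
    null_values = np.asarray(null_values, dtype=float)
    reps = null_values.size
    if reps < 1:
        raise ValueError("need at least one null value")
    n_lt = int(np.sum(null_values < observed - TIE_TOL))
    n_eq = int(np.sum(np.abs(null_values - observed) <= TIE_TOL))
    return float(2.0 * ((n_lt + 0.5 * n_eq) / reps) - 1.0)


@dataclass
class RCResult:
    """Observed Bray-Curtis and its Raup-Crick standardisation."""

    sample_a: str
    sample_b: str
    bray_observed: float
    rc_bray: float


def rc_bray(
    abund_a: np.ndarray,
    abund_b: np.ndarray,
    pool: RegionalPool,
    reps: int = 999,
    seed: int = 0,
    rng: np.random.Generator | None = None,
    sample_a: str = "a",
    sample_b: str = "b",
) -> RCResult:
    """Abundance-weighted Raup-Crick metric for one sample pair."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    abund_a = np.asarray(abund_a)
    abund_b = np.asarray(abund_b)
    observed = bray_curtis(abund_a, abund_b)
    if rng is None:
        rng = np.random.default_rng(seed)
    ra, ta = int(np.count_nonzero(abund_a)), int(abund_a.sum())
    rb, tb = int(np.count_nonzero(abund_b)), int(abund_b.sum())
    nulls = np.empty(reps)
    for r in range(reps):
        nulls[r] = rc_null_pair(pool, ra, ta, rb, tb, rng=rng)
    return RCResult(sample_a, sample_b, observed, rc_score(observed, nulls))
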