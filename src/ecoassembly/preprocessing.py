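"""Negative-control subtraction, rarefaction and alpha diversity.

These steps standardise an ASV count table before any between-sample
comparison: reads attributable to laboratory contamination are removed
by subtracting, per taxon, the total observed across negative-control
samples; sampling effort is equalised by rarefying every sample to a
common depth (sampling without replacement, i.e. a multivariate
hypergeometric draw); richness is summarised as observed ASVs and
bias-corrected Chao1.

Subsampling depths used for the five lake datasets this pipeline was
built around ship as :data:`DEPTH_PRESETS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .containers import CountTable

__all__ = [
    "subtract_controls",
    "rarefy",
    "rarefaction_curve",
    "alpha_diversity",
    "AlphaDiversity",
    "PreprocessReport",
    "DEPTH_PRESETS",
]

#: Even subsampling depths (reads) per biotic component.
DEPTH_PRESETS = {
    "SSbact": 24134,
    "SSeuks": 23188,
    "SPeuks": 11710,
    "LPeuks": 25297,
    "Pbact": 51362,
}


@dataclass
class PreprocessReport:
    """Side record of what a preprocessing step removed or zeroed."""

    dropped_samples: list[str] = field(default_factory=list)
    zeroed_taxa: list[str] = field(default_factory=list)


@dataclass
class AlphaDiversity:
    """Observed richness and bias-corrected Chao1 for one sample."""

    sample_id: str
    observed_asvs: int
    chao1: float


def subtract_controls(
    table: CountTable, control_ids: Sequence[str]
) -> tuple[CountTable, PreprocessReport]:
    """Subtract negative-control reads from every sample, flooring at zero.

    For each taxon the total of its reads across *all* control samples
    is subtracted from every non-control sample.  Control rows are
    removed from the output.  Taxa driven to all-zero columns are kept
    (so downstream taxon sets stay aligned) but flagged in the report.
    """
    control_ids = list(control_ids)
    missing = [c for c in control_ids if c not in table.sample_ids]
    if missing:
        raise ValueError(f"control ids not found in table: {missing}")
    keep = [s for s in table.sample_ids if s not in set(control_ids)]
    if not keep:
        raise ValueError("no non-control samples remain")

    ctrl_idx = [table.sample_index(c) for c in control_ids]
    ctrl_total = table.counts[ctrl_idx].sum(axis=0)
    kept = table.select_samples(keep)
    adjusted = np.maximum(kept.counts - ctrl_total[None, :], 0)

    was_present = kept.counts.sum(axis=0) > 0
    now_zero = adjusted.sum(axis=0) == 0
    zeroed = [t for t, w, z in zip(table.taxon_ids, was_present, now_zero) if w and z]
    out = CountTable(keep, list(table.taxon_ids), adjusted)
    return out, PreprocessReport(zeroed_taxa=zeroed)


def _subsample_row(row: np.ndarray, depth: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``depth`` reads without replacement from one sample's reads."""
    return rng.multivariate_hypergeometric(row, depth)


def rarefy(
    table: CountTable, depth: int, seed: int
) -> tuple[CountTable, PreprocessReport]:
    """Rarefy every sample to an even depth, without replacement.

    Samples whose total is below ``depth`` are dropped and listed in
    the report; a sample whose total equals ``depth`` is returned
    unchanged.  Deterministic for a given seed.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    totals = table.counts.sum(axis=1)
    keep_mask = totals >= depth
    if not keep_mask.any():
        raise ValueError(f"all samples fall below rarefaction depth {depth}")
    rng = np.random.default_rng(seed)
    rows = []
    kept_ids = []
    dropped = []
    for sid, row, total, ok in zip(table.sample_ids, table.counts, totals, keep_mask):
        if not ok:
            dropped.append(sid)
            continue
        kept_ids.append(sid)
        rows.append(row if total == depth else _subsample_row(row, depth, rng))
    out = CountTable(kept_ids, list(table.taxon_ids), np.array(rows))
    return out, PreprocessReport(dropped_samples=dropped)


def rarefaction_curve(
    table: CountTable,
    depths: Sequence[int],
    reps: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean (+/- sd over reps) observed ASVs per sample at each depth.

    Depths above a sample's total are reported as NaN.  Returns a tidy
    frame with columns sample_id, depth, mean_observed, sd_observed.
    """
    depths = list(depths)
    if any(b <= a for a, b in zip(depths, depths[1:])):
        raise ValueError("depths must be strictly increasing")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    for sid, row in zip(table.sample_ids, table.counts):
        total = int(row.sum())
        for depth in depths:
            if depth > total:
                records.append((sid, depth, np.nan, np.nan))
                continue
            obs = np.empty(reps)
            for r in range(reps):
                sub = row if depth == total else _subsample_row(row, depth, rng)
                obs[r] = np.count_nonzero(sub)
            records.append((sid, depth, obs.mean(), obs.std(ddof=1) if reps > 1 else 0.0))
    return pd.DataFrame(
        records, columns=["sample_id", "depth", "mean_observed", "sd_observed"]
    )


def chao1(abundances: Iterable[int]) -> float:
    """Bias-corrected Chao1: S_obs + F1*(F1-1) / (2*(F2+1))."""
    a = np.asarray(list(abundances))
    s_obs = int(np.count_nonzero(a))
    f1 = int(np.sum(a == 1))
    f2 = int(np.sum(a == 2))
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def alpha_diversity(table: CountTable) -> list[AlphaDiversity]:
    """Observed ASV richness and bias-corrected Chao1 per sample."""
    if table.n_samples == 0:
        raise ValueError("empty count table")
    out = []
    for sid, row in zip(table.sample_ids, table.counts):
        out.append(
            AlphaDiversity(
                sample_id=sid,
                observed_asvs=int(np.count_nonzero(row)),
                chao1=chao1(row),
            )
        )
    return out
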