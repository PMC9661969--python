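"""Two-stage classification of sample pairs into assembly processes.

Stage 1 (phylogenetic): betaNTI > 2 -> variable selection;
betaNTI < -2 -> homogeneous selection.  Stage 2 (compositional), for
pairs the phylogenetic stage leaves unresolved: RC_Bray > 0.95 ->
dispersal limitation; RC_Bray < -0.95 -> homogenizing dispersal;
otherwise no dominant process.  All inequalities are strict, so the
boundary values fall to the "else" side.

Pairs whose betaMNTD null distribution is degenerate (zero standard
deviation, betaNTI undefined) are sent to the compositional stage and
flagged in the run report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import dendropy

from .containers import CountTable, PairwiseResult, ProcessSummary, PROCESSES
from .io import align_table_and_tree
from .nullmodels import bray_curtis, rc_bray, regional_pool
from .phylo import bmntd, bmntd_null, bnti, cophenetic_distances, pair_rng

__all__ = [
    "classify_pair",
    "summarize_processes",
    "run_assembly_pipeline",
    "AssemblyConfig",
    "AssemblyReport",
    "BNTI_THRESHOLD",
    "RC_THRESHOLD",
]

BNTI_THRESHOLD = 2.0
RC_THRESHOLD = 0.95


def classify_pair(bnti_value: float, rc_bray_value: float | None) -> str:
    """Assign one of the five assembly-process labels to a pair.

    ``rc_bray_value`` must be provided when |betaNTI| <= 2 (or betaNTI
    is undefined); it is ignored otherwise.
    """
    if not math.isnan(bnti_value):
        if bnti_value > BNTI_THRESHOLD:
            return "variable_selection"
        if bnti_value < -BNTI_THRESHOLD:
            return "homogeneous_selection"
    if rc_bray_value is None:
        raise ValueError(
            "rc_bray is required when |betaNTI| <= 2 (or betaNTI is undefined)"
        )
    if rc_bray_value > RC_THRESHOLD:
        return "dispersal_limitation"
    if rc_bray_value < -RC_THRESHOLD:
        return "homogenizing_dispersal"
    return "no_dominant_process"


def summarize_processes(
    results: list[PairwiseResult], component: str = ""
) -> ProcessSummary:
    """Percentage of pairs per process, to one decimal place."""
    if not results:
        raise ValueError("no pairwise results to summarise")
    n = len(results)
    pct = {}
    for proc in PROCESSES:
        count = sum(1 for r in results if r.process == proc)
        pct[proc] = round(100.0 * count / n, 1)
    return ProcessSummary(component=component, n_pairs=n, percentages=pct)


@dataclass
class AssemblyConfig:
    """Knobs of the two-stage assembly run.

    reps: null-model repetitions for both stages (999 by default).
    weighted: abundance-weighted betaMNTD (the default) vs unweighted.
    rc_all_pairs: compute RC_Bray for every pair rather than only the
        |betaNTI| <= 2 subset (the classifier only consumes the subset).
    """

    reps: int = 999
    seed: int = 0
    weighted: bool = True
    rc_all_pairs: bool = False


@dataclass
class AssemblyReport:
    """Pairs flagged during a run (currently: degenerate betaMNTD nulls)."""

    degenerate_null_pairs: list[tuple[str, str]] = field(default_factory=list)


def run_assembly_pipeline(
    table: CountTable,
    tree: dendropy.Tree,
    config: AssemblyConfig | None = None,
    component: str = "",
) -> tuple[list[PairwiseResult], ProcessSummary, AssemblyReport]:
    """Classify every unordered sample pair of a component.

    The table and tree are aligned (intersection policy), the
    cophenetic matrix is computed once, and for each pair the observed
    betaMNTD, its null, betaNTI and (when needed) RC_Bray feed the
    classifier.  Per-pair random streams are keyed by (seed, pair
    index) so output is independent of evaluation order.
    """
    if config is None:
        config = AssemblyConfig()
    table, tree, _ = align_table_and_tree(table, tree, policy="intersect")
    dists = cophenetic_distances(tree)
    # align distance-matrix taxon order to the table's columns
    d = dists.filter(table.taxon_ids).data
    pool = regional_pool(table)

    results: list[PairwiseResult] = []
    report = AssemblyReport()
    for pair_index, (i, j) in enumerate(combinations(range(table.n_samples), 2)):
        sa, sb = table.sample_ids[i], table.sample_ids[j]
        xa, xb = table.counts[i], table.counts[j]
        rng = pair_rng(config.seed, pair_index)
        obs = bmntd(xa, xb, d, weighted=config.weighted)
        nulls = bmntd_null(xa, xb, d, reps=config.reps, weighted=config.weighted, rng=rng)
        z = bnti(obs, nulls)
        if math.isnan(z):
            report.degenerate_null_pairs.append((sa, sb))
        bc = bray_curtis(xa, xb)
        needs_rc = math.isnan(z) or abs(z) <= BNTI_THRESHOLD
        rc_value: float | None = None
        if needs_rc or config.rc_all_pairs:
            rc_value = rc_bray(
                xa, xb, pool, reps=config.reps, rng=rng, sample_a=sa, sample_b=sb
            ).rc_bray
        process = classify_pair(z, rc_value if needs_rc else None)
        results.append(
            PairwiseResult(
                sample_a=sa,
                sample_b=sb,
                bmntd=obs,
                bnti=z,
                bray_curtis=bc,
                rc_bray=rc_value,
                process=process,
            )
        )
    summary = summarize_processes(results, component=component)
    return results, summary, report
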