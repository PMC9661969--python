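"""Synthetic metacommunities with known assembly-process ground truth.

The generator produces everything the pipeline consumes — a phylogeny,
niche traits with phylogenetic signal, site environments and community
count tables — under five regimes:

variable_selection
    Sites are spread along an environmental gradient (anchored to the
    quantiles of the realised trait distribution so every site's niche
    is populated) and a Gaussian niche filter of width ``filter_width``
    selects taxa whose trait matches the local environment; sites far
    apart on the gradient are filtered toward different clades.
homogeneous_selection
    Every site shares one environment value (the median niche).  Within
    the selected envelope, very close relatives are treated as
    ecologically equivalent competitors: the envelope is partitioned
    into sibling pairs by phylogenetic proximity and each site
    stochastically retains one member per pair (limiting similarity /
    priority effects).  Sites therefore share the same narrow clade
    while constantly swapping close relatives — the signature
    homogeneous selection leaves in phylogenetic turnover.
dispersal_limitation
    No filtering; each site draws from its own random quarter of the
    taxon pool with heavy-tailed (log-normal) abundances — isolated
    drift.
homogenizing_dispersal
    Every site draws multinomially from one shared regional log-normal
    abundance vector (mass effects, mixing rate 1).
neutral
    A convex blend of the shared regional vector and a site-specific
    drifted copy of it (multiplicative log-normal jitter), mixing rate
    0.5 by default, with no filtering.

Trees are pure-birth (Yule) with total depth scaled to 1.  Niche
traits evolve by Brownian motion whose rate decays toward the present
(an early-burst model, ``signal_decay``); this concentrates trait
divergence at deep splits so that trait-similar taxa form clades — the
strong niche conservatism the betaNTI framework assumes.
``signal_decay = 0`` recovers rate-constant Brownian motion.

All randomness flows from the scenario seed through named substreams
(tree, traits, assembly) so each stage can be regenerated on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .containers import CountTable

__all__ = [
    "ScenarioSpec",
    "Scenario",
    "REGIMES",
    "simulate_tree",
    "evolve_trait",
    "assemble_communities",
    "ground_truth_labels",
    "simulate_scenario",
]

REGIMES = (
    "variable_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "neutral",
)

_SUBSTREAMS = {"tree": 11, "traits": 23, "assembly": 37}

#: Default early-burst rate-decay constant for trait evolution.
DEFAULT_SIGNAL_DECAY = 5.0

#: Maximum cophenetic distance for two envelope taxa to count as an
#: ecologically equivalent sibling pair (tree depth units).
SIBLING_DISTANCE_MAX = 0.6


def _substream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _SUBSTREAMS[name]]))


@dataclass
class ScenarioSpec:
    """Configuration of one simulated metacommunity.

    Parameters with units:

    trait_sigma : Brownian rate of the niche trait (trait units per
        unit branch length; the tree has depth 1).
    signal_decay : early-burst exponent; the Brownian rate at depth t
        is ``trait_sigma^2 * exp(-signal_decay * t)``.
    filter_width : Gaussian niche breadth in trait units; None means
        0.2 times the realised trait standard deviation.
    env_range : span of the selection gradient in trait units; None
        anchors the 15 sites to trait quantiles 0.02..0.98 instead,
        which keeps every site's envelope populated.
    mixing_rate : regional weight m of the neutral blend.
    drift_sigma : log-normal sd of isolated-drift pool abundances.
    regional_sigma : log-normal sd of the shared regional abundance
        vector (mass effects / neutral); larger values give sparser,
        more dominance-structured pools.
    neutral_jitter : log-normal sd of the per-site multiplicative
        perturbation of the regional vector under the neutral regime.
    selection_noise : log-normal sd of per-site abundance noise inside
        the selection regimes' niche envelopes.
    """

    regime: str = "neutral"
    n_taxa: int = 100
    n_sites: int = 15
    reads_per_site: int = 2000
    trait_sigma: float = 1.0
    signal_decay: float = DEFAULT_SIGNAL_DECAY
    filter_width: float | None = None
    env_range: float | None = None
    mixing_rate: float = 0.5
    drift_sigma: float = 1.5
    regional_sigma: float = 2.0
    neutral_jitter: float = 0.75
    selection_noise: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.n_taxa < 2 or self.n_sites < 2:
            raise ValueError("need at least 2 taxa and 2 sites")
        if not 0.0 <= self.mixing_rate <= 1.0:
            raise ValueError("mixing_rate must be in [0, 1]")
        if self.filter_width is not None and self.filter_width <= 0:
            raise ValueError("filter_width must be positive")


def simulate_tree(n_taxa: int, seed: int = 0) -> dendropy.Tree:
    """Ultrametric pure-birth (Yule) tree with depth scaled to 1.

    Tip labels are ``t1 .. tn``.  A uniformly chosen lineage splits
    after an exponential wait with rate equal to the number of extant
    lineages (per-lineage birth rate 1); branch lengths are then
    rescaled so the shared root-to-tip depth is exactly 1.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    rng = _substream(seed, "tree")
    tree = dendropy.Tree()
    active = [
        tree.seed_node.new_child(edge_length=0.0),
        tree.seed_node.new_child(edge_length=0.0),
    ]
    while len(active) < n_taxa:
        wait = rng.exponential(1.0 / len(active))
        for node in active:
            node.edge.length += wait
        parent = active.pop(rng.integers(len(active)))
        active.append(parent.new_child(edge_length=0.0))
        active.append(parent.new_child(edge_length=0.0))
    final = rng.exponential(1.0 / len(active))
    for node in active:
        node.edge.length += final

    depth = 0.0
    node = active[0]
    while node.parent_node is not None:
        depth += node.edge.length
        node = node.parent_node
    if depth > 0:
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length /= depth

    namespace = tree.taxon_namespace
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = namespace.new_taxon(label=f"t{i}")
    return tree


def evolve_trait(
    tree: dendropy.Tree,
    trait_sigma: float = 1.0,
    seed: int = 0,
    signal_decay: float = DEFAULT_SIGNAL_DECAY,
) -> dict[str, float]:
    """Niche trait from root value 0 under (early-burst) Brownian motion.

    With ``signal_decay = 0`` this is rate-constant Brownian motion:
    the change along a branch of length b is Normal(0, sigma^2 * b).
    With positive decay the instantaneous rate at depth t is
    ``sigma^2 * exp(-decay * t)``, so divergence concentrates at deep
    branches and close relatives keep very similar niches.
    """
    rng = _substream(seed, "traits")
    value = {tree.seed_node: 0.0}
    depth = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        b = node.edge.length or 0.0
        t0 = depth[node.parent_node]
        t1 = t0 + b
        depth[node] = t1
        if b <= 0:
            value[node] = value[node.parent_node]
            continue
        if signal_decay > 0:
            var = (
                trait_sigma**2
                * (np.exp(-signal_decay * t0) - np.exp(-signal_decay * t1))
                / signal_decay
            )
        else:
            var = trait_sigma**2 * b
        value[node] = value[node.parent_node] + np.sqrt(var) * rng.standard_normal()
    return {leaf.taxon.label: value[leaf] for leaf in tree.leaf_node_iter()}


def _tip_distance_matrix(tree: dendropy.Tree, taxa: list[str]) -> np.ndarray:
    from .phylo import cophenetic_distances

    return cophenetic_distances(tree).filter(taxa).data


def _sibling_pairs(d: np.ndarray, idx: np.ndarray, dmax: float) -> list[tuple[int, int]]:
    """Greedy partition of envelope taxa into closest-relative pairs."""
    sub = d[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    order = np.dstack(np.unravel_index(np.argsort(sub, axis=None), sub.shape))[0]
    unused = set(range(idx.size))
    pairs = []
    for i, j in order:
        if i in unused and j in unused and sub[i, j] <= dmax:
            pairs.append((int(idx[i]), int(idx[j])))
            unused -= {int(i), int(j)}
    return pairs


def _site_environments(
    spec: ScenarioSpec, trait_vec: np.ndarray
) -> np.ndarray:
    if spec.regime == "variable_selection":
        if spec.env_range is not None:
            return np.linspace(-spec.env_range / 2, spec.env_range / 2, spec.n_sites)
        return np.quantile(trait_vec, np.linspace(0.02, 0.98, spec.n_sites))
    if spec.regime == "homogeneous_selection":
        return np.full(spec.n_sites, float(np.quantile(trait_vec, 0.5)))
    return np.full(spec.n_sites, np.nan)  # non-filtering regimes


def assemble_communities(
    spec: ScenarioSpec,
    tree: dendropy.Tree,
    traits: dict[str, float],
) -> tuple[CountTable, np.ndarray]:
    """Draw site communities under the scenario's regime.

    Returns the count table (sites x taxa, every row summing exactly
    to ``reads_per_site``) and the per-site environment values (NaN
    for regimes without environmental filtering).
    """
    taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    missing = [t for t in taxa if t not in traits]
    if missing:
        raise ValueError(f"traits missing for taxa: {missing[:5]}")
    trait_vec = np.array([traits[t] for t in taxa])
    trait_sd = float(trait_vec.std(ddof=1))
    rng = _substream(spec.seed, "assembly")
    envs = _site_environments(spec, trait_vec)

    n, s = spec.n_taxa, spec.n_sites
    weights = np.empty((s, n))
    if spec.regime in ("variable_selection", "homogeneous_selection"):
        sigma_f = (
            spec.filter_width if spec.filter_width is not None else 0.2 * trait_sd
        )
        if sigma_f <= 0:
            raise ValueError("filter_width must be positive for filtering regimes")
        if spec.regime == "variable_selection":
            for i, e in enumerate(envs):
                kernel = np.exp(-((trait_vec - e) ** 2) / (2.0 * sigma_f**2))
                weights[i] = kernel
        else:
            # one shared niche; limiting similarity among the envelope's
            # closest relatives drives fine-scale turnover between sites
            kernel = np.exp(-((trait_vec - envs[0]) ** 2) / (2.0 * sigma_f**2))
            d = _tip_distance_matrix(tree, taxa)
            env_size = max(4, int(round(0.4 * n)))
            envelope = np.argsort(-kernel)[:env_size]
            pairs = _sibling_pairs(d, envelope, SIBLING_DISTANCE_MAX)
            for i in range(s):
                w = np.zeros(n)
                for a, b in pairs:
                    pick = a if rng.random() < 0.5 else b
                    w[pick] = kernel[pick]
                w *= rng.lognormal(0.0, spec.selection_noise, size=n)
                if np.count_nonzero(w) < 2:
                    w = np.zeros(n)
                    w[envelope] = kernel[envelope]
                weights[i] = w
    elif spec.regime == "dispersal_limitation":
        pool_size = max(2, n // 4)
        weights[:] = 0.0
        for i in range(s):
            pool = rng.choice(n, size=pool_size, replace=False)
            weights[i, pool] = rng.lognormal(0.0, spec.drift_sigma, size=pool_size)
    elif spec.regime == "homogenizing_dispersal":
        regional = rng.lognormal(0.0, spec.regional_sigma, size=n)
        weights[:] = regional[None, :]
    else:  # neutral: regional pool with per-site multiplicative drift
        regional = rng.lognormal(0.0, spec.regional_sigma, size=n)
        regional = regional / regional.sum()
        m = spec.mixing_rate
        for i in range(s):
            drifted = regional * rng.lognormal(0.0, spec.neutral_jitter, size=n)
            drifted = drifted / drifted.sum()
            weights[i] = m * regional + (1.0 - m) * drifted

    counts = np.empty((s, n), dtype=np.int64)
    for i in range(s):
        probs = weights[i] / weights[i].sum()
        counts[i] = rng.multinomial(spec.reads_per_site, probs)
    site_ids = [f"site{i + 1}" for i in range(s)]
    return CountTable(site_ids, taxa, counts), envs


def ground_truth_labels(
    spec: ScenarioSpec, envs: np.ndarray, trait_sd: float = 1.0
) -> dict[tuple[int, int], str]:
    """Expected modal process label per site pair under the regime.

    For variable selection, pairs whose environments differ by more
    than the niche breadth are expected to diverge (variable
    selection) while near-equal-environment pairs should converge
    (homogeneous selection); the other regimes imply one label for
    every pair.
    """
    fixed = {
        "homogeneous_selection": "homogeneous_selection",
        "dispersal_limitation": "dispersal_limitation",
        "homogenizing_dispersal": "homogenizing_dispersal",
        "neutral": "no_dominant_process",
    }
    sigma_f = spec.filter_width if spec.filter_width is not None else 0.2 * trait_sd
    out = {}
    for i in range(spec.n_sites):
        for j in range(i + 1, spec.n_sites):
            if spec.regime == "variable_selection":
                out[(i, j)] = (
                    "variable_selection"
                    if abs(envs[i] - envs[j]) > sigma_f
                    else "homogeneous_selection"
                )
            else:
                out[(i, j)] = fixed[spec.regime]
    return out


@dataclass
class Scenario:
    """One fully realised synthetic metacommunity."""

    spec: ScenarioSpec
    tree: dendropy.Tree
    traits: dict[str, float]
    table: CountTable
    environments: np.ndarray
    truth: dict[tuple[int, int], str] = field(default_factory=dict)


def simulate_scenario(spec: ScenarioSpec) -> Scenario:
    """Tree + traits + communities + ground truth from one seed."""
    tree = simulate_tree(spec.n_taxa, seed=spec.seed)
    traits = evolve_trait(
        tree, spec.trait_sigma, seed=spec.seed, signal_decay=spec.signal_decay
    )
    table, envs = assemble_communities(spec, tree, traits)
    trait_sd = float(np.std(list(traits.values()), ddof=1))
    truth = ground_truth_labels(spec, envs, trait_sd)
    return Scenario(spec, tree, traits, table, envs, truth)
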