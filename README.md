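# ecoassembly

Null-model partitioning of community assembly processes for
metabarcoding count tables, with a synthetic metacommunity generator
that provides known ground truth.

## The problem

Microbial and eukaryotic communities in lakes (and other discrete
habitats) are shaped by a mixture of deterministic processes —
selection by the local environment acting on fitness differences —
and stochastic ones — dispersal and ecological drift.  A widely used
framework classifies every *pair* of communities into one of five
processes using two nested null models:

1. **Phylogenetic stage.**  The between-community mean nearest taxon
   distance (βMNTD) measures how phylogenetically distant each taxon
   is from its closest relative in the other community, weighted by
   relative abundance.  Its z-score against a null that shuffles
   taxon labels across the phylogeny tips is the β nearest taxon
   index (βNTI):
   - βNTI > 2 → **variable selection** (communities pushed apart by
     differing environments),
   - βNTI < −2 → **homogeneous selection** (communities held together
     by a shared environment).
2. **Compositional stage**, for pairs with |βNTI| ≤ 2.  The observed
   Bray–Curtis dissimilarity is compared with an abundance-weighted
   Raup–Crick null that reassembles each community preserving its
   richness and read total (taxa drawn by regional occupancy, reads
   allocated by regional relative abundance), standardised to
   RC_Bray ∈ [−1, 1]:
   - RC_Bray > 0.95 → **dispersal limitation** (+ drift),
   - RC_Bray < −0.95 → **homogenizing dispersal**,
   - otherwise → **no dominant process**.

The package implements this two-stage classifier plus everything a
study needs around it: count-table/tree/metadata IO, negative-control
subtraction, rarefaction and alpha diversity (observed ASVs, Chao1),
environmental variable screening and imputation, distance-decay
regression of community similarity on environmental distance,
PERMANOVA / Kruskal–Wallis / Dunn group comparisons with
Benjamini–Hochberg adjustment, and geographic (haversine) distances.
A simulator generates metacommunities under each of the five regimes
so the whole pipeline can be validated against known ground truth —
see `docs/methods.md` for the model and its assumptions.

## Worked example

```python
from ecoassembly import ScenarioSpec, simulate_scenario
from ecoassembly.partition import AssemblyConfig, run_assembly_pipeline

# a metacommunity assembled by environmental filtering along a gradient
scenario = simulate_scenario(ScenarioSpec(regime="variable_selection", seed=1))
results, summary, report = run_assembly_pipeline(
    scenario.table, scenario.tree, AssemblyConfig(reps=999, seed=1)
)
print(summary.n_pairs, summary.percentages)
```

prints

```
105 {'variable_selection': 65.7, 'homogeneous_selection': 0.0,
     'dispersal_limitation': 14.3, 'homogenizing_dispersal': 11.4,
     'no_dominant_process': 8.6}
```

— of the 105 site pairs, 65.7% are classified as variable selection,
correctly identifying the generating regime as the dominant process;
the remainder mostly falls to the stochastic labels for neighbouring
sites whose environments (and therefore communities) are similar.
Each `results` entry carries the pair's βMNTD, βNTI, Bray–Curtis,
RC_Bray (where computed) and label, and `write_pairwise_results`
saves them as TSV.

The numbered drivers under `analysis/` run the full study arc on
simulated data and write tables under `results/`:

```bash
python analysis/00_preprocessing.py       # controls, rarefaction, alpha diversity
python analysis/01_simulate_scenarios.py  # one metacommunity per regime
python analysis/02_assembly_partition.py  # the five-process classification
python analysis/03_distance_decay.py      # similarity vs environmental distance
python analysis/04_group_comparisons.py   # PERMANOVA / KW / Dunn by access class
```

A thin CLI mirrors the same steps (`ecoassembly simulate|preprocess|
assembly|decay|groups`).

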