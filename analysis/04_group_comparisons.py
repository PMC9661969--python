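"""Group comparisons: PERMANOVA by access class and geographic tests.

For each scenario: (1) one-way PERMANOVA of the Bray-Curtis distance
matrix against the simulated human-access class, with BH-adjusted
pairwise comparisons; (2) Kruskal-Wallis comparison of the dominant
taxon's relative abundance across access classes with a Dunn post-hoc;
(3) under the dispersal regimes, a comparison of inter-site geographic
distances between pairs labelled homogenizing dispersal and those
labelled dispersal limitation.  Results land under results/groups/.
"""

import json
import os
import sys

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from ecoassembly import REGIMES, SampleMetadata
from ecoassembly.groupstats import (
    dunn_test,
    geographic_distances,
    kruskal_wallis,
    pairwise_permanova,
    permanova,
)
from ecoassembly.io import read_count_table, read_pairwise_results
from ecoassembly.nullmodels import bray_curtis_matrix

BASE = os.path.join(os.path.dirname(__file__), "..", "results")
SEED = 1


def main() -> None:
    os.makedirs(os.path.join(BASE, "groups"), exist_ok=True)
    summary = {}
    for regime in REGIMES:
        scen_dir = os.path.join(BASE, "scenarios", regime)
        table = read_count_table(os.path.join(scen_dir, "counts.tsv"))
        sites = pd.read_csv(os.path.join(scen_dir, "sites.csv"))
        groups = list(sites["access_class"])
        dist = DistanceMatrix(bray_curtis_matrix(table), ids=table.sample_ids)

        res = permanova(dist, groups, n_perm=999, seed=SEED)
        pw = pairwise_permanova(dist, groups, n_perm=999, seed=SEED)
        pw.to_csv(
            os.path.join(BASE, "groups", f"{regime}_pairwise_permanova.tsv"),
            sep="\t",
            index=False,
        )

        # dominant taxon's relative abundance across access classes
        rel = table.relative_abundance()
        dominant = int(np.argmax(rel.mean(axis=0)))
        kw = kruskal_wallis(rel[:, dominant], groups)
        dunn = dunn_test(rel[:, dominant], groups)
        dunn.to_csv(
            os.path.join(BASE, "groups", f"{regime}_dunn.tsv"), sep="\t", index=False
        )

        entry = {
            "permanova_F": res.pseudo_F,
            "permanova_r2": res.r_squared,
            "permanova_p": res.p_value,
            "dominant_taxon": table.taxon_ids[dominant],
            "kruskal_wallis_chi2": kw.statistic,
            "kruskal_wallis_p": kw.p_value,
        }

        # geographic distances of HD- vs DL-labelled pairs
        pairs = read_pairwise_results(
            os.path.join(BASE, "assembly", f"{regime}_pairs.tsv")
        )
        meta = [
            SampleMetadata(
                str(r.sample_id), float(r.latitude), float(r.longitude),
                str(r.access_class),
            )
            for r in sites.itertuples()
        ]
        geo = geographic_distances(meta)
        dists, labels = [], []
        for p in pairs:
            if p.process in ("homogenizing_dispersal", "dispersal_limitation"):
                dists.append(geo[p.sample_a, p.sample_b])
                labels.append(p.process)
        if len(set(labels)) == 2:
            kw_geo = kruskal_wallis(dists, labels)
            entry["geo_kruskal_wallis_chi2"] = kw_geo.statistic
            entry["geo_kruskal_wallis_p"] = kw_geo.p_value
        summary[regime] = entry
        print(
            f"{regime}: PERMANOVA F={res.pseudo_F:.2f} p={res.p_value:.3f}; "
            f"KW chi2={kw.statistic:.2f} p={kw.p_value:.3f}"
        )
    with open(os.path.join(BASE, "groups", "group_tests.json"), "w") as fh:
        json.dump(summary, fh, indent=2)


if __name__ == "__main__":
    sys.exit(main())
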