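#!/usr/bin/env python
"""Group per-conformation sites into consensus sites with persistence.

Sites from all dominant conformations are grouped by connected components
at a 5 Å neighbor distance (density clustering with minimum group size 1);
each group's persistence is the summed simulation percentage of the
conformations in which it was found.  Residues within 5 Å of each group
center are annotated from the highest-fraction member's representative.
On the shipped fixture the always-open cavity persists for 100% of the
simulation and the gated cavity for the first regime's share (~50%).
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from vasite.clustering import ConformationCluster
from vasite.consensus import build_consensus
from vasite.pockets import SitePrediction
from vasite.structure_io import read_structure


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cluster-table", type=Path,
                        default=Path("results/clustering/cluster_table.tsv"))
    parser.add_argument("--representatives", type=Path,
                        default=Path("results/clustering/representatives.pdb"))
    parser.add_argument("--sites", type=Path,
                        default=Path("results/pockets/sites_by_cluster.json"))
    parser.add_argument("--eps", type=float, default=5.0)
    parser.add_argument("--out", type=Path, default=Path("results/consensus"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    table = pd.read_csv(args.cluster_table, sep="\t")
    representatives = {c.frame_index: c for c in read_structure(args.representatives)}
    clusters = []
    for row in table.itertuples():
        cluster = ConformationCluster.from_members(
            int(row.cluster_id), set(range(int(row.n_members))))
        cluster.simulation_fraction = float(row.simulation_pct)
        cluster.rank = int(row.rank)
        cluster.representative = representatives[int(row.cluster_id)]
        clusters.append(cluster)

    raw = json.loads(args.sites.read_text())
    sites_by_cluster = {
        int(cid): [SitePrediction(center=np.array(s["center"]), score=s["score"],
                                  hydrophobic_fraction=s["hydrophobic_fraction"],
                                  source_conformation=int(cid))
                   for s in entries]
        for cid, entries in raw.items()
    }

    consensus = build_consensus(clusters, sites_by_cluster, eps=args.eps)
    rows = []
    for site in consensus:
        rows.append({
            "site_id": site.site_id,
            "persistence_pct": f"{site.persistence:.2f}",
            "x": f"{site.center[0]:.3f}", "y": f"{site.center[1]:.3f}",
            "z": f"{site.center[2]:.3f}",
            "n_conformations": len(site.member_conformations),
            "n_residues_within_5A": len(site.residues_within),
        })
        print(f"site {site.site_id}: persistence {site.persistence:.2f}% "
              f"({len(site.member_conformations)} of {len(clusters)} conformations), "
              f"{len(site.residues_within)} residues within 5 Å")
    pd.DataFrame(rows).to_csv(args.out / "consensus_sites.tsv", sep="\t", index=False)
    print(f"wrote {args.out}/consensus_sites.tsv")


if __name__ == "__main__":
    main()
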