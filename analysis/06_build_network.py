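"""Assemble the three-layered network and compute its topology.

Combines the significant processes, regulator cluster representatives
and linked physiological parameters into one gene-set overlap network
per timepoint (coefficient cutoff 0.5, relaxed to 0.3 for
physiology-process edges) and writes GraphML/SIF/TSV exports plus
topology statistics.  Prints the hubs by betweenness centrality.
"""

import argparse
from pathlib import Path

import pandas as pd

import trilayer as tl
from trilayer.io import export_network
from trilayer.pipeline import read_regulator_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--study", type=Path, default=Path("scratch/study"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    study = tl.read_study(args.study)
    for tp_dir in sorted(args.results.iterdir()):
        needed = ["de.tsv", "enrichment.tsv", "regulators.tsv",
                  "physiology_correlations.tsv"]
        if not all((tp_dir / n).exists() for n in needed):
            continue
        de = pd.read_csv(tp_dir / "de.tsv", sep="\t", index_col=0)
        classified = pd.read_csv(tp_dir / "enrichment.tsv", sep="\t")
        regs = read_regulator_table(tp_dir / "regulators.tsv")
        corr = pd.read_csv(tp_dir / "physiology_correlations.tsv", sep="\t")
        net = tl.build_network(
            tl.process_layer(classified, study.processes, de.index),
            tl.regulator_layer(regs),
            tl.physiology_layer(corr),
            tl.NetworkConfig(),
        )
        export_network(net, "graphml", tp_dir / "network.graphml")
        export_network(net, "sif", tp_dir / "network.sif")
        export_network(net, "tsv", tp_dir / "network_edges.tsv")
        topo, summary = tl.topology_stats(net)
        topo.to_csv(tp_dir / "topology.tsv", sep="\t", index=False)
        by_layer = {
            layer: sum(1 for _, d in net.nodes(data=True) if d["layer"] == layer)
            for layer in ("process", "regulator", "physiology")
        }
        print(f"{tp_dir.name}: {summary['n_nodes']} nodes {by_layer}, "
              f"{summary['n_edges']} edges, density {summary['density']:.3f}")
        for _, row in topo.head(3).iterrows():
            print(f"   hub: {row['node']} ({row['layer']}) "
                  f"betweenness={row['betweenness']:.1f} degree={row['degree']}")


if __name__ == "__main__":
    main()
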