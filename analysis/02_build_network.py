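#!/usr/bin/env python
"""Build the directed reaction-adjacency matrix from the input bundle.

Parses the reaction tables, excludes hub compounds (> 60 connections),
attaches localization labels, and exports the network (edge list + node
table + sparse matrix).
"""

import argparse
from pathlib import Path

from enzloc import (
    attach_localization,
    build_adjacency,
    load_id_list,
    load_reaction_tables,
    write_network,
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--inputs", type=Path, default=Path("results/synthetic_inputs"))
    ap.add_argument("--out", type=Path, default=Path("results/network"))
    ap.add_argument("--hub-threshold", type=int, default=60)
    args = ap.parse_args()

    records = load_reaction_tables(args.inputs / "reactions_irreversible.tsv",
                                   args.inputs / "reactions_reversible.tsv")
    localized_genes = load_id_list(args.inputs / "localized_genes.txt")
    net = build_adjacency(records, hub_threshold=args.hub_threshold)
    net = attach_localization(net, records, localized_genes)
    write_network(net, args.out, mtx=True)

    print(f"network: {net.n} reactions, {int(net.M.sum())} directed edges")
    print(f"  hub compounds excluded (> {args.hub_threshold} connections): "
          f"{sorted(net.excluded_compounds)}")
    print(f"  localized reactions: {int(net.localized.sum())} "
          f"of {net.n} ({net.localized.mean():.1%})")
    print(f"exported to {args.out} (edges.tsv, nodes.tsv, adjacency.mtx)")


if __name__ == "__main__":
    main()
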