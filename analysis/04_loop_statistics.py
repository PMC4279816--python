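#!/usr/bin/env python
"""Loop and feed-forward-loop statistics of the reaction network.

Computes per-node closed-walk counts [M^n]_ii (n = 2..7), the FFL measures
[M M^T M]_ii and [M M^T M M^T]_ii, and loop densities; contrasts localized
vs non-localized nodes with KS tests; and tests the mean loop-density
difference against the random-node-group null.
"""

import argparse
import json
from pathlib import Path

from enzloc import (
    group_loop_contrasts,
    load_network,
    loop_counts,
    loop_density,
    random_group_null,
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--network", type=Path, default=Path("results/network"))
    ap.add_argument("--out", type=Path, default=Path("results/loop_stats"))
    ap.add_argument("--n-draws", type=int, default=100000)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    net = load_network(args.network)
    profiles = loop_counts(net)
    profiles.to_csv(args.out / "loop_profiles.tsv", sep="\t")
    contrasts = group_loop_contrasts(profiles)
    contrasts.to_csv(args.out / "ks_contrasts.tsv", sep="\t", index=False)

    dens = loop_density(profiles)
    mask = dens["localized"].to_numpy(dtype=bool)
    nulls = {}
    for col in dens.columns:
        if col.startswith("density_"):
            ns = random_group_null(dens[col].to_numpy(), mask,
                                   n_draws=args.n_draws, seed=args.seed,
                                   statistic_name=col)
            nulls[col] = {"observed_diff": ns.observed, "z": ns.z, "p": ns.p,
                          "degenerate": ns.degenerate}
    (args.out / "density_null.json").write_text(json.dumps(nulls, indent=2))

    sig = contrasts[contrasts["ks_p"] < 0.05]["column"].tolist()
    print(f"{net.n} nodes; loop/FFL columns with KS p < 0.05 "
          f"(localized stochastically larger): {sig or 'none'}")
    best = min(nulls.items(), key=lambda kv: kv[1]["p"])
    print(f"strongest random-group density contrast: {best[0]} "
          f"z = {best[1]['z']:.2f}, p = {best[1]['p']:.4g}")
    print(f"tables written to {args.out}")


if __name__ == "__main__":
    main()
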