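# enzloc

Statistics of **enzyme localization in bacterial metabolic networks**: where
do enzymes that form punctate cytoplasmic foci sit within metabolic routes,
and how do the reactions they catalyze embed in the metabolic network?

The package is aimed at systems biologists who have (i) KEGG-style reaction
definitions, (ii) a list of localized genes (E. coli b-numbers), and
(iii) a table of Elementary Flux Patterns (EFPs) — ordered reaction routes
of length L through a metabolic subsystem — and want to test whether
localization follows positional and topological rules rather than being
scattered at random.

## What it computes

**Positional statistics in EFPs.** Each EFP of length L carries k localized
enzymes. The observed per-length ratios (first-or-last localized among EFPs
with k ≥ 1; first-and-last among EFPs with k ≥ 2) are tested against two
nulls:

* a *permutation null* — within every EFP its k flags are re-placed
  uniformly over the L positions, the ratio recomputed per draw, with a
  one-sided add-one-smoothed empirical p-value;
* a *closed-form null* — conditioned on k of L positions,
  P(first | k, L) = k/L and P(first ∧ last | k, L) = k(k−1)/(L(L−1)),
  averaged over the empirical distribution q(k;L):

  P(first ∨ last | L) = (2/L)·q(1;L) + Σ_{k≥2} [2k/L − k(k−1)/(L(L−1))]·q(k;L).

**Network topology.** A directed Boolean reaction-adjacency matrix M
(M_ij = 1 iff reaction i produces a compound reaction j consumes, hub
compounds with > 60 connections excluded) yields per-node statistics:

* feedback-loop counts [Mⁿ]_ii (closed walks, n = 2..7, exact integers),
  feed-forward measures [MMᵀM]_ii and [MMᵀMMᵀ]_ii, connection counts
  [MMᵀ]_ii, and loop densities, contrasted by KS tests and a random
  node-group null;
* within-group connectivity (directed edge probability inside a group),
  clustering coefficients and triangle composition on the symmetrized
  graph, and degree-preserving surrogate ensembles (directed double-edge
  swaps);
* Fisher-exact (hypergeometric upper-tail) category enrichment over an
  explicit gene universe, and pathway-scaling summaries.

A synthetic-data module generates all inputs with plantable effect sizes
(terminal-position odds, within-group edge boost, category
over-representation), so every statistic can be calibrated under the null
and validated for recovery of planted effects.

## Worked example

```python
from enzloc import (SyntheticConfig, generate_bundle, build_adjacency,
                    attach_localization, load_reaction_tables, load_id_list,
                    load_efps, efp_report, wgc_contrast,
                    within_group_connectivity)

cfg = SyntheticConfig(seed=1, terminal_enrichment=6.0, wgc_boost=3.0)
bundle = generate_bundle(cfg, "inputs")

records = load_reaction_tables("inputs/reactions_irreversible.tsv",
                               "inputs/reactions_reversible.tsv")
net = attach_localization(build_adjacency(records), records,
                          load_id_list("inputs/localized_genes.txt"))
efps = load_efps("inputs/efps.tsv", load_id_list("inputs/localized_reactions.txt"))

table = efp_report(efps, n_perm=10000, seed=1)
print(table[(table.L == 6) & (table.statistic == "first_or_last")]
      [["observed", "analytic", "perm_p"]].round(4).to_string(index=False))
print(round(within_group_connectivity(net, net.localized), 4),
      round(within_group_connectivity(net, ~net.localized), 4))
```

prints (seed 1):

```
 observed  analytic  perm_p
   0.8805    0.5333  0.0001
0.0495 0.047
```

i.e. at length 6 almost 90% of EFPs with a localized enzyme have it at a
terminal position, against a 53% closed-form expectation given the observed
k-distribution — the planted terminal preference is recovered with
permutation p = 1e-4 — and localized reactions connect to each other
slightly more often than non-localized ones do (the wgc excess for this
seed; `wgc_contrast` gives its z-score against random node groups).

The same analyses run as numbered scripts:

```sh
python analysis/01_simulate_inputs.py --seed 1
python analysis/02_build_network.py
python analysis/03_efp_positional_stats.py
python analysis/04_loop_statistics.py
python analysis/05_group_structure.py
python analysis/06_enrichment_scaling.py
```

or end-to-end via the CLI: `enzloc run --config run.yaml`,
with per-stage commands `enzloc simulate | efp-stats | loop-stats |
group-stats | enrich | reproduce` (see `--help`).

If the original study's supplementary files are available,
`enzloc reproduce --fixtures DIR` recomputes each published headline
quantity (EFP positional counts, wgc, clustering means, surrogate triangle
ratio) and prints computed vs expected; with no fixtures present every
target is reported as skipped.

## Layout

```
src/enzloc/        library: network, efp, loops, groups, enrichment,
                   simulate, nulls, report, pipeline, cli
analysis/          numbered narrative drivers writing results/ tables
tests/             pytest suite (unit, property and acceptance tests)
scripts/           acceptance.py
docs/methods.md    models, nulls, parameter choices, limitations
```
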