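"""Synthetic input generator with controlled, plantable statistical structure.

Every pipeline input — reaction tables, localization labels, EFP tables,
category tables — can be generated from a :class:`SyntheticConfig`, so the
full analysis is testable without any external data and planted effects are
recoverable:

* ``wgc_boost``: localized reactions preferentially consume compounds
  produced by other localized reactions (rejection-free mixture sampling on
  substrate assignment), raising their within-group connectivity.  At boost
  1 compound assignment is independent of the labels (exact null).
* ``terminal_enrichment``: when placing an EFP's k localized flags over its
  L positions, the two terminal positions carry these odds against 1 for
  interior positions (weighted sampling without replacement).  At 1 the
  placement is uniform, which is exactly the regime of the closed-form null.
* ``planted_enrichment``: the first ``n_planted`` categories over-sample
  localized genes by these odds.

All generators are deterministic functions of the config (which carries the
seed); written files round-trip through the package parsers warning-free.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .efp import FluxPattern
from .enrichment import PathwaySummary
from .network import ReactionRecord

logger = logging.getLogger(__name__)


@dataclass
class SyntheticConfig:
    seed: int = 0
    # reaction/compound bipartite structure
    n_compounds: int = 150
    n_reactions: int = 300
    substrate_range: tuple = (1, 3)
    product_range: tuple = (1, 3)
    n_hub_compounds: int = 3
    hub_incidence: int = 80
    fraction_reversible: float = 0.3
    genes_per_reaction: int = 1
    fraction_localized_genes: float = 0.25
    wgc_boost: float = 1.0
    # EFPs
    n_efps: int = 2000
    efp_length_range: tuple = (3, 12)
    terminal_enrichment: float = 1.0
    # categories
    n_categories: int = 20
    category_size_range: tuple = (10, 40)
    n_planted: int = 0
    planted_enrichment: float = 1.0
    # pathway summaries (Fig-style scaling analogue)
    n_pathways: int = 40
    pathway_length_range: tuple = (2, 60)
    pathway_loc_fraction: float = 1.0 / 7.0

    def __post_init__(self):
        for name in ("fraction_reversible", "fraction_localized_genes", "pathway_loc_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("wgc_boost", "terminal_enrichment", "planted_enrichment"):
            if getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be >= 1")
        for name in ("n_compounds", "n_reactions", "n_efps", "n_categories",
                     "genes_per_reaction", "n_hub_compounds", "hub_incidence"):
            if getattr(self, name) < 0 or (name in ("n_compounds", "n_reactions")
                                           and getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive")
        if self.hub_incidence > self.n_reactions:
            raise ValueError("infeasible config: hub_incidence exceeds n_reactions")
        if not (3 <= self.efp_length_range[0] <= self.efp_length_range[1] <= 12):
            raise ValueError("efp_length_range must lie within [3, 12]")
        if self.n_planted > self.n_categories:
            raise ValueError("n_planted exceeds n_categories")


def _compound_id(i):
    return f"C{i + 1:05d}"


def generate_network(config: SyntheticConfig, out_dir=None):
    """Generate reaction records plus a localized-gene list.

    Returns ``(records, localized_genes)``; with ``out_dir`` also writes
    ``reactions_irreversible.tsv``, ``reactions_reversible.tsv``,
    ``localized_genes.txt`` and a ``manifest.json`` of realized parameters.
    """
    rng = np.random.default_rng(config.seed)
    nR = config.n_reactions
    hubs = [_compound_id(i) for i in range(config.n_hub_compounds)]
    pool = [_compound_id(i) for i in range(config.n_hub_compounds, config.n_compounds)]
    if len(pool) < max(config.substrate_range[1], config.product_range[1]) * 2:
        raise ValueError("infeasible config: non-hub compound pool too small")

    # genes and localization labels
    genes = [[f"b{i * config.genes_per_reaction + g + 1:04d}"
              for g in range(config.genes_per_reaction)] for i in range(nR)]
    all_genes = [g for gs in genes for g in gs]
    loc_gene_mask = rng.random(len(all_genes)) < config.fraction_localized_genes
    localized_genes = {g for g, m in zip(all_genes, loc_gene_mask) if m}
    reaction_localized = [any(g in localized_genes for g in gs) for gs in genes]

    reversible = rng.random(nR) < config.fraction_reversible

    # products first, so a localized-product pool exists for wgc boosting
    products = []
    for i in range(nR):
        n_prod = int(rng.integers(config.product_range[0], config.product_range[1] + 1))
        products.append({str(c) for c in rng.choice(pool, size=n_prod, replace=False)})
    loc_products = sorted({c for i, ps in enumerate(products) if reaction_localized[i]
                           for c in ps})

    p_boost = 1.0 - 1.0 / config.wgc_boost  # 0 at boost 1, -> 1 as boost grows
    substrates = []
    for i in range(nR):
        n_sub = int(rng.integers(config.substrate_range[0], config.substrate_range[1] + 1))
        chosen = set()
        guard = 0
        while len(chosen) < n_sub:
            guard += 1
            if guard > 1000:
                raise ValueError("infeasible config: cannot sample distinct substrates")
            if (reaction_localized[i] and loc_products
                    and rng.random() < p_boost):
                c = loc_products[int(rng.integers(len(loc_products)))]
            else:
                c = pool[int(rng.integers(len(pool)))]
            if c not in products[i] and c not in chosen:
                chosen.add(c)
        substrates.append(chosen)

    # hub wiring: each hub touches hub_incidence distinct reactions, one role each
    for h, hub in enumerate(hubs):
        touched = rng.choice(nR, size=config.hub_incidence, replace=False)
        roles = rng.random(config.hub_incidence) < 0.5
        for r, as_substrate in zip(touched, roles):
            (substrates if as_substrate else products)[int(r)].add(hub)

    records = [
        ReactionRecord(
            reaction_id=f"R{i + 1:05d}",
            substrates=frozenset(substrates[i]),
            products=frozenset(products[i]),
            reversible=bool(reversible[i]),
            genes=frozenset(genes[i]),
        )
        for i in range(nR)
    ]

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_reaction_tables(records, out)
        with open(out / "localized_genes.txt", "w", encoding="utf-8") as fh:
            for g in sorted(localized_genes):
                fh.write(g + "\n")
        manifest = {
            "config": dataclasses.asdict(config),
            "n_localized_genes": len(localized_genes),
            "n_localized_reactions": int(sum(reaction_localized)),
            "n_reversible_reactions": int(reversible.sum()),
        }
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return records, localized_genes


def _write_reaction_tables(records, out: Path):
    def write(path, recs):
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#reaction_id\tsubstrates\tproducts\tgenes\n")
            for r in recs:
                fh.write("\t".join([
                    r.reaction_id,
                    ",".join(sorted(r.substrates)),
                    ",".join(sorted(r.products)),
                    ",".join(sorted(r.genes)),
                ]) + "\n")

    write(out / "reactions_irreversible.tsv", [r for r in records if not r.reversible])
    write(out / "reactions_reversible.tsv", [r for r in records if r.reversible])


def localized_reaction_ids(records, localized_genes):
    """Reactions catalyzed by at least one localized gene (the OR rule)."""
    loc = set(localized_genes)
    return {r.reaction_id for r in records if r.genes & loc}


def _weighted_positions(L: int, k: int, terminal_odds: float, rng) -> np.ndarray:
    """Sample k of L positions without replacement; terminals carry the odds.

    Gumbel-top-k keys realize sequential weighted sampling without
    replacement; with odds 1 everywhere this is uniform.
    """
    w = np.ones(L)
    w[0] = w[-1] = terminal_odds
    keys = np.log(w) + rng.gumbel(size=L)
    return np.sort(np.argpartition(-keys, k - 1)[:k]) if k > 0 else np.empty(0, dtype=int)


def generate_efps(config: SyntheticConfig, reaction_ids, localized_reactions,
                  out_path=None):
    """Generate EFPs with a planted terminal-localization preference.

    ``reaction_ids`` is the full reaction pool; ``localized_reactions`` the
    localized subset (must be non-empty).  Each EFP draws its length
    uniformly from ``efp_length_range``, a localized count k ~ Binomial(L,
    fraction localized in the pool), flag positions with terminal odds
    ``terminal_enrichment``, and fills steps with distinct reaction ids of
    the matching label.
    """
    loc_pool = sorted(set(localized_reactions))
    non_pool = sorted(set(reaction_ids) - set(localized_reactions))
    if not loc_pool:
        raise ValueError("localized reaction set is empty")
    if not non_pool:
        raise ValueError("need at least one non-localized reaction")
    f = len(loc_pool) / (len(loc_pool) + len(non_pool))
    rng = np.random.default_rng(config.seed + 1)
    lo, hi = config.efp_length_range
    efps = []
    for e in range(config.n_efps):
        L = int(rng.integers(lo, hi + 1))
        k = int(rng.binomial(L, f))
        k = min(k, len(loc_pool))
        if L - k > len(non_pool):
            k = L - len(non_pool)
        flag_pos = set(int(p) for p in _weighted_positions(L, k, config.terminal_enrichment, rng))
        loc_ids = rng.choice(loc_pool, size=k, replace=False) if k else []
        non_ids = rng.choice(non_pool, size=L - k, replace=False) if L - k else []
        steps, flags = [], []
        li = ni = 0
        for pos in range(L):
            if pos in flag_pos:
                steps.append(str(loc_ids[li])); li += 1
                flags.append(True)
            else:
                steps.append(str(non_ids[ni])); ni += 1
                flags.append(False)
        efps.append(FluxPattern(f"EFP{e + 1:05d}", tuple(steps), tuple(flags)))
    if out_path is not None:
        write_efps(efps, out_path)
    return efps


def write_efps(efps, out_path):
    with open(out_path, "w", encoding="utf-8") as fh:
        fh.write("#efp_id\treactions\n")
        for e in efps:
            fh.write(f"{e.efp_id}\t{','.join(e.steps)}\n")


def generate_categories(config: SyntheticConfig, universe_genes, localized_genes,
                        out_path=None):
    """Generate category membership tables with planted over-representation.

    The first ``n_planted`` categories sample localized genes with odds
    ``planted_enrichment`` against 1; the rest sample uniformly.
    """
    universe = sorted(set(universe_genes))
    localized = set(localized_genes)
    if not universe:
        raise ValueError("gene universe is empty")
    if config.category_size_range[0] < 1:
        raise ValueError("category size must be >= 1")
    if config.category_size_range[1] > len(universe):
        raise ValueError("infeasible config: category size exceeds universe")
    rng = np.random.default_rng(config.seed + 2)
    is_loc = np.array([g in localized for g in universe])
    cats = {}
    for c in range(config.n_categories):
        size = int(rng.integers(config.category_size_range[0],
                                config.category_size_range[1] + 1))
        if c < config.n_planted and config.planted_enrichment > 1.0:
            w = np.where(is_loc, config.planted_enrichment, 1.0)
            p = w / w.sum()
            members = rng.choice(universe, size=size, replace=False, p=p)
        else:
            members = rng.choice(universe, size=size, replace=False)
        name = f"CAT{c + 1:03d}" + ("_planted" if c < config.n_planted else "")
        cats[name] = frozenset(str(m) for m in members)
    if out_path is not None:
        with open(out_path, "w", encoding="utf-8") as fh:
            fh.write("#category\tgenes\n")
            for name in cats:
                fh.write(f"{name}\t{','.join(sorted(cats[name]))}\n")
    return cats


def generate_pathways(config: SyntheticConfig, out_path=None):
    """Pathway (length, n_localized) summaries for the scaling statistics."""
    rng = np.random.default_rng(config.seed + 3)
    lo, hi = config.pathway_length_range
    out = []
    for p in range(config.n_pathways):
        length = int(rng.integers(lo, hi + 1))
        n_loc = int(rng.binomial(length, config.pathway_loc_fraction))
        out.append(PathwaySummary(f"PW{p + 1:03d}", length, n_loc))
    if out_path is not None:
        with open(out_path, "w", encoding="utf-8") as fh:
            fh.write("#pathway_id\tlength\tn_localized\n")
            for pw in out:
                fh.write(f"{pw.pathway_id}\t{pw.length}\t{pw.n_localized}\n")
    return out


def generate_bundle(config: SyntheticConfig, out_dir):
    """Write the full synthetic input bundle (network, EFPs, categories,
    pathways) under ``out_dir`` and return the in-memory objects."""
    out = Path(out_dir)
    records, localized_genes = generate_network(config, out_dir=out)
    loc_reactions = localized_reaction_ids(records, localized_genes)
    all_ids = [r.reaction_id for r in records]
    efps = generate_efps(config, all_ids, loc_reactions, out_path=out / "efps.tsv")
    universe = sorted({g for r in records for g in r.genes})
    cats = generate_categories(config, universe, localized_genes,
                               out_path=out / "categories.tsv")
    with open(out / "universe_genes.txt", "w", encoding="utf-8") as fh:
        fh.writelines(g + "\n" for g in universe)
    pathways = generate_pathways(config, out_path=out / "pathways.tsv")
    with open(out / "localized_reactions.txt", "w", encoding="utf-8") as fh:
        fh.writelines(r + "\n" for r in sorted(loc_reactions))
    return {
        "records": records,
        "localized_genes": localized_genes,
        "localized_reactions": loc_reactions,
        "efps": efps,
        "categories": cats,
        "universe": universe,
        "pathways": pathways,
    }
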