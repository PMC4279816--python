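"""Category enrichment (Fisher exact) and pathway-scaling statistics.

Enrichment asks, for each functional category, whether localized genes are
over-represented among its members.  With a gene universe of size N, n_loc
localized genes, a category of size n_cat containing x localized members,
the one-sided p-value is the upper hypergeometric tail P(X >= x), and the
expected count under no association is n_cat * n_loc / N.  The universe is a
required explicit input: results change with it, so it is never assumed.

Pathway scaling summarizes how the number of localized enzymes grows with
pathway length: the Pearson correlation of log(length) vs log(n_localized)
over pathways with at least one localized enzyme, and the mean
length / n_localized ratio over the same set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PathwaySummary:
    pathway_id: str
    length: int
    n_localized: int

    def __post_init__(self):
        if not (0 <= self.n_localized <= self.length):
            raise ValueError(f"{self.pathway_id}: n_localized outside [0, length]")


@dataclass
class CategoryTable:
    """Category membership lists over an explicit gene universe."""

    categories: dict            # name -> frozenset of gene ids
    universe: frozenset
    localized: frozenset

    def __post_init__(self):
        self.universe = frozenset(self.universe)
        self.localized = frozenset(self.localized)
        if not self.universe or not self.localized:
            raise ValueError("universe and localized sets must be non-empty")
        stray_loc = self.localized - self.universe
        if stray_loc:
            raise ValueError(f"localized ids outside universe: {sorted(stray_loc)[:5]}")
        self.categories = {k: frozenset(v) for k, v in self.categories.items()}
        for name, members in self.categories.items():
            stray = members - self.universe
            if stray:
                raise ValueError(
                    f"category {name!r}: member {sorted(stray)[0]!r} not in universe"
                )


def load_category_table(categories_path, universe, localized) -> CategoryTable:
    """Read a category TSV (name TAB comma-joined gene ids)."""
    cats = {}
    with open(categories_path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{categories_path}: line {lineno}: expected 2 fields")
            name = parts[0].strip()
            members = frozenset(g for g in (x.strip() for x in parts[1].split(",")) if g)
            if not members:
                raise ValueError(f"{categories_path}: line {lineno}: empty category")
            cats[name] = members
    return CategoryTable(cats, frozenset(universe), frozenset(localized))


def fisher_enrichment(table: CategoryTable, adjust: bool = False) -> pd.DataFrame:
    """One-sided over-representation test per category, sorted by p.

    p = P(X >= n_loc_in_cat) for X ~ Hypergeom(N=|universe|,
    K=|localized|, n=n_cat).  Benjamini-Hochberg adjustment is off by
    default and adds a ``p_bh`` column when requested.
    """
    N = len(table.universe)
    K = len(table.localized)
    rows = []
    for name, members in table.categories.items():
        n_cat = len(members)
        x = len(members & table.localized)
        p = float(stats.hypergeom.sf(x - 1, N, K, n_cat))
        rows.append({
            "category": name,
            "n_cat": n_cat,
            "n_loc_in_cat": x,
            "expected": n_cat * K / N,
            "p": min(p, 1.0),
        })
    df = pd.DataFrame(rows).sort_values("p", kind="mergesort").reset_index(drop=True)
    if adjust and len(df):
        m = len(df)
        ranked = df["p"].to_numpy() * m / (np.arange(m) + 1)
        df["p_bh"] = np.minimum.accumulate(ranked[::-1])[::-1].clip(max=1.0)
    return df


def pathway_scaling(pathways) -> tuple:
    """(Pearson of log length vs log n_localized, mean length/n_localized).

    Restricted to pathways with n_localized > 0; needs at least two of them.
    """
    eligible = [p for p in pathways if p.n_localized > 0]
    if len(eligible) < 2:
        raise ValueError("need >= 2 pathways with at least one localized enzyme")
    lengths = np.array([p.length for p in eligible], dtype=float)
    n_loc = np.array([p.n_localized for p in eligible], dtype=float)
    log_l, log_k = np.log(lengths), np.log(n_loc)
    if np.ptp(log_l) == 0 or np.ptp(log_k) == 0:
        pearson = float("nan")
        logger.warning("pathway scaling: a log-variable is constant; correlation undefined")
    else:
        pearson = float(np.corrcoef(log_l, log_k)[0, 1])
    mean_ratio = float(np.mean(lengths / n_loc))
    return pearson, mean_ratio


def load_pathway_table(path):
    """Read a pathway TSV (pathway_id TAB length TAB n_localized)."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 fields")
            out.append(PathwaySummary(parts[0].strip(), int(parts[1]), int(parts[2])))
    return out
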