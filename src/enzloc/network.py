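"""Reaction tables, localization labels, and the reaction-adjacency matrix.

A metabolic network is represented as a directed Boolean matrix ``M`` over
reactions: ``M[i, j] = 1`` iff reaction *i* produces a compound that reaction
*j* consumes.  Reversible reactions contribute in both functional directions
(their substrate and product roles are unioned on each side).  Ubiquitous
"hub" compounds (water, ATP, pyruvate, ...) connect to so many reactions that
they would create dense spurious cliques, so any compound whose connection
count exceeds a threshold is excluded before edges are formed.

Reaction tables are 4-column TSV files (reaction id, comma-joined substrate
compound ids, comma-joined product compound ids, comma-joined gene ids), one
file for irreversible and one for reversible reactions.  Localization labels
arrive as a flat list of gene identifiers (E. coli b-numbers); a reaction is
*localized* iff at least one of its catalyzing genes is in that list.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_HUB_THRESHOLD = 60


class ReactionTableError(ValueError):
    """Malformed reaction table input."""


class DuplicateReactionError(ReactionTableError):
    """The same reaction id appears more than once."""


@dataclass(frozen=True)
class ReactionRecord:
    """One biochemical reaction.

    Parameters
    ----------
    reaction_id : KEGG-style identifier (e.g. ``"R00001"``).
    substrates, products : compound-id sets; each must be non-empty.  A
        compound may legitimately appear on both sides (it is logged).
    reversible : whether the reaction can run in either direction.
    genes : b-number gene ids of the catalyzing enzyme(s); may be empty.
    """

    reaction_id: str
    substrates: frozenset
    products: frozenset
    reversible: bool
    genes: frozenset

    def outputs(self):
        """Compounds this reaction can produce (both sides if reversible)."""
        return self.products | self.substrates if self.reversible else self.products

    def inputs(self):
        """Compounds this reaction can consume (both sides if reversible)."""
        return self.substrates | self.products if self.reversible else self.substrates


@dataclass
class ReactionNetwork:
    """Directed Boolean reaction-adjacency matrix plus localization mask.

    ``M[i, j] = 1`` iff some non-excluded compound is an output of reaction
    ``reactions[i]`` and an input of ``reactions[j]`` (``i != j``).
    """

    reactions: list
    M: np.ndarray
    localized: np.ndarray
    excluded_compounds: set = field(default_factory=set)

    def __post_init__(self):
        self.M = np.asarray(self.M, dtype=np.int8)
        n = len(self.reactions)
        if self.M.shape != (n, n):
            raise ValueError(f"matrix shape {self.M.shape} does not match {n} reactions")
        if self.localized is None:
            self.localized = np.zeros(n, dtype=bool)
        self.localized = np.asarray(self.localized, dtype=bool)
        if self.localized.shape != (n,):
            raise ValueError("localized mask length does not match reaction count")
        self._index = {r: i for i, r in enumerate(self.reactions)}
        if len(self._index) != n:
            raise DuplicateReactionError("reaction ids are not unique")

    @property
    def n(self) -> int:
        return len(self.reactions)

    def index(self, reaction_id: str) -> int:
        return self._index[reaction_id]

    @classmethod
    def from_edges(cls, reactions, edges, localized=None):
        """Build directly from an iterable of (source_id, target_id) pairs."""
        n = len(reactions)
        idx = {r: i for i, r in enumerate(reactions)}
        M = np.zeros((n, n), dtype=np.int8)
        for a, b in edges:
            i, j = idx[a], idx[b]
            if i != j:
                M[i, j] = 1
        if localized is None:
            localized = np.zeros(n, dtype=bool)
        return cls(list(reactions), M, np.asarray(localized, dtype=bool))

    def edge_list(self):
        """Directed edges as (source_id, target_id) pairs."""
        src, dst = np.nonzero(self.M)
        return [(self.reactions[i], self.reactions[j]) for i, j in zip(src, dst)]


def _split_ids(text: str, path, lineno: int, role: str, required: bool = True):
    ids = frozenset(t for t in (x.strip() for x in text.split(",")) if t)
    if required and not ids:
        raise ReactionTableError(f"{path}: line {lineno}: empty {role} list")
    return ids


def parse_reaction_table(path, dialect: str):
    """Parse one reaction TSV file.

    ``dialect`` is ``"irreversible"`` or ``"reversible"`` and sets the
    reversibility flag of every record in the file.  Lines starting with
    ``#`` and blank lines are skipped.
    """
    if dialect not in ("irreversible", "reversible"):
        raise ValueError(f"unknown dialect {dialect!r}")
    reversible = dialect == "reversible"
    records = []
    seen = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ReactionTableError(
                    f"{path}: line {lineno}: expected 4 tab-separated fields, got {len(parts)}"
                )
            rid, subs, prods, genes = (p.strip() for p in parts)
            if not rid:
                raise ReactionTableError(f"{path}: line {lineno}: empty reaction id")
            if rid in seen:
                raise DuplicateReactionError(f"duplicate reaction id {rid!r} at {path}:{lineno}")
            seen.add(rid)
            substrates = _split_ids(subs, path, lineno, "substrate")
            products = _split_ids(prods, path, lineno, "product")
            gene_set = _split_ids(genes, path, lineno, "gene", required=False)
            overlap = substrates & products
            if overlap:
                logger.warning(
                    "reaction %s lists %s as both substrate and product",
                    rid, ",".join(sorted(overlap)),
                )
            records.append(ReactionRecord(rid, substrates, products, reversible, gene_set))
    return records


def load_reaction_tables(irreversible_path, reversible_path):
    """Parse the irreversible + reversible table pair into one record list.

    A reaction id present in both files is a :class:`DuplicateReactionError`.
    """
    records = parse_reaction_table(irreversible_path, "irreversible")
    rev = parse_reaction_table(reversible_path, "reversible")
    seen = {r.reaction_id for r in records}
    for r in rev:
        if r.reaction_id in seen:
            raise DuplicateReactionError(
                f"reaction id {r.reaction_id!r} appears in both dialect files"
            )
    return records + rev


def load_id_list(path):
    """One identifier per line (b-numbers, reaction ids, ...); '#' comments allowed."""
    out = set()
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out


def compound_usage(records, count_mode: str = "role"):
    """Connection count per compound.

    ``count_mode="role"`` counts one connection per (reaction, role)
    incidence — a compound that is both substrate and product of the same
    reaction counts twice.  ``count_mode="reaction"`` counts each reaction at
    most once per compound.
    """
    if not records:
        raise ValueError("no reaction records")
    counts = Counter()
    for r in records:
        if count_mode == "role":
            for c in r.substrates:
                counts[c] += 1
            for c in r.products:
                counts[c] += 1
        elif count_mode == "reaction":
            for c in r.substrates | r.products:
                counts[c] += 1
        else:
            raise ValueError(f"unknown count_mode {count_mode!r}")
    return dict(counts)


def build_adjacency(records, hub_threshold: int = DEFAULT_HUB_THRESHOLD,
                    count_mode: str = "role") -> ReactionNetwork:
    """Construct the directed reaction-adjacency matrix.

    Compounds with connection count strictly greater than ``hub_threshold``
    are excluded before any edge is formed; the diagonal is forced to zero.
    """
    if not records:
        raise ValueError("no reaction records")
    if hub_threshold < 0:
        raise ValueError("hub_threshold must be >= 0")
    usage = compound_usage(records, count_mode=count_mode)
    excluded = {c for c, k in usage.items() if k > hub_threshold}
    if excluded:
        logger.info("excluding %d hub compounds (> %d connections)", len(excluded), hub_threshold)

    producers = {}
    consumers = {}
    for i, r in enumerate(records):
        for c in r.outputs() - excluded:
            producers.setdefault(c, []).append(i)
        for c in r.inputs() - excluded:
            consumers.setdefault(c, []).append(i)

    n = len(records)
    M = np.zeros((n, n), dtype=np.int8)
    for c, ps in producers.items():
        cs = consumers.get(c)
        if cs:
            M[np.ix_(ps, cs)] = 1
    np.fill_diagonal(M, 0)
    ids = [r.reaction_id for r in records]
    return ReactionNetwork(ids, M, np.zeros(n, dtype=bool), excluded)


def attach_localization(net: ReactionNetwork, records, localized_genes) -> ReactionNetwork:
    """Flag each reaction localized iff ANY of its genes is in the label set.

    Returns a new network; genes matching no reaction trigger a warning only.
    """
    by_id = {r.reaction_id: r for r in records}
    mask = np.zeros(net.n, dtype=bool)
    used = set()
    for i, rid in enumerate(net.reactions):
        rec = by_id.get(rid)
        if rec is None:
            raise KeyError(f"no reaction record for network node {rid!r}")
        hit = rec.genes & set(localized_genes)
        if hit:
            mask[i] = True
            used |= hit
    unmatched = set(localized_genes) - used
    if unmatched:
        logger.warning("%d localized genes match no reaction", len(unmatched))
    logger.info("flagged %d of %d reactions as localized", int(mask.sum()), net.n)
    return replace(net, localized=mask)


def write_network(net: ReactionNetwork, out_dir, mtx: bool = False):
    """Export as directed edge-list TSV + node table (and optionally MTX)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "edges.tsv", "w", encoding="utf-8") as fh:
        fh.write("#source_id\ttarget_id\n")
        for a, b in net.edge_list():
            fh.write(f"{a}\t{b}\n")
    with open(out / "nodes.tsv", "w", encoding="utf-8") as fh:
        fh.write("#reaction_id\tlocalized\n")
        for rid, loc in zip(net.reactions, net.localized):
            fh.write(f"{rid}\t{int(loc)}\n")
    if mtx:
        from scipy import io as spio
        from scipy import sparse

        spio.mmwrite(str(out / "adjacency.mtx"), sparse.coo_matrix(net.M))


def load_network(in_dir) -> ReactionNetwork:
    """Load a network previously written by :func:`write_network`."""
    in_dir = Path(in_dir)
    ids, loc = [], []
    with open(in_dir / "nodes.tsv", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rid, flag = line.split("\t")
            ids.append(rid)
            loc.append(bool(int(flag)))
    edges = []
    with open(in_dir / "edges.tsv", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            a, b = line.split("\t")
            edges.append((a, b))
    return ReactionNetwork.from_edges(ids, edges, np.asarray(loc, dtype=bool))
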