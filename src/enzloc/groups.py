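"""Group-structure statistics: within-group connectivity, clustering,
triangle composition, and degree-preserving surrogates.

The contrast of interest is between *localized* reaction nodes (enzyme shows
a punctate cytoplasmic focus) and the remaining nodes.  Localized reactions
in E. coli connect to each other more often than chance (higher within-group
connectivity) yet close fewer triangles among themselves (lower clustering),
i.e. they form a tree-like hierarchical backbone.

* within-group connectivity (wgc): the probability that an ordered pair of
  distinct group members is joined by a directed edge — internal edge count
  over g(g-1).  Unordered-pair and per-node normalizations are selectable.
* clustering coefficients and triangles are computed on the symmetrized
  simple graph (direction is deliberately ignored here, unlike the loop
  statistics).
* degree-preserving surrogates destroy higher-order structure while keeping
  every node's in- and out-degree, via repeated directed double-edge swaps:
  pick edges (a->b), (c->d), replace with (a->d), (c->b) unless a self-edge
  or duplicate would arise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .loops import ks_compare
from .network import ReactionNetwork
from .nulls import NullSummary, summarize_null

logger = logging.getLogger(__name__)


@dataclass
class TriangleComposition:
    """Undirected-triangle counts by number of localized vertices."""

    t3loc: int
    t2loc1non: int
    t1loc2non: int
    t0loc: int

    @property
    def total(self) -> int:
        return self.t3loc + self.t2loc1non + self.t1loc2non + self.t0loc

    @property
    def ratio_1to2(self):
        """t1loc2non / t2loc1non; None when the denominator is zero."""
        if self.t2loc1non == 0:
            return None
        return self.t1loc2non / self.t2loc1non


@dataclass
class SurrogateEnsemble:
    """ratio_1to2 over an ensemble of degree-preserving surrogates."""

    observed: float
    values: np.ndarray          # NaN where a surrogate's ratio is undefined
    n_surrogates: int
    n_swaps: int
    seed: object
    degenerate: bool

    @property
    def mean(self):
        return float(np.nanmean(self.values)) if not self.degenerate else float("nan")

    @property
    def sd(self):
        return float(np.nanstd(self.values, ddof=1)) if not self.degenerate else float("nan")

    def t_test(self):
        """One-sample t of the ensemble against the observed value.

        Returns (t, p_two_sided, p_one_sided) where the one-sided
        alternative is 'ensemble mean greater than observed'.
        """
        vals = self.values[~np.isnan(self.values)]
        res = stats.ttest_1samp(vals, self.observed)
        t = float(res.statistic)
        p2 = float(res.pvalue)
        p1 = p2 / 2 if t > 0 else 1 - p2 / 2
        return t, p2, p1


def within_group_connectivity(net: ReactionNetwork, mask, norm: str = "ordered") -> float:
    """Probability that a pair of distinct group nodes is joined by an edge.

    ``norm="ordered"`` divides the directed internal edge count by g(g-1)
    ordered pairs (default); ``"unordered"`` by g(g-1)/2; ``"per_node"``
    by g.
    """
    mask = np.asarray(mask, dtype=bool)
    g = int(mask.sum())
    if g < 2:
        raise ValueError("group must contain at least 2 nodes")
    e = int(net.M[np.ix_(mask, mask)].sum())
    if norm == "ordered":
        return e / (g * (g - 1))
    if norm == "unordered":
        return e / (g * (g - 1) / 2)
    if norm == "per_node":
        return e / g
    raise ValueError(f"unknown norm {norm!r}")


def wgc_contrast(net: ReactionNetwork, mask=None, n_draws: int = 10000, seed=None,
                 norm: str = "ordered") -> NullSummary:
    """wgc(group) - wgc(complement) against random same-size node groups."""
    mask = net.localized if mask is None else np.asarray(mask, dtype=bool)
    n = net.n
    g = int(mask.sum())
    if g < 2 or n - g < 2:
        raise ValueError("both groups need >= 2 nodes")
    M = net.M.astype(np.int64)
    total = int(M.sum())
    row_sums = M.sum(axis=1)
    col_sums = M.sum(axis=0)

    def diff_for(idx_bool):
        gg = int(idx_bool.sum())
        eg = int(M[np.ix_(idx_bool, idx_bool)].sum())
        ec = total - int(row_sums[idx_bool].sum()) - int(col_sums[idx_bool].sum()) + eg
        cg = n - gg
        a = eg / (gg * (gg - 1))
        b = ec / (cg * (cg - 1))
        if norm == "unordered":
            a, b = 2 * a, 2 * b
        elif norm == "per_node":
            a, b = eg / gg, ec / cg
        elif norm != "ordered":
            raise ValueError(f"unknown norm {norm!r}")
        return a - b

    observed = diff_for(mask)
    rng = np.random.default_rng(seed)
    samples = np.empty(n_draws, dtype=float)
    for d in range(n_draws):
        idx = np.zeros(n, dtype=bool)
        idx[rng.choice(n, size=g, replace=False)] = True
        samples[d] = diff_for(idx)
    summary = summarize_null(f"wgc_difference[{norm}]", observed, samples, seed=seed)
    if summary.degenerate:
        logger.warning("degenerate wgc null (sd = 0)")
    return summary


def _symmetrized(net: ReactionNetwork) -> np.ndarray:
    A = ((net.M + net.M.T) > 0).astype(np.int8)
    np.fill_diagonal(A, 0)
    return A


def clustering_coefficients(net: ReactionNetwork, mask=None,
                            include_degenerate: bool = True,
                            alternative: str = "two_sided"):
    """Per-node clustering on the symmetrized simple graph, plus contrast.

    c(i) = 2 * triangles(i) / (d(i) (d(i)-1)); nodes with undirected degree
    < 2 get c = 0 and are included by default (set
    ``include_degenerate=False`` to drop them from the group summaries).
    Returns (per-node Series, dict with group means and KS contrast).
    """
    mask = net.localized if mask is None else np.asarray(mask, dtype=bool)
    A = _symmetrized(net)
    G = nx.from_numpy_array(A)
    cc = nx.clustering(G)
    series = pd.Series([cc[i] for i in range(net.n)],
                       index=pd.Index(net.reactions, name="reaction_id"),
                       name="clustering")
    keep = np.ones(net.n, dtype=bool)
    if not include_degenerate:
        keep = A.sum(axis=1) >= 2
    vals = series.to_numpy()
    contrast = ks_compare(vals[mask & keep], vals[~mask & keep], alternative=alternative)
    contrast["mean_localized"] = contrast.pop("mean_a")
    contrast["mean_nonlocalized"] = contrast.pop("mean_b")
    return series, contrast


def triangle_composition(net: ReactionNetwork, mask=None) -> TriangleComposition:
    """Classify each undirected triangle by its number of localized vertices.

    Triangles are 3-cliques of the symmetrized simple graph, each counted
    once (via its lexicographically smallest edge).
    """
    mask = net.localized if mask is None else np.asarray(mask, dtype=bool)
    A = _symmetrized(net).astype(bool)
    n = net.n
    counts = [0, 0, 0, 0]
    loc = mask
    for i, j in zip(*np.nonzero(np.triu(A, 1))):
        common = A[i] & A[j]
        common[: j + 1] = False  # k > j ensures each triangle counted once
        if not common.any():
            continue
        base = int(loc[i]) + int(loc[j])
        n_loc_k = int(np.count_nonzero(common & loc))
        n_non_k = int(np.count_nonzero(common) - n_loc_k)
        counts[base + 1] += n_loc_k
        counts[base] += n_non_k
    tc = TriangleComposition(t3loc=counts[3], t2loc1non=counts[2],
                             t1loc2non=counts[1], t0loc=counts[0])
    if tc.ratio_1to2 is None:
        logger.warning("triangle ratio undefined: no triangle with exactly 2 localized vertices")
    return tc


def _swap_edges(edges, n_swaps: int, rng, attempt_factor: int = 100):
    """Directed double-edge swaps on an edge list; returns (edges, successes)."""
    edges = list(edges)
    edge_set = set(edges)
    m = len(edges)
    if m < 2:
        raise ValueError("need at least 2 edges to rewire")
    successes = 0
    cap = attempt_factor * n_swaps
    pair_idx = rng.integers(0, m, size=(cap, 2))
    for i1, i2 in pair_idx:
        if successes >= n_swaps:
            break
        if i1 == i2:
            continue
        a, b = edges[i1]
        c, d = edges[i2]
        if a == d or c == b or a == c or b == d:
            continue
        if (a, d) in edge_set or (c, b) in edge_set:
            continue
        edge_set.remove((a, b))
        edge_set.remove((c, d))
        edge_set.add((a, d))
        edge_set.add((c, b))
        edges[i1] = (a, d)
        edges[i2] = (c, b)
        successes += 1
    return edges, successes


def degree_preserving_rewire(net: ReactionNetwork, n_swaps=None, seed=None,
                             attempt_factor: int = 100) -> ReactionNetwork:
    """Randomize the directed edge set while preserving in/out degrees.

    ``n_swaps`` defaults to 10 x |E| successful swaps (a common mixing
    heuristic); attempts are capped at ``attempt_factor`` x n_swaps with a
    logged shortfall.  If no swap at all succeeds the degree sequence is
    rigid and the original network is returned with a warning.
    """
    edges = [(int(i), int(j)) for i, j in zip(*np.nonzero(net.M))]
    if len(edges) < 2:
        raise ValueError("network must have at least 2 edges")
    if n_swaps is None:
        n_swaps = 10 * len(edges)
    rng = np.random.default_rng(seed)
    new_edges, successes = _swap_edges(edges, n_swaps, rng, attempt_factor)
    if successes == 0:
        logger.warning("degree sequence appears rigid: no successful swap; returning original")
        return replace(net, M=net.M.copy())
    if successes < n_swaps:
        logger.info("rewiring shortfall: %d of %d requested swaps", successes, n_swaps)
    M = np.zeros_like(net.M)
    rows, cols = zip(*new_edges)
    M[list(rows), list(cols)] = 1
    return replace(net, M=M)


def surrogate_triangle_ratio(net: ReactionNetwork, mask=None,
                             n_surrogates: int = 100, n_swaps=None,
                             seed=None) -> SurrogateEnsemble:
    """ratio_1to2 over degree-preserving surrogates, same localization mask."""
    mask = net.localized if mask is None else np.asarray(mask, dtype=bool)
    observed_tc = triangle_composition(net, mask)
    observed = observed_tc.ratio_1to2
    rng = np.random.default_rng(seed)
    values = np.full(n_surrogates, np.nan)
    for s in range(n_surrogates):
        surr = degree_preserving_rewire(net, n_swaps=n_swaps,
                                        seed=int(rng.integers(2**31)))
        r = triangle_composition(surr, mask).ratio_1to2
        if r is not None:
            values[s] = r
    degenerate = bool(np.isnan(values).all()) or observed is None
    if degenerate:
        logger.warning("surrogate triangle ratio degenerate (undefined everywhere)")
    return SurrogateEnsemble(
        observed=float("nan") if observed is None else float(observed),
        values=values,
        n_surrogates=n_surrogates,
        n_swaps=-1 if n_swaps is None else int(n_swaps),
        seed=seed,
        degenerate=degenerate,
    )


def degree_and_path_contrast(net: ReactionNetwork, mask=None,
                             alternative: str = "two_sided") -> dict:
    """In/out-degree and directed shortest-path contrasts between groups.

    Shortest paths are directed and unweighted; for each group the
    distribution pools finite path lengths over ordered pairs whose *source*
    is in the group (targets anywhere, source != target).  Unreachable pairs
    are excluded from the distributions but counted.
    """
    mask = net.localized if mask is None else np.asarray(mask, dtype=bool)
    if mask.sum() == 0 or (~mask).sum() == 0:
        raise ValueError("both groups must be non-empty")
    out_deg = net.M.sum(axis=1)
    in_deg = net.M.sum(axis=0)
    D = shortest_path(csr_matrix(net.M), method="D", unweighted=True)
    np.fill_diagonal(D, np.inf)  # exclude trivial self pairs

    def paths_for(group_mask):
        sub = D[group_mask]
        finite = np.isfinite(sub)
        # the diagonal infs we planted are self pairs, not unreachable ones
        return sub[finite], int((~finite).sum()) - sub.shape[0]

    paths_loc, unreach_loc = paths_for(mask)
    paths_non, unreach_non = paths_for(~mask)
    result = {
        "in_degree": ks_compare(in_deg[mask], in_deg[~mask], alternative=alternative),
        "out_degree": ks_compare(out_deg[mask], out_deg[~mask], alternative=alternative),
        "unreachable_pairs": {"localized_source": unreach_loc,
                              "nonlocalized_source": unreach_non},
    }
    if paths_loc.size and paths_non.size:
        result["shortest_path"] = ks_compare(paths_loc, paths_non, alternative=alternative)
    else:
        result["shortest_path"] = None
        logger.warning("a group has no finite shortest path; contrast omitted")
    return result
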