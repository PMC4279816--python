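"""Loop and feed-forward-loop statistics from powers of the adjacency matrix.

For the directed Boolean adjacency M, the diagonal of the n-th matrix power,
``[M^n]_ii``, counts the closed directed walks of length n through node i —
the feedback-loop measure.  The feed-forward measures are the diagonals of
the mixed products ``M M^T M`` (FFL3) and ``M M^T M M^T`` (FFL4); these are
motif *measures*, not literal feed-forward-triad counts (on the canonical
triad A->B, B->C, A->C the FFL3 diagonal is (0, 1, 0), concentrated on the
intermediate node).  ``[M M^T]_ii`` equals the out-degree of node i and
serves as the per-node connection count; loop density is the loop count
divided by it.

All powers are exact integer arithmetic: closed-walk counts grow quickly and
floating point would corrupt the ranks fed to the KS tests.  Products are
computed in int64 with an explicit overflow bound and fall back to
arbitrary-precision (object dtype) if the bound could be exceeded.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .network import ReactionNetwork
from .nulls import NullSummary, summarize_null

logger = logging.getLogger(__name__)

_INT64_SAFE = 2**62


def _checked_matmul(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Integer matmul that upgrades to arbitrary precision before overflow."""
    if A.dtype == object or B.dtype == object:
        return A @ B
    a_max = int(A.max(initial=0))
    col_bound = int(B.sum(axis=0, dtype=np.int64).max(initial=0))
    if a_max * col_bound >= _INT64_SAFE:
        logger.info("matrix product near int64 range; switching to exact big integers")
        return A.astype(object) @ B.astype(object)
    return A.astype(np.int64) @ B.astype(np.int64)


def loop_counts(net: ReactionNetwork, n_max: int = 7) -> pd.DataFrame:
    """Per-node closed-walk counts, FFL measures and connection counts.

    Returns a DataFrame indexed by reaction id with columns ``loops2`` ..
    ``loops<n_max>``, ``ffl3``, ``ffl4``, ``connections`` and the node's
    ``localized`` flag.
    """
    if n_max < 2:
        raise ValueError("n_max must be >= 2")
    M = net.M.astype(np.int64)
    Mt = M.T.copy()
    data = {}
    P = _checked_matmul(M, M)
    data["loops2"] = np.diagonal(P).copy()
    power = P
    for n in range(3, n_max + 1):
        power = _checked_matmul(power, M)
        data[f"loops{n}"] = np.diagonal(power).copy()
    MMt = _checked_matmul(M, Mt)
    data["ffl3"] = np.diagonal(_checked_matmul(MMt, M)).copy()
    data["ffl4"] = np.diagonal(_checked_matmul(MMt, MMt)).copy()
    data["connections"] = np.diagonal(MMt).copy()
    df = pd.DataFrame(data, index=pd.Index(net.reactions, name="reaction_id"))
    df["localized"] = net.localized
    return df


def loop_density(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-node loop densities: each count column / connections.

    Nodes with zero connections (out-degree 0) have undefined density and
    are excluded (their count is logged); do not impute zero for them.
    """
    mask = profiles["connections"] > 0
    n_excluded = int((~mask).sum())
    if n_excluded:
        logger.info("excluding %d zero-out-degree nodes from density summaries", n_excluded)
    sub = profiles.loc[mask]
    out = pd.DataFrame(index=sub.index)
    conn = sub["connections"].astype(float)
    for col in sub.columns:
        if col.startswith("loops") or col.startswith("ffl"):
            out[f"density_{col}"] = sub[col] / conn
    out["connections"] = sub["connections"]
    if "localized" in sub.columns:
        out["localized"] = sub["localized"]
    return out


def ks_compare(values_a, values_b, alternative: str = "greater"):
    """Two-sample KS contrast; ``greater`` = group A stochastically larger.

    scipy's alternative naming refers to the CDFs (A stochastically larger
    means its ECDF lies *below* B's), hence the mapping below.
    """
    values_a = np.asarray(values_a, dtype=float)
    values_b = np.asarray(values_b, dtype=float)
    if values_a.size == 0 or values_b.size == 0:
        raise ValueError("both groups must be non-empty")
    if alternative == "greater":
        res = stats.ks_2samp(values_a, values_b, alternative="less")
    elif alternative == "two_sided":
        res = stats.ks_2samp(values_a, values_b, alternative="two-sided")
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return {
        "n_a": int(values_a.size),
        "n_b": int(values_b.size),
        "mean_a": float(values_a.mean()),
        "mean_b": float(values_b.mean()),
        "ks_stat": float(res.statistic),
        "ks_p": float(res.pvalue),
        "alternative": alternative,
    }


def group_loop_contrasts(profiles: pd.DataFrame, columns=None,
                         alternative: str = "greater") -> pd.DataFrame:
    """KS contrasts (localized vs non-localized) for each loop/FFL column."""
    loc = profiles["localized"].to_numpy(dtype=bool)
    if loc.sum() == 0 or (~loc).sum() == 0:
        raise ValueError("both localized and non-localized groups must be non-empty")
    if columns is None:
        columns = [c for c in profiles.columns
                   if c.startswith("loops") or c.startswith("ffl") or c.startswith("density_")]
    rows = []
    for col in columns:
        vals = profiles[col].to_numpy(dtype=float)
        res = ks_compare(vals[loc], vals[~loc], alternative=alternative)
        rows.append({"column": col, **res})
    return pd.DataFrame(rows)


def random_group_null(values, observed_mask, n_draws: int = 100000, seed=None,
                      statistic_name: str = "mean_difference",
                      chunk: int = 2000) -> NullSummary:
    """Random-node-group null for a mean difference of a per-node quantity.

    observed = mean(values | group) - mean(values | complement); each draw
    re-samples a group of the same size uniformly without replacement and
    recomputes the difference.
    """
    values = np.asarray(values, dtype=float)
    mask = np.asarray(observed_mask, dtype=bool)
    n = values.size
    g = int(mask.sum())
    if g == 0 or g >= n:
        raise ValueError("group size must be in [1, n_nodes - 1]")
    total = values.sum()
    observed = values[mask].mean() - values[~mask].mean()
    rng = np.random.default_rng(seed)
    samples = np.empty(n_draws, dtype=float)
    done = 0
    while done < n_draws:
        b = min(chunk, n_draws - done)
        # one random g-subset per draw via partial argsort of uniform keys
        keys = rng.random((b, n))
        idx = np.argpartition(keys, g - 1, axis=1)[:, :g]
        gsum = values[idx].sum(axis=1)
        samples[done:done + b] = gsum / g - (total - gsum) / (n - g)
        done += b
    summary = summarize_null(statistic_name, observed, samples, seed=seed)
    if summary.degenerate:
        logger.warning("degenerate null for %s: statistic constant across nodes", statistic_name)
    return summary
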