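"""Positional statistics of localized enzymes in Elementary Flux Patterns.

An Elementary Flux Pattern (EFP) is an ordered route of L reactions through a
metabolic subsystem.  Each step carries a Boolean flag: whether the enzyme
catalyzing that reaction is localized (punctate cytoplasmic focus) or
diffuse.  The question is whether localized enzymes are over-represented at
the *terminal* positions (first and/or last step).

Two nulls are provided for the per-length terminal ratios:

* a permutation null — within each EFP the k flags are re-placed uniformly
  over the L positions (k preserved per EFP), the ratio recomputed per draw;
* a closed-form null — conditioned on k flags among L positions the chance
  the first is flagged is k/L, the chance both terminals are flagged is
  k(k-1)/(L(L-1)), and averaging over the empirical distribution q(k;L) of k
  at each length gives

      P(first or last | L) = (2/L) q(1;L)
          + sum_{k>=2} [ 2k/L - k(k-1)/(L(L-1)) ] q(k;L).

q(k;L) conditions on k >= 1 by default because the observed ratios condition
on "at least one enzyme localized"; the unconditioned variant is available.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nulls import NullSummary, summarize_null

logger = logging.getLogger(__name__)

DEFAULT_LENGTH_RANGE = (3, 12)

STAT_FIRST_OR_LAST = "first_or_last"
STAT_FIRST_AND_LAST = "first_and_last"

COUNT_COLUMNS = [
    "n_total", "n_any", "n_first", "n_last", "n_both",
    "n_first_or_last", "n_intermediate", "n_two_plus",
]


class UndefinedRatioError(ZeroDivisionError):
    """Requested ratio has an empty denominator."""


@dataclass(frozen=True)
class FluxPattern:
    """One EFP: ordered reaction steps with per-step localization flags."""

    efp_id: str
    steps: tuple
    loc_flags: tuple

    def __post_init__(self):
        if len(self.steps) != len(self.loc_flags):
            raise ValueError(f"EFP {self.efp_id}: steps and flags differ in length")
        if len(self.steps) == 0:
            raise ValueError(f"EFP {self.efp_id}: empty")

    @property
    def L(self) -> int:
        return len(self.steps)

    @property
    def k(self) -> int:
        return sum(self.loc_flags)

    @property
    def first(self) -> bool:
        return bool(self.loc_flags[0])

    @property
    def last(self) -> bool:
        return bool(self.loc_flags[-1])


@dataclass(frozen=True)
class AnalyticNull:
    """Closed-form terminal-localization probabilities at one length."""

    L: int
    p_first: float
    p_last: float
    p_both: float
    p_first_or_last: float


def from_flags(flag_lists, prefix="E"):
    """Convenience: build FluxPatterns from raw 0/1 flag lists (tests, docs)."""
    return [
        FluxPattern(f"{prefix}{i + 1}", tuple(f"{prefix}{i + 1}_R{j}" for j in range(len(fl))),
                    tuple(bool(x) for x in fl))
        for i, fl in enumerate(flag_lists)
    ]


def load_efps(path, localized_reactions, known_reactions=None,
              length_range=DEFAULT_LENGTH_RANGE):
    """Load an EFP table (efp_id TAB comma-joined ordered reaction ids).

    Flags are set by membership in ``localized_reactions``.  If
    ``known_reactions`` is given, steps outside it are logged (flag False).
    EFPs with lengths outside ``length_range`` are dropped with a warning;
    pass ``length_range=None`` to keep all.
    """
    localized = set(localized_reactions)
    efps = []
    dropped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[1].strip():
                raise ValueError(f"{path}: line {lineno}: expected 'efp_id<TAB>R1,R2,...'")
            efp_id = parts[0].strip()
            steps = tuple(s for s in (x.strip() for x in parts[1].split(",")) if s)
            if not steps:
                raise ValueError(f"{path}: line {lineno}: empty EFP")
            if known_reactions is not None:
                unknown = [s for s in steps if s not in known_reactions]
                if unknown:
                    logger.warning("EFP %s references unknown reactions: %s",
                                   efp_id, ",".join(unknown))
            flags = tuple(s in localized for s in steps)
            efp = FluxPattern(efp_id, steps, flags)
            if length_range is not None and not (length_range[0] <= efp.L <= length_range[1]):
                dropped += 1
                continue
            efps.append(efp)
    if dropped:
        logger.warning("dropped %d EFPs with length outside %s", dropped, length_range)
    return efps


def count_positions(efps, length_range=DEFAULT_LENGTH_RANGE) -> pd.DataFrame:
    """Per-length positional counts, one row per EFP length.

    Columns: n_total, n_any (k>=1), n_first, n_last, n_both (first AND
    last), n_first_or_last, n_intermediate (>=1 flag at a non-terminal
    position), n_two_plus (k>=2).
    """
    if not efps:
        raise ValueError("no EFPs")
    rows = {}
    for e in efps:
        if length_range is not None and not (length_range[0] <= e.L <= length_range[1]):
            continue
        c = rows.setdefault(e.L, dict.fromkeys(COUNT_COLUMNS, 0))
        c["n_total"] += 1
        if e.k >= 1:
            c["n_any"] += 1
        if e.first:
            c["n_first"] += 1
        if e.last:
            c["n_last"] += 1
        if e.first and e.last:
            c["n_both"] += 1
        if e.first or e.last:
            c["n_first_or_last"] += 1
        if any(e.loc_flags[1:-1]):
            c["n_intermediate"] += 1
        if e.k >= 2:
            c["n_two_plus"] += 1
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "L"
    return df


def _eligible(efps, L, statistic):
    kmin = 1 if statistic == STAT_FIRST_OR_LAST else 2
    return [e for e in efps if (L is None or e.L == L) and e.k >= kmin]


def _hit(e: FluxPattern, statistic: str) -> bool:
    if statistic == STAT_FIRST_OR_LAST:
        return e.first or e.last
    if statistic == STAT_FIRST_AND_LAST:
        return e.first and e.last
    raise ValueError(f"unknown statistic {statistic!r}")


def ratio_first_or_last(efps, L: int) -> float:
    """n_first_or_last(L) / n_any(L) among EFPs of length L."""
    elig = _eligible(efps, L, STAT_FIRST_OR_LAST)
    if not elig:
        raise UndefinedRatioError(f"no EFP of length {L} with >=1 localized enzyme")
    return sum(_hit(e, STAT_FIRST_OR_LAST) for e in elig) / len(elig)


def ratio_first_and_last(efps, L: int) -> float:
    """n_both(L) / n_two_plus(L) among EFPs of length L."""
    elig = _eligible(efps, L, STAT_FIRST_AND_LAST)
    if not elig:
        raise UndefinedRatioError(f"no EFP of length {L} with >=2 localized enzymes")
    return sum(_hit(e, STAT_FIRST_AND_LAST) for e in elig) / len(elig)


def _terminal_hit_probability(L: int, k: int, statistic: str) -> float:
    """Exact probability of a terminal hit under uniform flag placement."""
    if statistic == STAT_FIRST_OR_LAST:
        # 1 - P(no flag at either terminal)
        return 1.0 - math.comb(L - 2, k) / math.comb(L, k) if L >= 2 else 1.0
    if statistic == STAT_FIRST_AND_LAST:
        return (k * (k - 1)) / (L * (L - 1))
    raise ValueError(f"unknown statistic {statistic!r}")


def permutation_null(efps, L, statistic: str = STAT_FIRST_OR_LAST,
                     n_perm: int = 10000, seed=None,
                     method: str = "group") -> NullSummary:
    """Permutation null for a terminal-localization ratio.

    Each draw independently re-places, within every eligible EFP, its k
    localized flags uniformly over the L positions (k preserved per EFP) and
    recomputes the ratio.  ``L=None`` pools all lengths.

    ``method="shuffle"`` performs the literal per-EFP re-placement;
    ``method="group"`` draws, for each (L, k) stratum of m EFPs, a
    Binomial(m, p) hit count with p the exact uniform-placement terminal-hit
    probability — the per-EFP hit indicators are iid Bernoulli(p), so the
    sampled distribution is identical and the cost is per-stratum rather
    than per-EFP.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    elig = _eligible(efps, L, statistic)
    if not elig:
        raise UndefinedRatioError(f"no eligible EFP for {statistic} at L={L}")
    m_total = len(elig)
    observed = sum(_hit(e, statistic) for e in elig) / m_total
    rng = np.random.default_rng(seed)

    if method == "group":
        strata = {}
        for e in elig:
            strata[(e.L, e.k)] = strata.get((e.L, e.k), 0) + 1
        counts = np.zeros(n_perm, dtype=np.int64)
        for (Ls, ks), m in sorted(strata.items()):
            p = _terminal_hit_probability(Ls, ks, statistic)
            counts += rng.binomial(m, p, size=n_perm)
        samples = counts / m_total
    elif method == "shuffle":
        samples = np.empty(n_perm, dtype=float)
        for d in range(n_perm):
            hits = 0
            for e in elig:
                pos = rng.choice(e.L, size=e.k, replace=False)
                if statistic == STAT_FIRST_OR_LAST:
                    hits += bool((pos == 0).any() or (pos == e.L - 1).any())
                else:
                    hits += bool((pos == 0).any() and (pos == e.L - 1).any())
            samples[d] = hits / m_total
    else:
        raise ValueError(f"unknown method {method!r}")

    name = f"{statistic}[L={'all' if L is None else L}]"
    return summarize_null(name, observed, samples, seed=seed)


def estimate_q(efps, condition: str = "localized") -> pd.DataFrame:
    """Empirical q(k;L): probability an EFP of length L has exactly k flags.

    ``condition="localized"`` (default) restricts to EFPs with k >= 1, the
    conditioning under which the observed terminal ratios are defined;
    ``condition="all"`` keeps k = 0 EFPs in the denominator (and the table).
    """
    if not efps:
        raise ValueError("no EFPs")
    if condition not in ("localized", "all"):
        raise ValueError(f"unknown condition {condition!r}")
    kmin = 1 if condition == "localized" else 0
    counts = {}
    for e in efps:
        if e.k >= kmin:
            counts[(e.L, e.k)] = counts.get((e.L, e.k), 0) + 1
    rows = []
    totals = {}
    for (L, k), c in counts.items():
        totals[L] = totals.get(L, 0) + c
    for (L, k), c in sorted(counts.items()):
        rows.append({"L": L, "k": k, "n": c, "q": c / totals[L]})
    return pd.DataFrame(rows, columns=["L", "k", "n", "q"])


def analytic_null(q_table: pd.DataFrame, L: int) -> AnalyticNull:
    """Closed-form terminal probabilities at length L from a q(k;L) table."""
    sub = q_table[q_table["L"] == L]
    if sub.empty:
        raise KeyError(f"q-table has no rows for L={L}")
    p_first = float(sum(r.k / L * r.q for r in sub.itertuples()))
    p_both = float(sum(r.k * (r.k - 1) / (L * (L - 1)) * r.q
                       for r in sub.itertuples() if r.k >= 2))
    p_first_or_last = 2.0 * p_first - p_both
    return AnalyticNull(L=L, p_first=p_first, p_last=p_first,
                        p_both=p_both, p_first_or_last=p_first_or_last)


def efp_report(efps, n_perm: int = 10000, seed=None,
               length_range=DEFAULT_LENGTH_RANGE,
               q_condition: str = "localized") -> pd.DataFrame:
    """Per-length table of observed ratio, closed-form null, permutation null.

    One row per (length, statistic); lengths with an undefined observed
    ratio are kept with ``defined=False`` rather than dropped.  With
    ``n_perm=0`` the permutation columns are NaN (analytic columns remain).
    """
    rows = []
    if not efps:
        return pd.DataFrame(columns=["L", "statistic", "n_eligible", "observed",
                                     "analytic", "perm_null_mean", "perm_null_sd",
                                     "perm_p", "defined"])
    q = estimate_q(efps, condition=q_condition)
    lengths = range(length_range[0], length_range[1] + 1)
    rng = np.random.default_rng(seed)
    for L in lengths:
        for stat in (STAT_FIRST_OR_LAST, STAT_FIRST_AND_LAST):
            elig = _eligible(efps, L, stat)
            row = {"L": L, "statistic": stat, "n_eligible": len(elig),
                   "observed": np.nan, "analytic": np.nan,
                   "perm_null_mean": np.nan, "perm_null_sd": np.nan,
                   "perm_p": np.nan, "defined": bool(elig)}
            if elig:
                row["observed"] = sum(_hit(e, stat) for e in elig) / len(elig)
                an = analytic_null(q, L)
                row["analytic"] = (an.p_first_or_last if stat == STAT_FIRST_OR_LAST
                                   else an.p_both)
                if n_perm > 0:
                    ns = permutation_null(efps, L, stat, n_perm=n_perm,
                                          seed=int(rng.integers(2**31)))
                    row["perm_null_mean"] = ns.null_mean
                    row["perm_null_sd"] = ns.null_sd
                    row["perm_p"] = ns.p
            rows.append(row)
    return pd.DataFrame(rows)
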