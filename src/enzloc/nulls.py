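"""Shared summary container for randomization nulls.

Every Monte-Carlo null in the package (flag permutation within flux
patterns, random node groups, degree-preserving surrogates) reports through
:class:`NullSummary`: the observed statistic, the null sample's mean and
standard deviation, a z-score against that empirical null, and a one-sided
empirical p-value with add-one smoothing, ``p = (1 + #{draws >= observed}) /
(1 + n_draws)``, so that p is never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# tolerance when counting draws >= observed, so float round-off does not
# silently drop exact ties
_TIE_EPS = 1e-12


@dataclass
class NullSummary:
    statistic: str
    observed: float
    null_mean: float
    null_sd: float
    z: float
    p: float
    n_draws: int
    seed: int | None = None
    degenerate: bool = False
    samples: np.ndarray | None = None

    def __repr__(self):  # samples elided: they can be huge
        return (
            f"NullSummary({self.statistic!r}, observed={self.observed:.6g}, "
            f"null_mean={self.null_mean:.6g}, null_sd={self.null_sd:.6g}, "
            f"z={self.z:.4g}, p={self.p:.4g}, n_draws={self.n_draws}, "
            f"degenerate={self.degenerate})"
        )


def summarize_null(statistic: str, observed: float, samples, seed=None,
                   keep_samples: bool = False) -> NullSummary:
    """Summarize null draws for a one-sided (observed high) alternative."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("no null draws")
    null_mean = float(samples.mean())
    null_sd = float(samples.std(ddof=1)) if samples.size > 1 else 0.0
    degenerate = not np.isfinite(null_sd) or null_sd == 0.0
    z = float("nan") if degenerate else (observed - null_mean) / null_sd
    p = float((1 + np.count_nonzero(samples >= observed - _TIE_EPS)) / (1 + samples.size))
    return NullSummary(
        statistic=statistic,
        observed=float(observed),
        null_mean=null_mean,
        null_sd=null_sd,
        z=z,
        p=p,
        n_draws=int(samples.size),
        seed=seed,
        degenerate=degenerate,
        samples=samples if keep_samples else None,
    )
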