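"""Convergence between the two populations' elevation responses.

A gene shows convergent cis-regulatory (or expression) evolution when the
highland-vs-lowland effect is significant in both populations and points in
the same direction.  Overlap significance is assessed with an upper-tail
hypergeometric test: of N assayed background genes, K significant in one
population and n in the other, how surprising is an overlap of x?
Effect-size concordance is quantified by comparing the Pearson correlation
of posterior mean effects over the convergent subset with that over all
assayed genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom


@dataclass
class OverlapTest:
    """Hypergeometric overlap summary."""

    N: int  # background genes assayed
    K: int  # significant in population 1
    n: int  # significant in population 2
    x: int  # overlap
    p: float  # upper-tail P(X >= x)

    def overlap_percent(self) -> float:
        """Overlap as a percentage of the smaller significant list."""
        smaller = min(self.K, self.n)
        return 100.0 * self.x / smaller if smaller else float("nan")


def hypergeom_overlap(N: int, K: int, n: int, x: int) -> float:
    """Upper-tail hypergeometric probability P(X >= x).

    X counts the overlap of a random size-n subset with a fixed size-K
    subset of N genes.  Computed in log space (survival function of
    ``scipy.stats.hypergeom``) for numerical stability; ``x = 0`` gives
    exactly 1.
    """
    for name, v in (("N", N), ("K", K), ("n", n), ("x", x)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a nonnegative integer, got {v}")
    if K > N or n > N:
        raise ValueError("K and n cannot exceed N")
    if x > min(K, n):
        raise ValueError(f"overlap x={x} exceeds min(K, n)={min(K, n)}")
    if x == 0:
        return 1.0
    return float(np.exp(hypergeom.logsf(x - 1, N, K, n)))


def overlap_test(N: int, K: int, n: int, x: int) -> OverlapTest:
    return OverlapTest(N=N, K=K, n=n, x=x, p=hypergeom_overlap(N, K, n, x))


def classify_convergent(
    lfsr1: Sequence[float],
    lfsr2: Sequence[float],
    pm1: Sequence[float],
    pm2: Sequence[float],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Flag convergent and significant-discordant genes.

    Convergent: lfsr below ``alpha`` in both populations and posterior
    means of the same (nonzero) sign.  Discordant: significant in both but
    with opposite signs.  Inputs are aligned per-gene vectors.
    """
    arrays = [np.asarray(a, float) for a in (lfsr1, lfsr2, pm1, pm2)]
    if len({a.shape for a in arrays}) != 1:
        raise ValueError("input vectors must have equal length")
    l1, l2, p1, p2 = arrays
    with np.errstate(invalid="ignore"):
        sig_both = (l1 < alpha) & (l2 < alpha)
        s1, s2 = np.sign(p1), np.sign(p2)
        convergent = sig_both & (s1 == s2) & (s1 != 0)
        discordant = sig_both & (s1 == -s2) & (s1 != 0)
    return pd.DataFrame(
        {
            "lfsr_1": l1,
            "lfsr_2": l2,
            "pm_1": p1,
            "pm_2": p2,
            "significant_both": sig_both,
            "convergent": convergent,
            "discordant": discordant,
        }
    )


def effect_concordance(
    pm1: Sequence[float],
    pm2: Sequence[float],
    subset: Sequence[bool],
    min_subset: int = 3,
) -> dict:
    """Pearson correlation of effects over all genes and over a subset.

    Returns ``{"r_all", "r_subset", "n_all", "n_subset"}``; a zero-variance
    input yields NaN with a warning rather than an error.
    """
    p1 = np.asarray(pm1, float)
    p2 = np.asarray(pm2, float)
    sub = np.asarray(subset, bool)
    if not (p1.shape == p2.shape == sub.shape):
        raise ValueError("input vectors must have equal length")
    ok = np.isfinite(p1) & np.isfinite(p2)
    if sub[ok].sum() < min_subset:
        raise ValueError(f"need at least {min_subset} genes in the subset")

    def _corr(a: np.ndarray, b: np.ndarray) -> float:
        if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
            warnings.warn("zero-variance input; correlation undefined")
            return float("nan")
        return float(np.corrcoef(a, b)[0, 1])

    return {
        "r_all": _corr(p1[ok], p2[ok]),
        "r_subset": _corr(p1[ok & sub], p2[ok & sub]),
        "n_all": int(ok.sum()),
        "n_subset": int((ok & sub).sum()),
    }
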