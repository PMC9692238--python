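"""Identity-by-descent classification between sibling F1 plants.

Two plants from the same F1 family share the same maternal (tester) genome
but each inherits one of the two paternal haplotypes per genomic segment.
Where the inherited paternal haplotypes coincide, the plants are identical
by descent (IBD) and carry the same heterozygous-SNP pattern; where they
differ, most heterozygous sites are private to one plant.

The classifier bins each chromosome into a fixed number of blocks with equal
SNP counts, computes per bin the fraction of shared heterozygous sites
(shared count divided by the smaller of the two per-sample het counts), fits
a two-component 1-D Gaussian mixture to those fractions, and labels bins by
the posterior probability of the higher-mean component: IBD above 0.9,
not-IBD below 0.1, ambiguous otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd


@dataclass
class GaussianMixture1D:
    """Two-component (or k-component) univariate Gaussian mixture fit.

    Components are ordered by mean: index 0 is the lower-mean component,
    index k-1 the higher-mean one.  ``posteriors`` column j gives the
    responsibility of component j for each input point.
    """

    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    posteriors: np.ndarray
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = True
    degenerate: bool = False


def bin_snps_equal_count(positions: Sequence[int], n_bins: int = 20) -> list[tuple[int, int]]:
    """Partition sorted SNP positions of one chromosome into ``n_bins``
    contiguous bins with SNP counts differing by at most 1.

    Returns half-open position boundaries ``[(start, end), ...]`` where each
    bin covers positions ``start <= p < end``; the final bin's end is one
    past the last SNP.
    """
    pos = np.asarray(positions)
    if np.any(np.diff(pos) < 0):
        raise ValueError("positions must be sorted")
    n = len(pos)
    if n < n_bins:
        raise ValueError(f"fewer SNPs ({n}) than bins ({n_bins})")
    # equal-count split: first (n % n_bins) bins get one extra SNP
    sizes = np.full(n_bins, n // n_bins)
    sizes[: n % n_bins] += 1
    edges = np.concatenate([[0], np.cumsum(sizes)])
    bounds = []
    for b in range(n_bins):
        start = int(pos[edges[b]])
        end = int(pos[edges[b + 1]]) if b + 1 < n_bins else int(pos[-1]) + 1
        bounds.append((start, end))
    return bounds


def shared_het_fraction(het_a: set, het_b: set) -> float:
    """|A ∩ B| / min(|A|, |B|); NaN if either set is empty. Symmetric."""
    a, b = set(het_a), set(het_b)
    if not a or not b:
        return float("nan")
    return len(a & b) / min(len(a), len(b))


def fit_gmm_1d(
    values: Sequence[float],
    k: int = 2,
    tol: float = 1e-8,
    max_iter: int = 1000,
    min_var: float = 1e-8,
) -> GaussianMixture1D:
    """EM fit of a k-component univariate Gaussian mixture.

    Initialization: component means at evenly spaced quantiles (25th/75th
    percentile for k=2), equal variances set to the overall variance, equal
    weights.  Components in the result are ordered by mean.  If the data are
    (numerically) constant the fit is flagged degenerate and all posteriors
    are uniform (0.5 each for k=2).
    """
    x = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if x.size < 2 * k:
        raise ValueError(f"need at least {2 * k} finite values, got {x.size}")
    overall_var = float(np.var(x))
    if overall_var < min_var:
        post = np.full((x.size, k), 1.0 / k)
        return GaussianMixture1D(
            means=np.full(k, float(np.mean(x))),
            variances=np.full(k, min_var),
            weights=np.full(k, 1.0 / k),
            posteriors=post,
            degenerate=True,
        )
    qs = np.linspace(0, 1, k + 2)[1:-1]
    means = np.quantile(x, qs)
    variances = np.full(k, overall_var)
    weights = np.full(k, 1.0 / k)

    loglik_trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        # E step in log space
        log_dens = (
            -0.5 * np.log(2 * np.pi * variances)[None, :]
            - 0.5 * (x[:, None] - means[None, :]) ** 2 / variances[None, :]
            + np.log(weights)[None, :]
        )
        m = log_dens.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(log_dens - m).sum(axis=1))
        ll = float(lse.sum())
        resp = np.exp(log_dens - lse[:, None])
        # M step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        weights = nk / x.size
        means = (resp * x[:, None]).sum(axis=0) / nk
        variances = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        variances = np.maximum(variances, min_var)
        if loglik_trace and abs(ll - loglik_trace[-1]) < tol:
            loglik_trace.append(ll)
            converged = True
            break
        loglik_trace.append(ll)
    if not converged:
        warnings.warn("GMM EM did not converge; returning best fit found")
    order = np.argsort(means)
    # final responsibilities under the ordered parameters
    means, variances, weights = means[order], variances[order], weights[order]
    log_dens = (
        -0.5 * np.log(2 * np.pi * variances)[None, :]
        - 0.5 * (x[:, None] - means[None, :]) ** 2 / variances[None, :]
        + np.log(weights)[None, :]
    )
    m = log_dens.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(log_dens - m).sum(axis=1))
    resp = np.exp(log_dens - lse[:, None])
    return GaussianMixture1D(
        means=means,
        variances=variances,
        weights=weights,
        posteriors=resp,
        loglik_trace=loglik_trace,
        converged=converged,
    )


def classify_bins(posteriors: Sequence[float], hi: float = 0.90, lo: float = 0.10) -> np.ndarray:
    """Label bins from posterior probabilities of the higher-mean component.

    Strictly above ``hi`` -> "IBD"; strictly below ``lo`` -> "not-IBD";
    everything else (including NaN posteriors) -> "ambiguous".
    """
    p = np.asarray(posteriors, dtype=float)
    out = np.full(p.shape, "ambiguous", dtype=object)
    with np.errstate(invalid="ignore"):
        out[p > hi] = "IBD"
        out[p < lo] = "not-IBD"
    return out


def classify_ibd_pair(
    het_a: pd.DataFrame,
    het_b: pd.DataFrame,
    snp_positions: pd.DataFrame,
    n_bins: int = 20,
    hi: float = 0.90,
    lo: float = 0.10,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> pd.DataFrame:
    """Full IBD classification for one sibling pair.

    ``het_a`` / ``het_b``: frames with ``contig`` and ``position`` of each
    sample's heterozygous calls (SNPs that passed the per-sample ASE
    filters).  ``snp_positions``: the full SNP panel (``contig, position``)
    used to define equal-count bins.  Returns a frame with one row per bin:
    chromosome, bin, start, end, f, posterior, class.

    Shared-het fractions from all chromosomes of the pair are pooled into a
    single two-component mixture fit; bins where either sample has no het
    site are excluded from the fit and labeled ambiguous.
    """
    set_a = {(c, p) for c, p in zip(het_a["contig"], het_a["position"])}
    set_b = {(c, p) for c, p in zip(het_b["contig"], het_b["position"])}
    rows = []
    for contig, sub in snp_positions.groupby("contig"):
        pos = np.sort(sub["position"].unique())
        if len(pos) < n_bins:
            raise ValueError(f"chromosome {contig}: fewer SNPs ({len(pos)}) than bins ({n_bins})")
        for b, (start, end) in enumerate(bin_snps_equal_count(pos, n_bins)):
            in_a = {p for (c, p) in set_a if c == contig and start <= p < end}
            in_b = {p for (c, p) in set_b if c == contig and start <= p < end}
            rows.append(
                {
                    "chromosome": contig,
                    "bin": b,
                    "start": start,
                    "end": end,
                    "f": shared_het_fraction(in_a, in_b),
                }
            )
    out = pd.DataFrame(rows)
    finite = np.isfinite(out["f"].to_numpy())
    if finite.sum() >= 4:
        gmm = fit_gmm_1d(out.loc[finite, "f"], k=2, tol=tol, max_iter=max_iter)
        post = np.full(len(out), np.nan)
        post[finite] = gmm.posteriors[:, -1]
        out["posterior"] = post
    else:
        out["posterior"] = np.nan
    out["class"] = classify_bins(out["posterior"], hi=hi, lo=lo)
    return out
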