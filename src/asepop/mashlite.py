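"""Multivariate adaptive shrinkage meta-analysis across conditions.

Given per-gene effect estimates ``Bhat`` and standard errors ``Shat`` over R
conditions (here: population-by-site:tissue elevation effects), the model
places a mixture-of-multivariate-normals prior on the true effects:

    b_j ~ sum_{k,w} pi_{k,w} N(0, w * U_k)    (+ a point mass at zero)

where the U_k are unit-scale covariance "shapes" — the canonical set (null,
identity, per-condition singletons, equal effects across conditions, and
partially shared effects with off-diagonal 0.25/0.5/0.75) plus data-driven
shapes from a principal-component decomposition of the strongest signals —
and w ranges over a geometric scale grid.  Observations are modeled as
``Bhat_j ~ N(b_j, V_j)`` with ``V_j = diag(Shat_j) C diag(Shat_j)`` for a
residual correlation matrix C.  Mixture weights are fit by maximum
(penalized) likelihood EM with a null-biased prior; posterior means, SDs
and local false sign rates (lfsr) follow from the conjugate normal algebra.

The lfsr of condition r is ``min(P(b_r <= 0 | data), P(b_r >= 0 | data))``,
counting the point mass at zero in both terms — the posterior probability
that a sign call would be wrong or the effect is zero.  Missing conditions
enter with ``Bhat = 0`` and an essentially infinite SE, contributing no
information.

Deliberate simplifications relative to the full mash machinery: data-driven
covariances come from PCA only (no extreme-deconvolution refinement), and
the residual correlation is the empirical correlation of weak-signal
z-scores shrunk toward the identity rather than the EM estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

_IMPUTE_SHAT = 1e6


@dataclass
class EffectTable:
    """Per-gene effect sizes and standard errors over R conditions."""

    bhat: pd.DataFrame
    shat: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.bhat.columns) != list(self.shat.columns) or len(self.bhat) != len(self.shat):
            raise ValueError("Bhat and Shat must share shape and condition names")
        bad = (self.shat.to_numpy() <= 0) & np.isfinite(self.shat.to_numpy())
        if bad.any():
            raise ValueError("Shat must be positive where observed")

    @property
    def conditions(self) -> list[str]:
        return list(self.bhat.columns)

    @property
    def mask(self) -> np.ndarray:
        """True where the (gene, condition) cell is observed."""
        return np.isfinite(self.bhat.to_numpy()) & np.isfinite(self.shat.to_numpy())

    def imputed(self) -> tuple[np.ndarray, np.ndarray]:
        """(Bhat, Shat) arrays with missing cells set to (0, 1e6)."""
        m = self.mask
        b = np.where(m, np.nan_to_num(self.bhat.to_numpy(float)), 0.0)
        s = np.where(m, self.shat.to_numpy(float), _IMPUTE_SHAT)
        return b, s


@dataclass
class MashModel:
    covariances: list          # [(name, U)] excluding the null
    grid: np.ndarray           # omega scale grid
    pi: pd.Series              # weights indexed by "null" and "name@omega"
    C: np.ndarray              # residual correlation (R x R)
    loglik: float = np.nan
    conditions: list = field(default_factory=list)

    def component_iter(self):
        """Yield (label, omega, U) for every non-null mixture component."""
        for name, U in self.covariances:
            for w in self.grid:
                yield f"{name}@{w:.6g}", w, U


@dataclass
class MashResult:
    posterior_mean: pd.DataFrame
    posterior_sd: pd.DataFrame
    lfsr: pd.DataFrame
    overall_lfsr: pd.Series     # min over conditions per gene
    model: MashModel


# ---------------------------------------------------------------------------
# residual correlation


def estimate_residual_correlation(
    table: EffectTable, z_max: float = 2.0, shrink: float = 0.05, min_genes: int = 50
) -> np.ndarray:
    """Empirical correlation of weak-signal z-scores, shrunk toward identity.

    Uses genes observed in all conditions with |z| < ``z_max`` everywhere —
    approximately null genes, whose z-score correlation reflects shared
    noise rather than shared signal.  A simplification of the mash EM
    estimator of the residual correlation.
    """
    r = len(table.conditions)
    b, s = table.bhat.to_numpy(float), table.shat.to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = b / s
    full = table.mask.all(axis=1)
    weak = full & (np.abs(np.where(np.isfinite(z), z, np.inf)) < z_max).all(axis=1)
    if weak.sum() < min_genes:
        warnings.warn(
            f"only {int(weak.sum())} genes qualify for residual-correlation "
            "estimation; returning identity"
        )
        return np.eye(r)
    c = np.corrcoef(z[weak], rowvar=False)
    c = (1.0 - shrink) * c + shrink * np.eye(r)
    np.fill_diagonal(c, 1.0)
    return c


# ---------------------------------------------------------------------------
# covariance shapes


def _normalize_cov(u: np.ndarray) -> np.ndarray:
    d = np.max(np.diag(u))
    return u / d if d > 0 else u


def canonical_covariances(r: int) -> list[tuple[str, np.ndarray]]:
    """The canonical unit-scale shapes (deduplicated; null excluded)."""
    covs: list[tuple[str, np.ndarray]] = [("identity", np.eye(r))]
    for i in range(r):
        u = np.zeros((r, r))
        u[i, i] = 1.0
        covs.append((f"singleton_{i + 1}", u))
    covs.append(("equal_effects", np.ones((r, r))))
    for c in (0.25, 0.5, 0.75):
        u = np.full((r, r), c)
        np.fill_diagonal(u, 1.0)
        covs.append((f"het_{c}", u))
    # drop duplicates (R=1 collapses everything onto the scalar 1)
    seen, out = set(), []
    for name, u in covs:
        key = tuple(np.round(u, 10).ravel())
        if key not in seen:
            seen.add(key)
            out.append((name, u))
    return out


def build_covariances(
    table: EffectTable,
    z_strong: float = 3.3,
    n_pcs: int = 2,
) -> list[tuple[str, np.ndarray]]:
    """Canonical shapes plus data-driven PCA shapes from strong genes.

    Strong genes are selected by |z| > ``z_strong`` in at least one observed
    condition (a first-pass proxy for per-condition significance, since lfsr
    is unavailable before fitting).  From their z-score matrix the top
    ``n_pcs`` principal components give rank-1 shapes, plus the rank-n_pcs
    reconstruction; each is normalized to unit maximum diagonal.  With fewer
    strong genes than ``n_pcs`` the canonical set is returned alone, with a
    warning.
    """
    r = len(table.conditions)
    covs = canonical_covariances(r)
    b, s = table.bhat.to_numpy(float), table.shat.to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(table.mask, b / s, 0.0)
    strong = (np.abs(z) > z_strong).any(axis=1)
    if strong.sum() < max(n_pcs, 2):
        warnings.warn(
            f"only {int(strong.sum())} strong genes; using canonical covariances only"
        )
        return covs
    zs = z[strong]
    _, svals, vt = np.linalg.svd(zs, full_matrices=False)
    n_pcs = min(n_pcs, vt.shape[0])
    for i in range(n_pcs):
        u = np.outer(vt[i], vt[i]) * svals[i] ** 2 / zs.shape[0]
        covs.append((f"pca_{i + 1}", _normalize_cov(u)))
    recon = (vt[:n_pcs].T * (svals[:n_pcs] ** 2 / zs.shape[0])) @ vt[:n_pcs]
    covs.append((f"pca_rank{n_pcs}", _normalize_cov(recon)))
    return covs


def default_grid(table: EffectTable, ratio: float = 2.0) -> np.ndarray:
    """Geometric omega grid from (min Shat / 10)^2 to (4 max |Bhat|)^2."""
    m = table.mask
    s = table.shat.to_numpy(float)
    b = table.bhat.to_numpy(float)
    s_obs = s[m]
    b_obs = np.abs(b[m])
    if s_obs.size == 0:
        raise ValueError("no observed effects")
    lo = (s_obs.min() / 10.0) ** 2
    hi = max((4.0 * b_obs.max()) ** 2, lo * ratio)
    n = int(np.ceil(np.log(hi / lo) / np.log(ratio))) + 1
    return lo * ratio ** np.arange(n)


# ---------------------------------------------------------------------------
# likelihood and EM


def _component_loglik(
    b: np.ndarray, s: np.ndarray, C: np.ndarray, covs, grid
) -> tuple[np.ndarray, list[str]]:
    """Log-likelihood matrix (genes x components); component 0 is the null."""
    g, r = b.shape
    V = s[:, :, None] * C[None, :, :] * s[:, None, :]
    labels = ["null"]
    cols = [_mvn_logpdf_batch(b, V)]
    for name, U in covs:
        for w in grid:
            cols.append(_mvn_logpdf_batch(b, V + w * U[None, :, :]))
            labels.append(f"{name}@{w:.6g}")
    return np.column_stack(cols), labels


def _mvn_logpdf_batch(b: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """log N(b_j; 0, sigma_j) for stacked (G, R) observations."""
    g, r = b.shape
    sign, logdet = np.linalg.slogdet(sigma)
    if np.any(sign <= 0):
        sigma = sigma + 1e-10 * np.eye(r)[None]
        sign, logdet = np.linalg.slogdet(sigma)
    sol = np.linalg.solve(sigma, b[:, :, None])[:, :, 0]
    quad = np.einsum("gr,gr->g", b, sol)
    return -0.5 * (r * np.log(2 * np.pi) + logdet + quad)


def fit_mixture_em(
    loglik: np.ndarray,
    null_bias: float = 10.0,
    tol_per_gene: float = 1e-8,
    max_iter: int = 20000,
) -> tuple[np.ndarray, float]:
    """EM for mixture weights with fixed component likelihoods.

    Maximizes the penalized log-likelihood with a Dirichlet prior putting
    pseudo-weight ``null_bias`` on the null component (conservative default,
    as in mash).  Returns (pi, loglik-without-penalty).
    """
    g, k = loglik.shape
    bad = ~np.isfinite(loglik).any(axis=1)
    if bad.any():
        warnings.warn(f"excluding {int(bad.sum())} gene(s) with non-finite likelihoods")
        loglik = loglik[~bad]
        g = loglik.shape[0]
    if g == 0:
        raise ValueError("no genes with finite likelihoods")
    prior = np.ones(k)
    prior[0] = null_bias
    # likelihoods are fixed: precompute row-scaled densities once so each EM
    # step is two matrix-vector products
    row_max = loglik.max(axis=1, keepdims=True)
    dens = np.exp(np.where(np.isfinite(loglik), loglik, -np.inf) - row_max)
    pi = np.full(k, 1.0 / k)
    last = -np.inf
    for _ in range(max_iter):
        mix = dens @ pi                          # per-gene mixture density
        nk = pi * (dens.T @ (1.0 / mix)) + prior - 1.0
        pi_new = np.maximum(nk, 0.0)
        pi_new /= pi_new.sum()
        ll = np.log(mix).sum() + float(row_max.sum()) + (
            (prior - 1.0) * np.log(np.maximum(pi_new, 1e-300))
        ).sum()
        pi = pi_new
        if abs(ll - last) < tol_per_gene * g:
            break
        last = ll
    ll_plain = float(np.log(dens @ pi).sum() + row_max.sum())
    return pi, ll_plain


def fit_mash(
    table: EffectTable,
    covariances: Optional[list] = None,
    grid: Optional[np.ndarray] = None,
    C: Optional[np.ndarray] = None,
    null_bias: float = 10.0,
) -> MashModel:
    """Fit the mixture model: covariances, grid, residual correlation, EM."""
    if C is None:
        C = estimate_residual_correlation(table)
    if covariances is None:
        covariances = build_covariances(table)
    if grid is None:
        grid = default_grid(table)
    b, s = table.imputed()
    loglik, labels = _component_loglik(b, s, C, covariances, grid)
    pi, ll = fit_mixture_em(loglik, null_bias=null_bias)
    return MashModel(
        covariances=covariances,
        grid=np.asarray(grid, float),
        pi=pd.Series(pi, index=labels, name="pi"),
        C=C,
        loglik=ll,
        conditions=table.conditions,
    )


# ---------------------------------------------------------------------------
# posterior summaries


def posterior_summaries(table: EffectTable, model: MashModel) -> MashResult:
    """Posterior means, SDs and local false sign rates per gene x condition.

    For each non-null component the posterior of the true effect is the
    conjugate multivariate-normal conditional; mixing over components with
    the per-gene responsibilities gives the reported moments.  The null
    component's point mass at zero counts toward both tails of the sign
    probability, so ``lfsr = min(P(b <= 0), P(b >= 0))`` equals 1 when the
    posterior is entirely at zero.
    """
    b, s = table.imputed()
    g, r = b.shape
    C = model.C
    V = s[:, :, None] * C[None, :, :] * s[:, None, :]

    # responsibilities under the fitted weights
    loglik, labels = _component_loglik(
        b, s, C, model.covariances, model.grid
    )
    pi = model.pi.reindex(labels).to_numpy(float)
    lw = loglik + np.log(np.maximum(pi, 1e-300))[None, :]
    m = lw.max(axis=1, keepdims=True)
    resp = np.exp(lw - (m[:, 0] + np.log(np.exp(lw - m).sum(axis=1)))[:, None])

    post_mean = np.zeros((g, r))
    post_m2 = np.zeros((g, r))
    p_neg = np.zeros((g, r))
    p_zero = np.zeros((g, r))

    # null component: point mass at zero in every condition
    p_zero += resp[:, [0]]

    ci = 1
    for label, w, U in model.component_iter():
        rk = resp[:, ci]
        ci += 1
        if rk.max() < 1e-12:
            continue
        wU = w * U
        A = V + wU[None, :, :]
        sol_b = np.linalg.solve(A, b[:, :, None])[:, :, 0]     # A^{-1} Bhat
        mu1 = sol_b @ wU.T                                     # wU A^{-1} Bhat
        M = np.linalg.solve(A, np.broadcast_to(wU, (g, r, r)))  # A^{-1} wU
        var1 = np.diag(wU)[None, :] - np.einsum("rj,gjr->gr", wU, M)
        var1 = np.maximum(var1, 0.0)
        post_mean += rk[:, None] * mu1
        post_m2 += rk[:, None] * (var1 + mu1 ** 2)
        sd1 = np.sqrt(var1)
        pointmass = sd1 <= 1e-12
        with np.errstate(divide="ignore", invalid="ignore"):
            cdf0 = norm.cdf(0.0, loc=mu1, scale=np.where(pointmass, 1.0, sd1))
        p_neg += rk[:, None] * np.where(pointmass, (mu1 < 0).astype(float), cdf0)
        p_zero += rk[:, None] * (pointmass & (np.abs(mu1) <= 1e-12)).astype(float)

    post_var = np.maximum(post_m2 - post_mean ** 2, 0.0)
    p_pos = np.clip(1.0 - p_neg - p_zero, 0.0, 1.0)
    lfsr = np.minimum(p_neg + p_zero, p_pos + p_zero)
    lfsr = np.clip(lfsr, 0.0, 1.0)

    idx, cond = table.bhat.index, table.conditions
    mask = table.mask
    pm = pd.DataFrame(np.where(mask, post_mean, np.nan), index=idx, columns=cond)
    psd = pd.DataFrame(np.where(mask, np.sqrt(post_var), np.nan), index=idx, columns=cond)
    lf = pd.DataFrame(np.where(mask, lfsr, np.nan), index=idx, columns=cond)
    overall = lf.min(axis=1, skipna=True)
    return MashResult(
        posterior_mean=pm,
        posterior_sd=psd,
        lfsr=lf,
        overall_lfsr=overall,
        model=model,
    )


def mash_analysis(
    table: EffectTable,
    null_bias: float = 10.0,
    C: Optional[np.ndarray] = None,
) -> MashResult:
    """Convenience wrapper: fit the model and compute posterior summaries."""
    model = fit_mash(table, C=C, null_bias=null_bias)
    return posterior_summaries(table, model)
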