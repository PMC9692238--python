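"""Precision-weighted linear modeling of expression and ASE ratios.

The same engine drives both analysis paths:

* the total-expression path normalizes counts to log2 counts-per-million and
  derives per-observation precision weights from the classic voom
  mean-variance trend;
* the ASE path models per-gene log2 allelic ratios, whose sampling variance
  depends on the ASE-informative read total of that gene in that sample
  rather than on expression level alone.  A lowess trend of sqrt(residual
  SD) against log2 normalized total count is fit across genes and evaluated
  at each observation's own total to predict its variance; the weight is the
  inverse predicted variance, and exactly zero wherever either allele has
  zero reads.

Per-gene precision-weighted least squares then yields coefficients,
unscaled standard deviations and residual variances, and empirical-Bayes
moderation shrinks the residual variances toward a common prior estimated
by moment matching on the log residual variances (a scaled-F model),
giving moderated t-statistics with augmented degrees of freedom.

The design matrix mirrors the field experiment: block (where more than one
exists), sampling team, a per-team cubic polynomial of the order in which
plants were sampled (time-of-day proxy), a population-by-elevation-class
interaction whose named columns are the highland-vs-lowland contrast within
each population, and population-by-latitude terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

ELEV_PREFIX = "elev_"


# ---------------------------------------------------------------------------
# design matrix


def _orthogonal_poly(x: np.ndarray, degree: int) -> np.ndarray:
    """Orthogonal polynomial basis of ``x`` (R ``poly()``-style, sans intercept)."""
    x = np.asarray(x, dtype=float)
    degree = min(degree, len(np.unique(x)) - 1)
    if degree < 1:
        return np.zeros((len(x), 0))
    xm = x - x.mean()
    raw = np.vander(xm, degree + 1, increasing=True)
    q, _ = np.linalg.qr(raw)
    basis = q[:, 1 : degree + 1]
    norms = np.sqrt((basis ** 2).sum(axis=0))
    basis = basis / norms
    # canonical sign (row-order invariant): positive loading on x^k
    for j in range(basis.shape[1]):
        s = basis[:, j] @ xm ** (j + 1)
        if s < 0:
            basis[:, j] = -basis[:, j]
    return basis


def build_design(
    metadata: pd.DataFrame,
    cell_scores: Optional[pd.DataFrame] = None,
    poly_degree: int = 3,
) -> pd.DataFrame:
    """Build the sample x covariate design matrix for one site:tissue.

    Columns: intercept; block dummies (only if the tissue spans more than
    one block); team dummies; per-team orthogonal polynomial of field order
    (``poly_degree`` columns per team); one population main-effect dummy per
    non-reference population; ``elev_<population>`` highland-contrast
    dummies, one per population; ``lat_<population>`` within-population
    centered latitude; optional cell-composition covariates (one column per
    score, aligned on sample).

    Raises if the assembled matrix is rank deficient, listing the aliased
    columns.
    """
    meta = metadata.reset_index(drop=True)
    n = len(meta)
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(n)}

    if "block" in meta.columns and meta["block"].nunique() > 1:
        blocks = sorted(meta["block"].unique())
        for b in blocks[1:]:
            cols[f"block_{b}"] = (meta["block"] == b).to_numpy(float)

    teams = sorted(meta["team"].unique()) if "team" in meta.columns else []
    for t in teams[1:]:
        cols[f"team_{t}"] = (meta["team"] == t).to_numpy(float)

    if "field_order" in meta.columns and teams:
        for t in teams:
            mask = (meta["team"] == t).to_numpy()
            basis = _orthogonal_poly(meta.loc[mask, "field_order"].to_numpy(), poly_degree)
            for d in range(basis.shape[1]):
                col = np.zeros(n)
                col[mask] = basis[:, d]
                cols[f"order_team{t}_p{d + 1}"] = col

    pops = sorted(meta["population"].unique())
    for p in pops[1:]:
        cols[f"pop_{p}"] = (meta["population"] == p).to_numpy(float)
    for p in pops:
        in_pop = (meta["population"] == p).to_numpy()
        cols[f"{ELEV_PREFIX}{p}"] = (
            in_pop & (meta["elevation"] == "Highland").to_numpy()
        ).astype(float)
    if "latitude" in meta.columns:
        for p in pops:
            in_pop = (meta["population"] == p).to_numpy()
            lat = np.zeros(n)
            lat[in_pop] = (
                meta.loc[in_pop, "latitude"] - meta.loc[in_pop, "latitude"].mean()
            )
            cols[f"lat_{p}"] = lat

    design = pd.DataFrame(cols, index=meta["sample"])
    if cell_scores is not None:
        cs = cell_scores.reindex(design.index)
        if cs.isna().any().any():
            raise ValueError("cell_scores missing values for some samples")
        for c in cs.columns:
            design[f"cell_{c}"] = cs[c].to_numpy(float)

    x = design.to_numpy()
    rank = np.linalg.matrix_rank(x)
    if rank < design.shape[1]:
        _, r = np.linalg.qr(x)
        diag = np.abs(np.diag(r))
        aliased = [design.columns[i] for i in range(len(diag)) if diag[i] < 1e-8 * diag.max()]
        raise ValueError(f"design matrix is rank deficient; aliased columns: {aliased}")
    return design


# ---------------------------------------------------------------------------
# variance trends


@dataclass
class VarianceTrend:
    """Lowess trend of sqrt(residual SD) against log2 normalized count."""

    x: np.ndarray  # knot abscissae, strictly increasing
    y: np.ndarray  # fitted sqrt-residual-SD ordinates, positive

    def __post_init__(self) -> None:
        order = np.argsort(self.x)
        x, y = np.asarray(self.x, float)[order], np.asarray(self.y, float)[order]
        keep = np.concatenate([[True], np.diff(x) > 0])
        self.x, self.y = x[keep], np.maximum(y[keep], 1e-6)

    def __call__(self, at: np.ndarray) -> np.ndarray:
        """Linear interpolation with endpoint clamping."""
        return np.interp(at, self.x, self.y)


def _ols_residual_sd(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Vectorized OLS of every row of ``y`` (genes) on ``x``; returns
    (residual SD per gene, fitted values, residual df)."""
    pinv = np.linalg.pinv(x)
    beta = y @ pinv.T
    fitted = beta @ x.T
    resid = y - fitted
    df = y.shape[1] - np.linalg.matrix_rank(x)
    if df < 1:
        raise ValueError("fewer than 1 residual degree of freedom")
    s = np.sqrt((resid ** 2).sum(axis=1) / df)
    return s, fitted, df


def voom_counts(
    counts: pd.DataFrame,
    factors: pd.Series,
    design: pd.DataFrame,
    span: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame, VarianceTrend]:
    """Standard voom: log2-CPM transform plus mean-variance precision weights.

    Returns ``(log2cpm, weights, trend)``.  Library sizes are column sums
    scaled by the TMM factors; ``y = log2((count + 0.5) / (lib + 1) * 1e6)``.
    The lowess trend of sqrt(residual SD) on mean log2 count is evaluated at
    each observation's fitted log2 count and raised to the -4th power.
    """
    x = design.loc[counts.columns].to_numpy(float)
    if counts.shape[1] - np.linalg.matrix_rank(x) < 2:
        raise ValueError("fewer than 2 residual degrees of freedom")
    lib = counts.sum(axis=0).to_numpy(float) * factors.loc[counts.columns].to_numpy(float)
    y = np.log2((counts.to_numpy(float) + 0.5) / (lib + 1.0)[None, :] * 1e6)
    s, fitted, _ = _ols_residual_sd(y, x)
    sx = y.mean(axis=1) + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    sy = np.sqrt(s)
    smooth = sm_lowess(sy, sx, frac=span, it=3, return_sorted=True)
    trend = VarianceTrend(smooth[:, 0], smooth[:, 1])
    fitted_count = fitted + np.log2(lib + 1.0)[None, :] - np.log2(1e6)
    w = trend(fitted_count) ** -4
    log2cpm = pd.DataFrame(y, index=counts.index, columns=counts.columns)
    weights = pd.DataFrame(w, index=counts.index, columns=counts.columns)
    return log2cpm, weights, trend


def ase_voom(
    log2ase: pd.DataFrame,
    total: pd.DataFrame,
    design: pd.DataFrame,
    span: float = 0.5,
    min_df: int = 1,
) -> tuple[pd.DataFrame, VarianceTrend]:
    """ASE adaptation of voom: per-observation weights from the total
    ASE-informative read count.

    1. unweighted per-gene least squares of the design on log2ASE, missing
       cells excluded;
    2. lowess of sqrt(residual SD) against log2 mean normalized total count
       per gene;
    3. the trend evaluated at each observation's own log2 normalized total
       predicts its sqrt-SD; the weight is its -4th power;
    4. missing cells (zero reads for either allele) get weight exactly 0.

    Genes with fewer than ``min_df`` residual degrees of freedom in step 1
    are dropped with a warning; their rows are absent from the returned
    weight matrix.
    """
    x_full = design.loc[log2ase.columns].to_numpy(float)
    y = log2ase.to_numpy(float)
    tot = total.reindex(index=log2ase.index, columns=log2ase.columns).to_numpy(float)
    lib = tot.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("sample(s) with zero total ASE-informative reads")
    norm = tot * (lib.mean() / lib)[None, :]

    s_list, keep_idx = [], []
    mean_log_norm = []
    for gi in range(y.shape[0]):
        obs = np.isfinite(y[gi])
        xg = x_full[obs]
        df = obs.sum() - np.linalg.matrix_rank(xg) if obs.sum() else 0
        if df < min_df:
            continue
        beta, _, _, _ = np.linalg.lstsq(xg, y[gi, obs], rcond=None)
        resid = y[gi, obs] - xg @ beta
        s_list.append(np.sqrt((resid ** 2).sum() / df))
        keep_idx.append(gi)
        mean_log_norm.append(np.log2(norm[gi].mean() + 0.5))
    if len(keep_idx) < len(log2ase):
        warnings.warn(
            f"dropped {len(log2ase) - len(keep_idx)} gene(s) with <{min_df} residual df"
        )
    if len(keep_idx) < 10:
        raise ValueError("too few genes with estimable residual SD for a variance trend")

    sx = np.asarray(mean_log_norm)
    sy = np.sqrt(np.asarray(s_list))
    smooth = sm_lowess(sy, sx, frac=span, it=3, return_sorted=True)
    trend = VarianceTrend(smooth[:, 0], smooth[:, 1])

    keep = np.asarray(keep_idx)
    obs_log = np.log2(norm[keep] + 0.5)
    w = trend(obs_log) ** -4
    w[~np.isfinite(y[keep])] = 0.0
    w[tot[keep] <= 0] = 0.0
    weights = pd.DataFrame(w, index=log2ase.index[keep], columns=log2ase.columns)
    return weights, trend


# ---------------------------------------------------------------------------
# weighted least squares + empirical Bayes


@dataclass
class WeightedFit:
    """Per-gene weighted least-squares results, before/after moderation."""

    coefficients: pd.DataFrame      # genes x columns, log2 units
    stdev_unscaled: pd.DataFrame    # genes x columns
    sigma: pd.Series                # residual SD per gene
    df_residual: pd.Series          # residual df per gene
    design: pd.DataFrame
    dropped: list = field(default_factory=list)
    # filled by ebayes_moderate:
    df_prior: float = np.nan
    s2_prior: float = np.nan
    s2_post: Optional[pd.Series] = None
    t_mod: Optional[pd.DataFrame] = None
    p_value: Optional[pd.DataFrame] = None

    @property
    def se(self) -> pd.DataFrame:
        """Reported standard errors: sqrt(s2.post) * stdev.unscaled."""
        if self.s2_post is None:
            raise ValueError("run ebayes_moderate first")
        return self.stdev_unscaled.mul(np.sqrt(self.s2_post), axis=0)


def fit_weighted_lm(
    y: pd.DataFrame,
    design: pd.DataFrame,
    weights: Optional[pd.DataFrame] = None,
) -> WeightedFit:
    """Per-gene precision-weighted least squares.

    Observations with zero weight (or missing response) are excluded from
    that gene's fit.  Genes with fewer than rank+2 usable observations, or
    with singular weighted normal equations, are dropped with a warning and
    listed in ``fit.dropped``.
    """
    x_full = design.loc[y.columns].to_numpy(float)
    p = x_full.shape[1]
    yv = y.to_numpy(float)
    if weights is None:
        wv = np.ones_like(yv)
    else:
        wv = weights.reindex(index=y.index, columns=y.columns).to_numpy(float)
        wv = np.where(np.isfinite(wv), wv, 0.0)
    wv = np.where(np.isfinite(yv), wv, 0.0)

    genes, betas, sus, sigmas, dfs, dropped = [], [], [], [], [], []
    for gi, gene in enumerate(y.index):
        w = wv[gi]
        use = w > 0
        n_use = int(use.sum())
        if n_use < p + 2:
            dropped.append(gene)
            continue
        sw = np.sqrt(w[use])
        xw = x_full[use] * sw[:, None]
        yw = yv[gi, use] * sw
        xtx = xw.T @ xw
        try:
            xtx_inv = np.linalg.inv(xtx)
        except np.linalg.LinAlgError:
            dropped.append(gene)
            continue
        if np.linalg.matrix_rank(xw) < p:
            dropped.append(gene)
            continue
        beta = xtx_inv @ (xw.T @ yw)
        resid = yw - xw @ beta
        df = n_use - p
        sigma = np.sqrt((resid ** 2).sum() / df)
        genes.append(gene)
        betas.append(beta)
        sus.append(np.sqrt(np.diag(xtx_inv)))
        sigmas.append(sigma)
        dfs.append(df)
    if dropped:
        warnings.warn(f"dropped {len(dropped)} gene(s) with too few usable observations "
                      "or singular weighted normal equations")
    if not genes:
        raise ValueError("no genes could be fit")
    idx = pd.Index(genes, name=y.index.name)
    return WeightedFit(
        coefficients=pd.DataFrame(betas, index=idx, columns=design.columns),
        stdev_unscaled=pd.DataFrame(sus, index=idx, columns=design.columns),
        sigma=pd.Series(sigmas, index=idx, name="sigma"),
        df_residual=pd.Series(dfs, index=idx, name="df_residual"),
        design=design,
        dropped=dropped,
    )


def _trigamma_inverse(z: float, max_iter: int = 50) -> float:
    """Solve trigamma(y) = z for y > 0 (Newton iteration)."""
    if z > 1e7:
        return 1.0 / np.sqrt(z)
    if z < 1e-6:
        return 1.0 / z
    y = 0.5 + 1.0 / z
    for _ in range(max_iter):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / z) / polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_f_prior(sigma2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment-match a scaled-F prior to the observed residual variances.

    Works on ``e_g = log(s_g^2) - digamma(d_g / 2) + log(d_g / 2)``: under
    the model, ``var(e_g) = trigamma(d0/2) + trigamma(d_g/2)``, so the prior
    df solves ``trigamma(d0/2) = var(e) - mean(trigamma(d_g/2))``.  A
    non-positive target means no detectable excess dispersion: the prior df
    is infinite and every variance shrinks fully to ``s0^2``.
    Returns ``(d0, s0^2)``.
    """
    sigma2 = np.asarray(sigma2, float)
    df = np.asarray(df, float)
    ok = np.isfinite(sigma2) & (sigma2 > 0) & (df > 0)
    if ok.sum() < 10:
        raise ValueError("need at least 10 genes with positive residual df")
    s2, d = sigma2[ok], df[ok]
    e = np.log(s2) - digamma(d / 2.0) + np.log(d / 2.0)
    emean = e.mean()
    evar = float(np.var(e, ddof=1)) - float(np.mean(polygamma(1, d / 2.0)))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_2 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_2 = float(np.exp(emean))
    return d0, s0_2


def ebayes_moderate(fit: WeightedFit) -> WeightedFit:
    """Empirical-Bayes moderation of the per-gene variances and t-statistics.

    ``s2.post = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)``; moderated
    ``t = beta / (sqrt(s2.post) * stdev.unscaled)`` on ``d0 + d_g`` df.
    """
    d0, s0_2 = estimate_f_prior(fit.sigma.to_numpy() ** 2, fit.df_residual.to_numpy())
    s2 = fit.sigma.to_numpy() ** 2
    d = fit.df_residual.to_numpy(float)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.full_like(d, np.inf)
    else:
        s2_post = (d0 * s0_2 + d * s2) / (d0 + d)
        df_total = d0 + d
    fit.df_prior, fit.s2_prior = d0, s0_2
    fit.s2_post = pd.Series(s2_post, index=fit.sigma.index, name="s2_post")
    se = fit.stdev_unscaled.to_numpy() * np.sqrt(s2_post)[:, None]
    t = fit.coefficients.to_numpy() / se
    with np.errstate(invalid="ignore"):
        pv = 2.0 * t_dist.sf(np.abs(t), df_total[:, None])
    fit.t_mod = pd.DataFrame(t, index=fit.coefficients.index, columns=fit.coefficients.columns)
    fit.p_value = pd.DataFrame(pv, index=fit.coefficients.index, columns=fit.coefficients.columns)
    return fit


def posterior_variance(s2: float, d: float, s0_2: float, d0: float) -> float:
    """Closed-form posterior variance ``(d0 s0^2 + d s^2) / (d0 + d)``."""
    if np.isinf(d0):
        return s0_2
    return (d0 * s0_2 + d * s2) / (d0 + d)


def extract_elevation_effects(fit: WeightedFit) -> pd.DataFrame:
    """Per-population highland-vs-lowland effect and SE for every gene.

    Returns a long frame: gene, population, beta, se, t, df, p.  Requires a
    design built with the population-by-elevation interaction (``elev_*``
    columns) and a moderated fit.
    """
    elev_cols = [c for c in fit.coefficients.columns if c.startswith(ELEV_PREFIX)]
    if not elev_cols:
        raise ValueError(f"design has no '{ELEV_PREFIX}*' contrast columns")
    if fit.s2_post is None:
        raise ValueError("run ebayes_moderate before extracting effects")
    se = fit.se
    d = fit.df_residual.to_numpy(float)
    df_total = np.inf if np.isinf(fit.df_prior) else fit.df_prior + d
    frames = []
    for col in elev_cols:
        pop = col[len(ELEV_PREFIX):]
        frames.append(
            pd.DataFrame(
                {
                    "gene": fit.coefficients.index,
                    "population": pop,
                    "beta": fit.coefficients[col].to_numpy(),
                    "se": se[col].to_numpy(),
                    "t": fit.t_mod[col].to_numpy(),
                    "df": df_total,
                    "p": fit.p_value[col].to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
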