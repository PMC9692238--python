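"""Design construction, voom weights, ASE-voom weights, WLS, eBayes."""

import numpy as np
import pandas as pd
import pytest

from asepop import voomlm
from asepop.voomlm import (
    VarianceTrend,
    ase_voom,
    build_design,
    ebayes_moderate,
    estimate_f_prior,
    extract_elevation_effects,
    fit_weighted_lm,
    posterior_variance,
    voom_counts,
)


def _meta(n_per_group=16, teams=3, blocks=2, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for pop in ("Mexico", "SouthAmerica"):
        for elev in ("Highland", "Lowland"):
            for _ in range(n_per_group):
                rows.append(
                    {
                        "sample": f"s{i:03d}",
                        "population": pop,
                        "elevation": elev,
                        "latitude": rng.uniform(0, 10) + (20 if pop == "Mexico" else -30),
                        "block": (i % blocks) + 1,
                        "team": (i % teams) + 1,
                        "site_tissue": "MetLeaftip",
                    }
                )
                i += 1
    meta = pd.DataFrame(rows)
    meta["field_order"] = rng.permutation(len(meta)) + 1
    return meta


# ---------------------------------------------------------------------------
# design


def test_design_has_one_elevation_contrast_per_population():
    design = build_design(_meta())
    elev_cols = [c for c in design.columns if c.startswith("elev_")]
    assert sorted(elev_cols) == ["elev_Mexico", "elev_SouthAmerica"]


def test_design_single_team_has_three_polynomial_columns():
    meta = _meta(teams=1)
    design = build_design(meta)
    poly = [c for c in design.columns if c.startswith("order_team")]
    assert len(poly) == 3


def test_design_three_teams_nine_polynomial_columns():
    design = build_design(_meta(teams=3))
    poly = [c for c in design.columns if c.startswith("order_team")]
    assert len(poly) == 9


def test_design_single_block_omits_block_column():
    meta = _meta(blocks=1)
    design = build_design(meta)
    assert not any(c.startswith("block_") for c in design.columns)


def test_design_row_permutation_alignment():
    meta = _meta()
    design = build_design(meta)
    perm = meta.sample(frac=1.0, random_state=1).reset_index(drop=True)
    design_p = build_design(perm)
    pd.testing.assert_frame_equal(
        design_p.loc[design.index], design, check_like=True
    )


def test_design_rank_deficiency_reported():
    meta = _meta()
    scores = pd.DataFrame(
        {"dup": (meta["population"] == "SouthAmerica").to_numpy(float)},
        index=meta["sample"],
    )
    with pytest.raises(ValueError, match="rank deficient"):
        build_design(meta, cell_scores=scores)


# ---------------------------------------------------------------------------
# voom (counts path)


def test_voom_homoskedastic_weights_nearly_constant(rng):
    meta = _meta(8)
    design = build_design(meta)
    counts = pd.DataFrame(
        rng.poisson(1000, size=(300, len(meta))),
        index=[f"g{i}" for i in range(300)],
        columns=meta["sample"],
    )
    factors = pd.Series(1.0, index=meta["sample"])
    _, weights, _ = voom_counts(counts, factors, design)
    w = weights.to_numpy()
    assert w.std() / w.mean() < 0.10
    assert np.all(np.isfinite(w)) and np.all(w > 0)


def test_voom_cpm_invariant_to_library_doubling(rng):
    meta = _meta(8)
    design = build_design(meta)
    base = rng.poisson(500, size=(200, len(meta))) + 1
    counts = pd.DataFrame(base, index=[f"g{i}" for i in range(200)],
                          columns=meta["sample"])
    doubled = counts.copy()
    doubled.iloc[:, 0] = 2 * counts.iloc[:, 0]
    factors = pd.Series(1.0, index=meta["sample"])
    y1, _, _ = voom_counts(counts, factors, design)
    y2, _, _ = voom_counts(doubled, factors, design)
    # log2((2c+0.5)/(2L+1)) == log2((c+0.25)/(L+0.5)) ~ log2((c+0.5)/(L+1))
    np.testing.assert_allclose(
        y1.iloc[:, 0].to_numpy(), y2.iloc[:, 0].to_numpy(), atol=5e-3
    )


# ---------------------------------------------------------------------------
# ASE voom


def test_ase_voom_zero_weight_for_missing_cells(rng):
    meta = _meta(8)
    design = build_design(meta)
    n_g, n_s = 100, len(meta)
    total = pd.DataFrame(
        rng.integers(20, 500, size=(n_g, n_s)).astype(float),
        index=[f"g{i}" for i in range(n_g)], columns=meta["sample"],
    )
    y = pd.DataFrame(
        rng.normal(0, 0.3, size=(n_g, n_s)),
        index=total.index, columns=total.columns,
    )
    y.iloc[0, 0] = np.nan       # zero counts in one allele -> missing
    total.iloc[0, 0] = 0
    weights, trend = ase_voom(y, total, design)
    assert weights.iloc[0, 0] == 0.0
    assert (weights.to_numpy() >= 0).all()


def test_ase_voom_monotone_trend_weight_ordering(rng):
    """Where the fitted trend is non-increasing, a larger total implies a
    weight at least as large (checked through the trend evaluation)."""
    meta = _meta(8)
    design = build_design(meta)
    n_g, n_s = 150, len(meta)
    scale = np.exp(rng.uniform(np.log(16), np.log(2000), size=n_g))
    total = pd.DataFrame(
        scale[:, None] * rng.lognormal(0, 0.4, size=(n_g, n_s)),
        index=[f"g{i}" for i in range(n_g)], columns=meta["sample"],
    )
    # counting-style noise: variance inversely proportional to total
    y = pd.DataFrame(
        rng.normal(0, 1.0 / np.sqrt(total.to_numpy())),
        index=total.index, columns=total.columns,
    )
    weights, trend = ase_voom(y, total, design)
    xs = np.linspace(trend.x.min(), trend.x.max(), 50)
    ys = trend(xs)
    if np.all(np.diff(ys) <= 1e-12):  # trend non-increasing on the range
        lo, hi = trend(np.array([5.0])), trend(np.array([9.0]))
        assert hi[0] <= lo[0]
    # oracle: weights equal trend evaluated at each observation ^ -4
    lib = total.sum(axis=0).to_numpy()
    norm = total.to_numpy() * (lib.mean() / lib)[None, :]
    expect = trend(np.log2(norm + 0.5)) ** -4
    got = weights.to_numpy()
    np.testing.assert_allclose(got[got > 0], expect[got > 0], rtol=1e-10)


def test_ase_voom_inverse_variance_weights_track_totals(rng):
    """Variance ~ 1/total: estimated weights rank-correlate with totals."""
    from scipy.stats import spearmanr

    meta = _meta(12)
    design = build_design(meta)
    n_g, n_s = 300, len(meta)
    # genes differ in scale (as real expression does); observations vary
    # around their gene's scale
    scale = np.exp(rng.uniform(np.log(16), np.log(8000), size=n_g))
    total = pd.DataFrame(
        scale[:, None] * rng.lognormal(0, 0.4, size=(n_g, n_s)),
        index=[f"g{i}" for i in range(n_g)], columns=meta["sample"],
    )
    y = pd.DataFrame(
        rng.normal(0, 1.0 / np.sqrt(total.to_numpy())),
        index=total.index, columns=total.columns,
    )
    weights, _ = ase_voom(y, total, design)
    rho = spearmanr(
        weights.to_numpy().ravel(), total.loc[weights.index].to_numpy().ravel()
    ).statistic
    assert rho > 0.9


# ---------------------------------------------------------------------------
# weighted least squares


def _toy_design(n=12, seed=0):
    rng = np.random.default_rng(seed)
    x = np.column_stack([np.ones(n), rng.normal(size=n)])
    return pd.DataFrame(x, columns=["Intercept", "x"],
                        index=[f"s{i}" for i in range(n)])


def test_unit_weights_equal_ols():
    rng = np.random.default_rng(3)
    design = _toy_design()
    y = pd.DataFrame(rng.normal(size=(20, 12)), columns=design.index)
    fit = fit_weighted_lm(y, design)
    x = design.to_numpy()
    beta_ols = y.to_numpy() @ np.linalg.pinv(x).T
    np.testing.assert_allclose(fit.coefficients.to_numpy(), beta_ols, atol=1e-10)


def test_weight_scaling_invariance():
    rng = np.random.default_rng(4)
    design = _toy_design()
    y = pd.DataFrame(rng.normal(size=(30, 12)), columns=design.index)
    w = pd.DataFrame(rng.uniform(0.5, 2.0, size=(30, 12)), columns=design.index)
    fit1 = ebayes_moderate(fit_weighted_lm(y, design, w))
    fit2 = ebayes_moderate(fit_weighted_lm(y, design, 7.3 * w))
    np.testing.assert_allclose(
        fit1.coefficients.to_numpy(), fit2.coefficients.to_numpy(), atol=1e-10
    )
    np.testing.assert_allclose(
        fit1.t_mod.to_numpy(), fit2.t_mod.to_numpy(), atol=1e-8
    )


def test_duplicated_halfweight_observation_equals_single():
    """Algebraic identity: one observation at weight 1 is equivalent to the
    same observation duplicated at weight 1/2 each."""
    rng = np.random.default_rng(5)
    n = 5
    x = np.column_stack([np.ones(n), np.arange(n, dtype=float)])
    yvals = rng.normal(size=n)
    design_a = pd.DataFrame(x, columns=["Intercept", "x"],
                            index=[f"s{i}" for i in range(n)])
    y_a = pd.DataFrame([yvals], columns=design_a.index)
    fit_a = fit_weighted_lm(y_a, design_a)

    x_b = np.vstack([x, x[-1]])
    design_b = pd.DataFrame(x_b, columns=["Intercept", "x"],
                            index=[f"s{i}" for i in range(n)] + ["s4dup"])
    y_b = pd.DataFrame([np.append(yvals, yvals[-1])], columns=design_b.index)
    w_b = pd.DataFrame([[1, 1, 1, 1, 0.5, 0.5]], columns=design_b.index)
    fit_b = fit_weighted_lm(y_b, design_b, w_b)
    np.testing.assert_allclose(
        fit_a.coefficients.to_numpy(), fit_b.coefficients.to_numpy(), atol=1e-10
    )
    np.testing.assert_allclose(
        fit_a.stdev_unscaled.to_numpy(), fit_b.stdev_unscaled.to_numpy(), atol=1e-10
    )


def test_too_few_observations_dropped_with_warning():
    design = _toy_design(6)
    y = pd.DataFrame([[1.0, 2, 3, np.nan, np.nan, np.nan]], columns=design.index)
    with pytest.warns(UserWarning, match="dropped"):
        with pytest.raises(ValueError, match="no genes"):
            fit_weighted_lm(y, design)


# ---------------------------------------------------------------------------
# empirical Bayes


def test_s2_post_closed_form():
    assert posterior_variance(4.0, 10, 1.0, 5) == pytest.approx(3.0, abs=1e-12)


def test_s2_post_limits():
    assert posterior_variance(4.0, 10, 1.0, np.inf) == pytest.approx(1.0, abs=1e-10)
    assert posterior_variance(4.0, 10, 1.0, 0.0) == pytest.approx(4.0, abs=1e-10)


def test_f_prior_parameter_recovery():
    """Variances simulated from the scaled-F hierarchy (d0=4, s0^2=2,
    d_g=20): moment matching recovers d0 within 25% and s0^2 within 10%."""
    rng = np.random.default_rng(12)
    d0, s0_2, dg, n = 4.0, 2.0, 20, 5000
    sigma2 = s0_2 * d0 / rng.chisquare(d0, size=n)      # inverse-chi2 prior
    s2 = sigma2 * rng.chisquare(dg, size=n) / dg
    d0_hat, s0_hat = estimate_f_prior(s2, np.full(n, dg))
    assert abs(d0_hat - d0) / d0 < 0.25
    assert abs(s0_hat - s0_2) / s0_2 < 0.10


def test_moderated_t_matches_invariant():
    rng = np.random.default_rng(6)
    design = _toy_design(16, seed=2)
    y = pd.DataFrame(rng.normal(size=(60, 16)), columns=design.index)
    fit = ebayes_moderate(fit_weighted_lm(y, design))
    if np.isinf(fit.df_prior):
        expected = np.full(len(fit.sigma), fit.s2_prior)
    else:
        expected = (
            fit.df_prior * fit.s2_prior
            + fit.df_residual.to_numpy() * fit.sigma.to_numpy() ** 2
        ) / (fit.df_prior + fit.df_residual.to_numpy())
    np.testing.assert_allclose(fit.s2_post.to_numpy(), expected, rtol=1e-12)
    np.testing.assert_allclose(
        fit.se.to_numpy(),
        fit.stdev_unscaled.to_numpy() * np.sqrt(fit.s2_post.to_numpy())[:, None],
        rtol=1e-12,
    )


# ---------------------------------------------------------------------------
# elevation-effect extraction


def _simulate_expression(meta, beta_mex, beta_sa, n_genes, noise_sd, seed=0):
    rng = np.random.default_rng(seed)
    design = build_design(meta)
    eff = np.zeros((n_genes, design.shape[1]))
    eff[:, design.columns.get_loc("elev_Mexico")] = beta_mex
    eff[:, design.columns.get_loc("elev_SouthAmerica")] = beta_sa
    y = eff @ design.to_numpy().T + rng.normal(0, noise_sd, size=(n_genes, len(meta)))
    return pd.DataFrame(y, index=[f"g{i}" for i in range(n_genes)],
                        columns=design.index), design


def test_elevation_effect_recovery_and_coverage():
    meta = _meta(20, seed=7)
    y, design = _simulate_expression(meta, 1.0, 0.0, 400, 0.5, seed=8)
    fit = ebayes_moderate(fit_weighted_lm(y, design))
    eff = extract_elevation_effects(fit)
    mex = eff[eff["population"] == "Mexico"]
    sa = eff[eff["population"] == "SouthAmerica"]
    assert abs(mex["beta"].mean() - 1.0) < 0.05
    assert abs(sa["beta"].mean()) < 0.05
    # ~95% CI coverage of the true Mexican effect
    z = 1.96
    cover = (
        (mex["beta"] - z * mex["se"] <= 1.0) & (1.0 <= mex["beta"] + z * mex["se"])
    ).mean()
    assert 0.90 <= cover <= 0.99
    assert (eff["se"] > 0).all() and np.isfinite(eff["se"]).all()


def test_elevation_sign_flip_symmetry():
    meta = _meta(10, seed=9)
    y, design = _simulate_expression(meta, 0.7, -0.2, 50, 0.4, seed=10)
    fit = ebayes_moderate(fit_weighted_lm(y, design))
    flipped = meta.copy()
    flipped["elevation"] = np.where(
        flipped["elevation"] == "Highland", "Lowland", "Highland"
    )
    design_f = build_design(flipped)
    fit_f = ebayes_moderate(fit_weighted_lm(y, design_f))
    np.testing.assert_allclose(
        fit.coefficients["elev_Mexico"].to_numpy(),
        -fit_f.coefficients["elev_Mexico"].to_numpy(),
        atol=1e-8,
    )
    np.testing.assert_allclose(
        np.abs(fit.t_mod["elev_Mexico"].to_numpy()),
        np.abs(fit_f.t_mod["elev_Mexico"].to_numpy()),
        atol=1e-6,
    )


def test_type_i_error_control_on_null():
    """Null data: elevation-contrast p-values reject at ~5%."""
    meta = _meta(16, seed=13)
    y, design = _simulate_expression(meta, 0.0, 0.0, 2000, 1.0, seed=14)
    fit = ebayes_moderate(fit_weighted_lm(y, design))
    frac = float((fit.p_value["elev_Mexico"] < 0.05).mean())
    assert 0.03 <= frac <= 0.07


def test_allele_swap_negates_beta_keeps_t_magnitude():
    """Negating the response (allele-label swap of log2ASE) negates the
    elevation coefficients and preserves |moderated t|."""
    meta = _meta(10, seed=15)
    y, design = _simulate_expression(meta, 0.6, 0.3, 80, 0.4, seed=16)
    fit = ebayes_moderate(fit_weighted_lm(y, design))
    fit_neg = ebayes_moderate(fit_weighted_lm(-y, design))
    for col in ("elev_Mexico", "elev_SouthAmerica"):
        np.testing.assert_allclose(
            fit.coefficients[col].to_numpy(),
            -fit_neg.coefficients[col].to_numpy(), atol=1e-10,
        )
        np.testing.assert_allclose(
            np.abs(fit.t_mod[col].to_numpy()),
            np.abs(fit_neg.t_mod[col].to_numpy()), atol=1e-8,
        )
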