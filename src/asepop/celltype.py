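"""Cell-population composition scores from weighted marker-gene projection.

Bulk RNA samples of a structured tissue mix transcripts from several cell
populations; shifts in their proportions masquerade as differential
expression.  Given reference marker-gene sets with per-gene weights (log2
fold-change enrichment of the marker in its cell population), the
projection score of sample s for population c is

    score[s, c] = sum_g w[g, c] * (x[g, s] - mean_s' x[g, s'])

over the markers assayed in the expression matrix (log2 scale).  This is a
relaxed, regression-free relative of least-squares cell-type deconvolution:
it does not assume the reference spans every population present, and scores
are relative (centered over samples), not proportions.

Score reliability is assessed against a permutation null that reassigns
marker identities to random expressed genes (weights retained) and
recomputes the total score variance; a principal-component summary of the
score matrix exposes the dominant composition axes, which can be injected
as design covariates in the differential-expression model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd


@dataclass
class ProjectionScores:
    """Samples x cell-populations score matrix and its summaries."""

    scores: pd.DataFrame                       # samples x populations
    n_markers_used: pd.Series                  # per population
    dropped_markers: dict = field(default_factory=dict)
    pc_coordinates: Optional[pd.DataFrame] = None
    pc_variance_explained: Optional[np.ndarray] = None


def read_marker_sets(path: str) -> pd.DataFrame:
    """Marker table TSV with columns: population, gene, weight."""
    df = pd.read_csv(path, sep="\t")
    required = {"population", "gene", "weight"}
    if not required.issubset(df.columns):
        raise ValueError(f"marker table must have columns {sorted(required)}")
    return df


def projection_scores(
    expression: pd.DataFrame,
    markers: pd.DataFrame,
) -> ProjectionScores:
    """Weighted sums of mean-centered expression over each marker set.

    ``expression``: genes x samples on the log2 scale.  ``markers``: long
    frame (population, gene, weight).  Markers absent from the expression
    matrix are dropped and reported; a population with no assayed markers
    yields no score column (with a warning).
    """
    x = expression.sub(expression.mean(axis=1), axis=0)
    cols, n_used, dropped = {}, {}, {}
    for pop, sub in markers.groupby("population"):
        present = sub[sub["gene"].isin(x.index)]
        absent = sorted(set(sub["gene"]) - set(present["gene"]))
        dropped[pop] = absent
        if present.empty:
            warnings.warn(f"marker set {pop!r} has no assayed genes; column omitted")
            continue
        agg = present.groupby("gene")["weight"].sum()
        cols[pop] = x.loc[agg.index].mul(agg, axis=0).sum(axis=0)
        n_used[pop] = len(agg)
    if not cols:
        raise ValueError("no marker set had any assayed genes")
    scores = pd.DataFrame(cols)
    scores.index.name = "sample"
    return ProjectionScores(
        scores=scores,
        n_markers_used=pd.Series(n_used, name="n_markers"),
        dropped_markers=dropped,
    )


def score_total_variance(scores: pd.DataFrame) -> float:
    """Total variance of scores across samples, summed over populations."""
    return float(scores.var(axis=0, ddof=1).sum())


def permutation_null(
    expression: pd.DataFrame,
    markers: pd.DataFrame,
    n_perm: int = 200,
    seed: int = 0,
) -> dict:
    """Permutation null for the total score variance.

    Each permutation reassigns every marker's gene identity uniformly at
    random (without replacement within a population's marker set) among the
    expressed genes, keeping the weights, then recomputes the scores.  The
    empirical p-value is ``(1 + #{null >= real}) / (n_perm + 1)``.
    """
    if n_perm < 20:
        warnings.warn(f"n_perm={n_perm} gives an unstable empirical p-value")
    rng = np.random.default_rng(seed)
    real = projection_scores(expression, markers)
    real_stat = score_total_variance(real.scores)
    pool = np.asarray(expression.index)
    null_stats = np.empty(n_perm)
    for i in range(n_perm):
        perm_frames = []
        for pop, sub in markers.groupby("population"):
            k = len(sub)
            if k > len(pool):
                raise ValueError("not enough expressed genes to permute markers")
            genes = rng.choice(pool, size=k, replace=False)
            perm_frames.append(
                pd.DataFrame(
                    {"population": pop, "gene": genes, "weight": sub["weight"].to_numpy()}
                )
            )
        perm = pd.concat(perm_frames, ignore_index=True)
        null_stats[i] = score_total_variance(projection_scores(expression, perm).scores)
    p = (1.0 + np.sum(null_stats >= real_stat)) / (n_perm + 1.0)
    return {
        "real_stat": real_stat,
        "null_stats": null_stats,
        "p_value": float(p),
        "scores": real,
    }


def score_pca(
    proj: ProjectionScores, n_pcs: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered PCA of the score matrix.

    Sign convention: within each PC the loading of largest magnitude is
    positive, so results are deterministic.  Returns (coordinates,
    fraction of variance explained); flags all-zero-variance input.
    """
    x = proj.scores.to_numpy(float)
    if x.shape[1] < 2:
        raise ValueError("need scores for at least 2 cell populations")
    xc = x - x.mean(axis=0, keepdims=True)
    u, svals, vt = np.linalg.svd(xc, full_matrices=False)
    total = (svals ** 2).sum()
    if total <= 0:
        warnings.warn("constant score matrix; PCA variance is zero")
        var_exp = np.zeros(min(n_pcs, len(svals)))
        coords = np.zeros((x.shape[0], len(var_exp)))
    else:
        n_pcs = min(n_pcs, len(svals))
        flip = np.sign(vt[np.arange(n_pcs), np.argmax(np.abs(vt[:n_pcs]), axis=1)])
        flip[flip == 0] = 1.0
        coords = (u[:, :n_pcs] * svals[:n_pcs]) * flip
        var_exp = svals[:n_pcs] ** 2 / total
    pc_df = pd.DataFrame(
        coords, index=proj.scores.index, columns=[f"PC{i + 1}" for i in range(coords.shape[1])]
    )
    proj.pc_coordinates = pc_df
    proj.pc_variance_explained = var_exp
    return pc_df, var_exp
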