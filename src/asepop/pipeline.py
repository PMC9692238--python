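"""End-to-end orchestration: simulate -> filter -> aggregate -> model.

A :class:`RunConfig` (loadable from a flat YAML file) names either a fixture
directory of input tables or a simulation block, the stages to run, and the
analysis thresholds.  :func:`run` executes the requested stages in
dependency order, writes per-stage TSVs plus a manifest with input hashes
and row counts, and is deterministic for a fixed config: all randomness
flows from one root seed through named substreams per stage.

Stages
------
simulate    synthetic cohort written as a fixture directory
qc          drop samples below the mapped-read threshold
filter_snps per-sample ASE SNP filters
aggregate   SNP -> gene allelic counts and log2ASE ratios
ibd         IBD bin classification for sibling plant pairs
de          per-tissue voom + weighted lm + eBayes on total expression
dase        per-tissue ASE-voom + weighted lm + eBayes on log2ASE
mash        joint meta-analysis across population x site:tissue conditions
celltype    marker projection scores, permutation null, PCA
converge    convergent-gene classification + hypergeometric overlap
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import allelic_io, celltype, convergence, ibd, mashlite, simdata, voomlm

logger = logging.getLogger("asepop")

STAGE_ORDER = [
    "simulate", "qc", "filter_snps", "aggregate", "ibd",
    "de", "dase", "celltype", "converge",
]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    outdir: str = "asepop_run"
    fixture_dir: Optional[str] = None       # input directory; None => simulate
    simulate: Optional[simdata.SimConfig] = None
    stages: list = field(default_factory=lambda: list(STAGE_ORDER))
    markers_path: Optional[str] = None      # celltype reference (TSV)
    # thresholds (defaults are the analysis constants)
    min_reads: int = 32
    min_samples: int = 10
    snp_total: int = 10
    log2_cap: float = 2.0
    lfsr_alpha: float = 0.05
    gmm_hi: float = 0.90
    gmm_lo: float = 0.10
    n_bins: int = 20
    n_perm: int = 200
    min_mapped: float = 2e6
    celltype_covariates: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in ("min_reads", "min_samples", "snp_total", "n_bins", "n_perm"):
            if getattr(self, name) < 1:
                raise ValueError(f"threshold {name} must be positive")
        if self.log2_cap <= 0 or not 0 < self.lfsr_alpha < 1:
            raise ValueError("log2_cap must be positive and 0 < lfsr_alpha < 1")
        unknown = [s for s in self.stages if s not in STAGE_ORDER]
        if unknown:
            raise ValueError(f"unknown stage(s): {unknown}")
        if self.fixture_dir is None and self.simulate is None and "simulate" not in self.stages:
            raise ValueError("need a fixture_dir or a simulate block")


def load_config(path: str) -> RunConfig:
    """Load a RunConfig from a flat YAML (key: value) file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = raw.pop("simulate", None)
    cfg = RunConfig(**{k: v for k, v in raw.items() if k in RunConfig.__dataclass_fields__})
    if sim:
        cfg.simulate = simdata.SimConfig(**sim)
    return cfg


def sample_qc(
    counts: pd.DataFrame, metadata: pd.DataFrame, min_mapped: float = 2e6
) -> tuple[list, pd.DataFrame]:
    """Drop samples whose total mapped reads fall below ``min_mapped``.

    Returns (retained sample list, report frame).  Fatal if nothing is left.
    """
    totals = counts.sum(axis=0)
    keep = totals >= min_mapped
    report = pd.DataFrame(
        {"sample": totals.index, "mapped_reads": totals.to_numpy(), "retained": keep.to_numpy()}
    )
    retained = [s for s in counts.columns if keep[s]]
    if not retained:
        raise ValueError(
            f"all samples fall below the {min_mapped:.0f} mapped-read threshold"
        )
    dropped = [s for s in counts.columns if not keep[s]]
    if dropped:
        logger.info("qc: dropped %d sample(s): %s", len(dropped), dropped[:10])
    return retained, report


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _condition(pop: str, tissue: str) -> str:
    return f"{pop}|{tissue}"


class Pipeline:
    """Holds intermediate state of one run; stages populate attributes."""

    def __init__(self, config: RunConfig):
        config.validate()
        self.config = config
        self.outdir = config.outdir
        os.makedirs(self.outdir, exist_ok=True)
        ss = np.random.SeedSequence(config.seed)
        names = ["simulate", "ibd", "celltype", "mash"]
        self.substreams = {n: c for n, c in zip(names, ss.spawn(len(names)))}
        self.manifest: dict = {"seed": config.seed, "stages": {}, "files": {}}
        # state
        self.metadata: Optional[pd.DataFrame] = None
        self.snp_counts: Optional[pd.DataFrame] = None
        self.gene_totals: Optional[pd.DataFrame] = None
        self.exons: Optional[pd.DataFrame] = None
        self.cohort: Optional[simdata.SimCohort] = None
        self.retained_samples: Optional[list] = None
        self.snp_filtered: Optional[pd.DataFrame] = None
        self.ase_matrix: Optional[allelic_io.GeneAllelicMatrix] = None
        self.log2cpm: dict = {}
        self.effects: dict = {}       # "de"/"dase" -> long effect frame
        self.mash_results: dict = {}  # "de"/"dase" -> MashResult
        self.cell_scores: Optional[pd.DataFrame] = None

    # -- I/O helpers --------------------------------------------------------

    def _write(self, name: str, df: pd.DataFrame, index: bool = False) -> str:
        path = os.path.join(self.outdir, name)
        df.to_csv(path, sep="\t", index=index)
        self.manifest["files"][name] = {"sha256": _sha256(path), "rows": int(len(df))}
        return path

    def _record(self, stage: str, **info) -> None:
        self.manifest["stages"][stage] = info
        logger.info("stage %s: %s", stage, info)

    # -- stages -------------------------------------------------------------

    def stage_simulate(self) -> None:
        sim_cfg = self.config.simulate or simdata.SimConfig(seed=self.config.seed)
        if sim_cfg.seed != self.config.seed:
            sim_cfg = dataclasses.replace(sim_cfg, seed=sim_cfg.seed)
        self.cohort = simdata.simulate_cohort(sim_cfg)
        fixture = os.path.join(self.outdir, "fixture")
        paths = simdata.write_fixture(self.cohort, fixture)
        self.metadata = self.cohort.metadata
        self.snp_counts = self.cohort.snp_counts
        self.gene_totals = self.cohort.gene_totals
        self.exons = allelic_io.read_gff3_exons(paths["annotation"])
        self._record(
            "simulate",
            n_samples=len(self.metadata),
            n_genes=int(self.gene_totals.shape[0]),
            n_snp_rows=int(len(self.snp_counts)),
        )

    def _load_inputs(self) -> None:
        d = self.config.fixture_dir
        if d is None:
            raise ValueError("stage requires inputs: no fixture_dir and simulate not run")
        self.metadata = allelic_io.read_metadata(os.path.join(d, "metadata.tsv"))
        self.gene_totals = allelic_io.read_count_matrix(os.path.join(d, "gene_totals.tsv"))
        snp_dir = os.path.join(d, "snp_counts")
        if os.path.isdir(snp_dir):
            self.snp_counts = allelic_io.read_snp_counts_dir(snp_dir)
        gff = os.path.join(d, "genes.gff3")
        if os.path.exists(gff):
            self.exons = allelic_io.read_gff3_exons(gff)

    def _require(self, attr: str, stage: str, upstream: str):
        if getattr(self, attr) is None:
            raise ValueError(f"stage '{stage}' is missing output of upstream stage '{upstream}'")

    def stage_qc(self) -> None:
        if self.metadata is None:
            self._load_inputs()
        self.retained_samples, report = sample_qc(
            self.gene_totals, self.metadata, self.config.min_mapped
        )
        self.metadata = self.metadata[self.metadata["sample"].isin(self.retained_samples)]
        self.gene_totals = self.gene_totals[self.retained_samples]
        if self.snp_counts is not None:
            self.snp_counts = self.snp_counts[
                self.snp_counts["sample"].isin(self.retained_samples)
            ]
        self._write("qc_samples.tsv", report)
        self._record("qc", retained=len(self.retained_samples), total=len(report))

    def stage_filter_snps(self) -> None:
        self._require("snp_counts", "filter_snps", "qc")
        filtered, report = allelic_io.filter_ase_snps(
            self.snp_counts, min_total=self.config.snp_total, log2_cap=self.config.log2_cap
        )
        self.snp_filtered = filtered
        self._write("snp_filter_report.tsv", report.to_frame())
        self._record(
            "filter_snps", n_input=report.n_input, n_kept=report.n_kept,
            cumulative=report.cumulative,
        )

    def stage_aggregate(self) -> None:
        self._require("snp_filtered", "aggregate", "filter_snps")
        if self.exons is None:
            raise ValueError("stage 'aggregate' needs a gene annotation (genes.gff3)")
        assigned = allelic_io.assign_snps_to_genes(self.snp_filtered, self.exons)
        self.ase_matrix = allelic_io.aggregate_gene_allelic_counts(assigned, mode="snp_sum")
        self._write("gene_ase_landrace.tsv", self.ase_matrix.landrace, index=True)
        self._write("gene_ase_b73.tsv", self.ase_matrix.b73, index=True)
        self._write("gene_ase_log2ase.tsv", self.ase_matrix.log2ase, index=True)
        self._record(
            "aggregate",
            n_genes=int(self.ase_matrix.landrace.shape[0]),
            n_samples=int(self.ase_matrix.landrace.shape[1]),
            n_ambiguous_snps=assigned.attrs.get("n_ambiguous", 0),
        )

    def stage_ibd(self) -> None:
        self._require("snp_filtered", "ibd", "filter_snps")
        panel = self.snp_counts[["contig", "position"]].drop_duplicates()
        meta = self.metadata
        rows = []
        for family, fam_meta in meta.groupby("family"):
            plants = fam_meta.drop_duplicates("plant")
            if len(plants) < 2:
                continue
            # one representative sample per plant
            reps = fam_meta.sort_values("site_tissue").drop_duplicates("plant")
            plist = list(reps.itertuples())
            for i in range(len(plist)):
                for j in range(i + 1, len(plist)):
                    a, b = plist[i], plist[j]
                    het_a = self.snp_filtered[self.snp_filtered["sample"] == a.sample]
                    het_b = self.snp_filtered[self.snp_filtered["sample"] == b.sample]
                    try:
                        bins = ibd.classify_ibd_pair(
                            het_a, het_b, panel,
                            n_bins=self.config.n_bins,
                            hi=self.config.gmm_hi, lo=self.config.gmm_lo,
                        )
                    except ValueError:
                        continue
                    bins.insert(0, "family", family)
                    bins.insert(1, "plant_a", a.plant)
                    bins.insert(2, "plant_b", b.plant)
                    rows.append(bins)
        out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
        self._write("ibd_bins.tsv", out)
        self.ibd_bins = out
        n_ibd = int((out["class"] == "IBD").sum()) if len(out) else 0
        self._record("ibd", n_pairs=len({tuple(r) for r in
                     out[["plant_a", "plant_b"]].itertuples(index=False)}) if len(out) else 0,
                     n_bins=len(out), n_ibd=n_ibd)

    def _tissue_design(self, meta_t: pd.DataFrame) -> pd.DataFrame:
        scores = None
        if self.config.celltype_covariates and self.cell_scores is not None:
            scores = self.cell_scores
        return voomlm.build_design(meta_t, cell_scores=scores)

    def stage_de(self) -> None:
        self._require("gene_totals", "de", "qc")
        frames = []
        for tissue, meta_t in self.metadata.groupby("site_tissue"):
            samples = list(meta_t["sample"])
            counts = allelic_io.filter_genes_for_expression(
                self.gene_totals[samples], meta_t,
                min_samples=self.config.min_samples, min_reads=self.config.min_reads,
            )
            if counts.shape[0] < 10:
                raise ValueError(
                    f"de: tissue {tissue} retains {counts.shape[0]} genes after the "
                    f"expression filter (min_samples={self.config.min_samples}, "
                    f"min_reads={self.config.min_reads}); thresholds exceed cohort size?"
                )
            factors = allelic_io.tmm_normalization_factors(counts)
            design = self._tissue_design(meta_t)
            log2cpm, weights, _ = voomlm.voom_counts(counts, factors, design)
            self.log2cpm[tissue] = log2cpm
            fit = voomlm.fit_weighted_lm(log2cpm, design, weights)
            fit = voomlm.ebayes_moderate(fit)
            eff = voomlm.extract_elevation_effects(fit)
            eff["site_tissue"] = tissue
            frames.append(eff)
        self.effects["de"] = pd.concat(frames, ignore_index=True)
        self._write("de_effects.tsv", self.effects["de"])
        self._record("de", n_rows=len(self.effects["de"]))

    def stage_dase(self) -> None:
        self._require("ase_matrix", "dase", "aggregate")
        frames = []
        for tissue, meta_t in self.metadata.groupby("site_tissue"):
            sub = self.ase_matrix.subset_samples(meta_t["sample"])
            meta_sub = meta_t[meta_t["sample"].isin(sub.landrace.columns)]
            filt = allelic_io.filter_genes_for_ase(
                sub, meta_sub,
                min_samples=self.config.min_samples, min_reads=self.config.min_reads,
            )
            if filt.landrace.shape[0] < 10:
                logger.warning("dase: tissue %s has <10 genes after filtering; skipped", tissue)
                continue
            design = voomlm.build_design(meta_sub)
            weights, _ = voomlm.ase_voom(filt.log2ase, filt.total, design)
            y = filt.log2ase.loc[weights.index]
            fit = voomlm.fit_weighted_lm(y, design, weights)
            fit = voomlm.ebayes_moderate(fit)
            eff = voomlm.extract_elevation_effects(fit)
            eff["site_tissue"] = tissue
            frames.append(eff)
        if not frames:
            raise ValueError("dase: no tissue had enough genes after filtering")
        self.effects["dase"] = pd.concat(frames, ignore_index=True)
        self._write("dase_effects.tsv", self.effects["dase"])
        self._record("dase", n_rows=len(self.effects["dase"]))

    def _mash_one(self, which: str) -> mashlite.MashResult:
        eff = self.effects[which]
        eff = eff.assign(condition=[
            _condition(p, t) for p, t in zip(eff["population"], eff["site_tissue"])
        ])
        bhat = eff.pivot_table(index="gene", columns="condition", values="beta")
        shat = eff.pivot_table(index="gene", columns="condition", values="se")
        table = mashlite.EffectTable(bhat=bhat, shat=shat.reindex_like(bhat))
        result = mashlite.mash_analysis(table)
        self.mash_results[which] = result
        self._write(f"{which}_mash_posterior_mean.tsv", result.posterior_mean, index=True)
        self._write(f"{which}_mash_lfsr.tsv", result.lfsr, index=True)
        n_sig = int((result.overall_lfsr < self.config.lfsr_alpha).sum())
        self._record(f"{which}_mash", n_genes=len(bhat), n_significant=n_sig)
        return result

    def stage_mash(self, which: str) -> None:
        if which not in self.effects:
            raise ValueError(f"stage 'mash' is missing output of upstream stage '{which}'")
        self._mash_one(which)

    def stage_celltype(self) -> None:
        if not self.log2cpm:
            raise ValueError("stage 'celltype' is missing output of upstream stage 'de'")
        tissue = sorted(self.log2cpm)[0]
        expr = self.log2cpm[tissue]
        if self.config.markers_path:
            markers = celltype.read_marker_sets(self.config.markers_path)
        else:
            markers = synthetic_marker_sets(
                expr, seed=int(self.substreams["celltype"].generate_state(1)[0] % 2**31)
            )
        null = celltype.permutation_null(
            expr, markers, n_perm=self.config.n_perm,
            seed=int(self.substreams["celltype"].generate_state(2)[1] % 2**31),
        )
        proj = null["scores"]
        celltype.score_pca(proj)
        self.cell_scores = proj.scores
        self._write("celltype_scores.tsv", proj.scores, index=True)
        self._write("celltype_pca.tsv", proj.pc_coordinates, index=True)
        self._record(
            "celltype", tissue=tissue, p_value=null["p_value"],
            real_stat=null["real_stat"],
        )

    def stage_converge(self) -> None:
        if "dase" not in self.mash_results:
            raise ValueError("stage 'converge' is missing output of upstream stage 'dase'")
        result = self.mash_results["dase"]
        pops = sorted({c.split("|")[0] for c in result.lfsr.columns})
        if len(pops) != 2:
            raise ValueError(f"convergence needs exactly 2 populations, found {pops}")
        per_pop = {}
        for pop in pops:
            cols = [c for c in result.lfsr.columns if c.startswith(pop + "|")]
            per_pop[pop] = {
                "lfsr": result.lfsr[cols].min(axis=1, skipna=True),
                "pm": result.posterior_mean[cols].mean(axis=1, skipna=True),
            }
        p1, p2 = pops
        calls = convergence.classify_convergent(
            per_pop[p1]["lfsr"], per_pop[p2]["lfsr"],
            per_pop[p1]["pm"], per_pop[p2]["pm"],
            alpha=self.config.lfsr_alpha,
        )
        calls.insert(0, "gene", result.lfsr.index)
        alpha = self.config.lfsr_alpha
        sig1 = int((per_pop[p1]["lfsr"] < alpha).sum())
        sig2 = int((per_pop[p2]["lfsr"] < alpha).sum())
        both = int(calls["significant_both"].sum())
        test = convergence.overlap_test(
            N=len(calls), K=sig1, n=sig2, x=both
        )
        conc = None
        if calls["convergent"].sum() >= 3:
            conc = convergence.effect_concordance(
                per_pop[p1]["pm"], per_pop[p2]["pm"], calls["convergent"].to_numpy()
            )
        self._write("convergence_genes.tsv", calls)
        summary = pd.DataFrame(
            [{
                "N": test.N, "K": test.K, "n": test.n, "x": test.x,
                "p": test.p, "overlap_percent": test.overlap_percent(),
                "n_convergent": int(calls["convergent"].sum()),
                "n_discordant": int(calls["discordant"].sum()),
                "r_all": conc["r_all"] if conc else np.nan,
                "r_subset": conc["r_subset"] if conc else np.nan,
            }]
        )
        self._write("convergence_overlap.tsv", summary)
        self.convergence_summary = summary
        self._record("converge", **summary.iloc[0].to_dict())


def synthetic_marker_sets(
    expression: pd.DataFrame,
    n_sets: int = 7,
    genes_per_set: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic stand-in for a single-cell marker reference.

    Draws ``n_sets`` disjoint random gene sets from the assayed genes with
    lognormal weights.  Purely a demonstration reference: real analyses
    should supply marker sets derived from single-cell data of the tissue.
    """
    rng = np.random.default_rng(seed)
    pool = np.asarray(expression.index)
    genes_per_set = min(genes_per_set, len(pool) // n_sets)
    if genes_per_set < 3:
        raise ValueError("not enough assayed genes for synthetic marker sets")
    need = n_sets * genes_per_set
    chosen = rng.choice(pool, size=need, replace=False)
    return pd.DataFrame(
        {
            "population": np.repeat([f"cell{i + 1}" for i in range(n_sets)], genes_per_set),
            "gene": chosen,
            "weight": rng.lognormal(0.0, 0.5, size=need),
        }
    )


def run(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order; return manifest."""
    pipe = Pipeline(config)
    stages = [s for s in STAGE_ORDER if s in config.stages]
    if config.fixture_dir is not None and "simulate" in stages:
        stages.remove("simulate")  # inputs come from the fixture directory
    for stage in stages:
        if stage == "simulate":
            pipe.stage_simulate()
        elif stage == "qc":
            pipe.stage_qc()
        elif stage == "filter_snps":
            pipe.stage_filter_snps()
        elif stage == "aggregate":
            pipe.stage_aggregate()
        elif stage == "ibd":
            pipe.stage_ibd()
        elif stage == "de":
            pipe.stage_de()
            pipe.stage_mash("de")
        elif stage == "dase":
            pipe.stage_dase()
            pipe.stage_mash("dase")
        elif stage == "celltype":
            pipe.stage_celltype()
        elif stage == "converge":
            pipe.stage_converge()
    manifest_path = os.path.join(config.outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(pipe.manifest, fh, indent=2, default=str)
    pipe.manifest["manifest_path"] = manifest_path
    pipe.manifest["_pipeline"] = pipe
    return pipe.manifest
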