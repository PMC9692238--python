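"""Synthetic F1 cohort simulator.

Emulates the experimental design of a population-level allele-specific
expression (ASE) study: a panel of outbred paternal parents ("landraces")
sampled from highland and lowland sites of two populations, each crossed to
a common inbred maternal tester, with F1 plants grown in multi-block field
trials and RNA sampled from several site:tissue combinations.

Every F1 plant is heterozygous landrace/tester at any locus where its
inherited paternal haplotype differs from the tester, so allelic read counts
at exonic SNPs measure cis-regulatory activity of the landrace allele
relative to the tester allele.  The generative model is:

* per gene g, paternal haplotype h of family f: a cis effect
  ``theta[g, f, h] ~ N(delta_g * highland_f, tau^2)`` on the log2 scale,
  where ``delta_g`` is nonzero only for designated DASE genes;
* gene totals are negative-binomial around a library-size-scaled mean
  multiplied by (1 + 2^theta)/2, so a cis-up landrace allele also raises
  the gene's total expression;
* the landrace share of a gene's ASE-informative reads is beta-binomial
  with mean ``p = 2^theta / (1 + 2^theta)`` and intra-class correlation
  ``bb_rho``;
* SNP-level counts arise by multinomial thinning of the gene-level allelic
  reads across the gene's exonic SNPs; a SNP is heterozygous in a sample
  only if the inherited paternal haplotype carries the alternate allele
  there, otherwise its landrace reads are indistinguishable from tester
  reads; sequencing errors flip individual allele calls at rate
  ``seq_error_rate``.

Paternal haplotypes segregate independently across fixed-length chromosome
segments, giving sibling plants a known identity-by-descent (IBD) mosaic
for testing IBD classification.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

SITE_TISSUES = ("MetLeaftip", "MetLeafbase", "PvLeaftip")
POPULATIONS = ("Mexico", "SouthAmerica")

# latitude bands (degrees) of the two sampled populations
_LAT_RANGES = {"Mexico": (14.0, 25.0), "SouthAmerica": (-34.0, -2.0)}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the study design being emulated: 108 F1 families split
    evenly between two populations and between highland and lowland origin,
    three site:tissues (two tissues x two blocks at the highland field site,
    one tissue x one block at the lowland site), three sampling teams.
    """

    n_families: int = 108
    frac_highland: float = 0.5
    n_populations: int = 2
    n_genes: int = 2000
    n_chromosomes: int = 10
    snps_per_gene_mean: float = 3.0
    n_dase_genes: int = 200
    delta: float = 1.0          # highland - lowland shift of log2 cis effect
    tau: float = 0.3            # SD of per-haplotype baseline cis effect (log2)
    library_size_mean: int = 5_000_000
    nb_dispersion: float = 0.05  # NB overdispersion of gene totals
    bb_rho: float = 0.01        # beta-binomial ICC of the allelic split
    seq_error_rate: float = 0.001
    n_tissues: int = 3
    plants_per_family_per_site: tuple[int, int] = (2, 1)  # (Metepec, PuertoVallarta)
    segments_per_chromosome: int = 5
    het_rate: float = 0.5       # chance a paternal haplotype carries ALT at a SNP
    trans_frac: float = 0.2     # fraction of genes with a field-order trans effect
    trans_sd: float = 0.2       # SD of that effect (log2 per unit scaled order)
    emit_read_assignments: bool = False
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_families": self.n_families,
            "n_populations": self.n_populations,
            "n_genes": self.n_genes,
            "n_chromosomes": self.n_chromosomes,
            "n_dase_genes": self.n_dase_genes + 1,  # 0 allowed
            "library_size_mean": self.library_size_mean,
            "n_tissues": self.n_tissues,
            "segments_per_chromosome": self.segments_per_chromosome,
        }
        for name, v in counts.items():
            if not np.isfinite(v) or int(v) != v or v < 1:
                raise ValueError(f"invalid config value for {name!r}: {v}")
        if not 0.0 <= self.frac_highland <= 1.0:
            raise ValueError(f"invalid config value for 'frac_highland': {self.frac_highland}")
        if not 0.0 <= self.bb_rho < 1.0:
            raise ValueError(f"invalid config value for 'bb_rho': {self.bb_rho}")
        if not np.isfinite(self.delta):
            raise ValueError(f"invalid config value for 'delta': {self.delta}")
        if not (np.isfinite(self.tau) and self.tau >= 0):
            raise ValueError(f"invalid config value for 'tau': {self.tau}")
        if not (np.isfinite(self.snps_per_gene_mean) and self.snps_per_gene_mean > 0):
            raise ValueError(
                f"invalid config value for 'snps_per_gene_mean': {self.snps_per_gene_mean}"
            )
        if not (np.isfinite(self.nb_dispersion) and self.nb_dispersion > 0):
            raise ValueError(f"invalid config value for 'nb_dispersion': {self.nb_dispersion}")
        if not 0.0 <= self.seq_error_rate < 1.0:
            raise ValueError(f"invalid config value for 'seq_error_rate': {self.seq_error_rate}")
        if self.n_dase_genes > self.n_genes:
            raise ValueError("invalid config value for 'n_dase_genes': exceeds n_genes")
        if self.n_tissues < 1 or self.n_tissues > len(SITE_TISSUES):
            raise ValueError(f"invalid config value for 'n_tissues': {self.n_tissues}")
        if not 0.0 <= self.het_rate <= 1.0:
            raise ValueError(f"invalid config value for 'het_rate': {self.het_rate}")


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort, for recovery testing."""

    genes: pd.DataFrame            # gene, chrom, segment, start, end, n_snps, delta, is_dase
    theta: np.ndarray              # (n_genes, n_families, 2) log2 cis effect per haplotype
    haplotypes: pd.DataFrame       # plant, chrom, segment, haplotype (0/1)
    expected_p: pd.DataFrame       # genes x samples expected landrace fraction
    config: SimConfig


@dataclass
class SimCohort:
    """A simulated F1 cohort: metadata, counts and ground truth."""

    metadata: pd.DataFrame          # one row per RNA sample
    snp_counts: pd.DataFrame        # long table across samples (ASEReadCounter columns + sample)
    gene_totals: pd.DataFrame       # genes x samples total-expression counts
    truth: SimTruth
    read_assignments: Optional[pd.DataFrame] = None  # read_id, sample, gene, allele, contig, position

    @property
    def samples(self) -> list[str]:
        return list(self.metadata["sample"])

    def realized_elevation_effects(self) -> pd.DataFrame:
        """The estimand of the DASE model for this cohort.

        For each gene and (population, site:tissue) condition: the mean true
        log2 cis effect over the highland samples minus that over the
        lowland samples, using each sample's actually inherited haplotype.
        For a gene with no designated elevation shift this is not exactly
        zero — baseline per-haplotype effects do not average out in a
        finite cohort — so it is the correct sign oracle for recovery
        checks.  Columns are "<population>|<site_tissue>".
        """
        truth = self.truth
        fam_index = truth._fam_index            # type: ignore[attr-defined]
        hap_arr = truth._hap_arr                # type: ignore[attr-defined]
        plant_index = {p: i for i, p in enumerate(truth._plants)}  # type: ignore[attr-defined]
        genes = truth.genes
        ng = len(genes)
        chrom_i = genes["chrom_i"].to_numpy()
        seg_i = genes["segment"].to_numpy()
        out = {}
        for (pop, tissue), sub in self.metadata.groupby(["population", "site_tissue"]):
            means = {}
            for elev, ss in sub.groupby("elevation"):
                acc = np.zeros(ng)
                for _, row in ss.iterrows():
                    fi = fam_index[row["family"]]
                    pi = plant_index[row["plant"]]
                    hap_g = hap_arr[pi, chrom_i, seg_i]
                    acc += truth.theta[np.arange(ng), fi, hap_g]
                means[elev] = acc / len(ss)
            if {"Highland", "Lowland"} <= set(means):
                out[f"{pop}|{tissue}"] = means["Highland"] - means["Lowland"]
        return pd.DataFrame(out, index=genes["gene"])


def _betabinom(rng: np.random.Generator, n: np.ndarray, p: np.ndarray, rho: float) -> np.ndarray:
    """Beta-binomial draws; rho=0 degenerates to binomial.

    Parameterization alpha = p(1-rho)/rho, beta = (1-p)(1-rho)/rho.
    """
    n = np.asarray(n)
    p = np.broadcast_to(np.asarray(p, dtype=float), n.shape)
    if rho == 0.0:
        return rng.binomial(n, p)
    scale = (1.0 - rho) / rho
    pp = rng.beta(np.maximum(p * scale, 1e-12), np.maximum((1.0 - p) * scale, 1e-12))
    return rng.binomial(n, pp)


def _thin_across_snps(
    rng: np.random.Generator, totals: np.ndarray, n_snps: np.ndarray, max_snps: int
) -> np.ndarray:
    """Split per-gene totals uniformly across each gene's SNPs.

    Stick-breaking equivalent of an equal-probability multinomial, vectorized
    over genes.  Returns an array (n_genes, max_snps); entries beyond a
    gene's SNP count are zero.
    """
    out = np.zeros((totals.shape[0], max_snps), dtype=np.int64)
    remaining = totals.astype(np.int64).copy()
    for j in range(max_snps):
        live = n_snps > j
        k = n_snps[live] - j
        take = rng.binomial(remaining[live], 1.0 / k)
        out[live, j] = take
        remaining[live] -= take
    return out


def simulate_cohort(config: SimConfig) -> SimCohort:
    """Generate a full synthetic cohort under ``config``.

    Deterministic for a fixed config (including its seed).
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rngs = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ["design", "genome", "genetics", "counts", "errors"], ss.spawn(5)
        )
    }

    meta = _simulate_metadata(config, rngs["design"])
    genes, snps = _simulate_genome(config, rngs["genome"])
    truth, alt_carrier, hap = _simulate_genetics(config, meta, genes, snps, rngs["genetics"])
    gene_totals, snp_counts, reads, p_mat = _simulate_counts(
        config, meta, genes, snps, truth, alt_carrier, hap, rngs["counts"], rngs["errors"]
    )
    truth.expected_p = pd.DataFrame(p_mat, index=genes["gene"], columns=meta["sample"])
    return SimCohort(
        metadata=meta,
        snp_counts=snp_counts,
        gene_totals=gene_totals,
        truth=truth,
        read_assignments=reads,
    )


def _simulate_metadata(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    nf = config.n_families
    pops = [POPULATIONS[i % config.n_populations] for i in range(nf)]
    fams = [f"F{i + 1:03d}" for i in range(nf)]
    # balanced highland assignment within each population
    elev = np.empty(nf, dtype=object)
    for pop in sorted(set(pops)):
        idx = [i for i, p in enumerate(pops) if p == pop]
        n_high = int(round(config.frac_highland * len(idx)))
        chosen = rng.choice(idx, size=n_high, replace=False)
        for i in idx:
            elev[i] = "Highland" if i in set(chosen) else "Lowland"
    lat = np.array([rng.uniform(*_LAT_RANGES.get(p, (0.0, 1.0))) for p in pops])

    site_tissues = SITE_TISSUES[: config.n_tissues]
    n_met_blocks, n_pv = config.plants_per_family_per_site
    rows = []
    for i, fam in enumerate(fams):
        plant_ids = {}
        for b in range(n_met_blocks):
            plant_ids[("Met", b + 1)] = f"{fam}_Met_b{b + 1}"
        for b in range(n_pv):
            plant_ids[("Pv", b + 1)] = f"{fam}_Pv_b{b + 1}"
        for st in site_tissues:
            site = "Met" if st.startswith("Met") else "Pv"
            nb = n_met_blocks if site == "Met" else n_pv
            for b in range(nb):
                rows.append(
                    {
                        "sample": f"{fam}_{st}_b{b + 1}",
                        "family": fam,
                        "plant": plant_ids[(site, b + 1)],
                        "population": pops[i],
                        "elevation": elev[i],
                        "latitude": round(lat[i], 4),
                        "block": b + 1,
                        "site_tissue": st,
                    }
                )
    meta = pd.DataFrame(rows)
    # teams and field order assigned round-robin within each site:tissue
    meta["team"] = 0
    meta["field_order"] = 0
    for st, sub in meta.groupby("site_tissue"):
        order = rng.permutation(len(sub))
        meta.loc[sub.index, "field_order"] = order + 1
        meta.loc[sub.index, "team"] = (order % 3) + 1
    return meta.sort_values(["site_tissue", "block", "field_order"]).reset_index(drop=True)


def _simulate_genome(config: SimConfig, rng: np.random.Generator):
    ng = config.n_genes
    chrom = np.arange(ng) % config.n_chromosomes
    idx_on_chrom = np.arange(ng) // config.n_chromosomes
    gene_len, spacing = 3000, 10000
    start = idx_on_chrom * spacing + 1
    end = start + gene_len - 1
    genes_per_chrom = np.ceil(ng / config.n_chromosomes)
    chrom_len = genes_per_chrom * spacing + gene_len
    seg_len = chrom_len / config.segments_per_chromosome
    segment = np.minimum(
        (start / seg_len).astype(int), config.segments_per_chromosome - 1
    )
    n_snps = rng.poisson(config.snps_per_gene_mean, size=ng)
    genes = pd.DataFrame(
        {
            "gene": [f"gene{g + 1:05d}" for g in range(ng)],
            "chrom": [f"chr{c + 1}" for c in chrom],
            "chrom_i": chrom,
            "segment": segment,
            "start": start,
            "end": end,
            "n_snps": n_snps,
        }
    )
    snp_gene = np.repeat(np.arange(ng), n_snps)
    # distinct positions within each gene
    pos = np.concatenate(
        [
            start[g] + np.sort(rng.choice(gene_len, size=n_snps[g], replace=False))
            for g in range(ng)
            if n_snps[g] > 0
        ]
    ) if n_snps.sum() else np.array([], dtype=int)
    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, size=len(snp_gene))]
    alt = bases[(np.char.find("ACGT", ref.astype(str)) + rng.integers(1, 4, size=len(ref))) % 4]
    snps = pd.DataFrame(
        {
            "snp": np.arange(len(snp_gene)),
            "gene_i": snp_gene,
            "position": pos.astype(int),
            "refAllele": ref,
            "altAllele": alt,
        }
    )
    return genes, snps


def _simulate_genetics(config, meta, genes, snps, rng):
    ng, nf = config.n_genes, config.n_families
    fams = sorted(meta["family"].unique())
    fam_index = {f: i for i, f in enumerate(fams)}
    elev_by_fam = meta.drop_duplicates("family").set_index("family")["elevation"]

    dase_idx = rng.choice(ng, size=config.n_dase_genes, replace=False)
    delta_g = np.zeros(ng)
    delta_g[dase_idx] = config.delta

    highland = np.array([elev_by_fam[f] == "Highland" for f in fams])
    # per-haplotype baseline + elevation shift applied to highland families
    theta = rng.normal(0.0, config.tau, size=(ng, nf, 2))
    theta += delta_g[:, None, None] * highland[None, :, None]

    # each paternal haplotype carries ALT at a SNP independently
    alt_carrier = rng.random((len(snps), nf, 2)) < config.het_rate

    plants = meta.drop_duplicates("plant")[["plant", "family"]].reset_index(drop=True)
    hap_arr = rng.integers(
        0, 2, size=(len(plants), config.n_chromosomes, config.segments_per_chromosome)
    )
    hap_rows = []
    for pi, row in plants.iterrows():
        for c in range(config.n_chromosomes):
            for s in range(config.segments_per_chromosome):
                hap_rows.append(
                    {
                        "plant": row["plant"],
                        "chrom": f"chr{c + 1}",
                        "segment": s,
                        "haplotype": int(hap_arr[pi, c, s]),
                    }
                )
    genes_out = genes.copy()
    genes_out["delta"] = delta_g
    genes_out["is_dase"] = False
    genes_out.loc[dase_idx, "is_dase"] = True
    truth = SimTruth(
        genes=genes_out,
        theta=theta,
        haplotypes=pd.DataFrame(hap_rows),
        expected_p=pd.DataFrame(),
        config=config,
    )
    truth._fam_index = fam_index          # type: ignore[attr-defined]
    truth._hap_arr = hap_arr              # type: ignore[attr-defined]
    truth._plants = list(plants["plant"])  # type: ignore[attr-defined]
    return truth, alt_carrier, hap_arr


def _simulate_counts(config, meta, genes, snps, truth, alt_carrier, hap_arr, rng, rng_err):
    ng = config.n_genes
    n_samples = len(meta)
    fam_index = truth._fam_index
    plant_index = {p: i for i, p in enumerate(truth._plants)}

    rel = rng.lognormal(0.0, 1.0, size=ng)
    rel /= rel.sum()
    lib = np.round(config.library_size_mean * rng.lognormal(0.0, 0.2, size=n_samples)).astype(int)

    # trans effect: smooth field-order modulation of a subset of genes
    trans_genes = rng.random(ng) < config.trans_frac
    trans_slope = np.where(trans_genes, rng.normal(0.0, config.trans_sd, size=ng), 0.0)
    order_scaled = meta.groupby("site_tissue")["field_order"].transform(
        lambda s: (s - s.mean()) / max(s.std(ddof=0), 1.0)
    ).to_numpy()

    chrom_i = genes["chrom_i"].to_numpy()
    seg_i = genes["segment"].to_numpy()
    n_snps = genes["n_snps"].to_numpy()
    max_snps = int(n_snps.max()) if len(n_snps) else 0
    # probability a read overlaps at least one SNP of the gene
    read_frac = 0.1
    capture = 1.0 - (1.0 - read_frac) ** n_snps

    gene_totals = np.zeros((ng, n_samples), dtype=np.int64)
    p_mat = np.zeros((ng, n_samples))
    snp_frames = []
    read_frames = [] if config.emit_read_assignments else None

    snp_gene = snps["gene_i"].to_numpy()
    for si in range(n_samples):
        row = meta.iloc[si]
        fi = fam_index[row["family"]]
        pi = plant_index[row["plant"]]
        hap_g = hap_arr[pi, chrom_i, seg_i]            # inherited haplotype per gene
        theta_g = truth.theta[np.arange(ng), fi, hap_g]
        p = 2.0 ** theta_g / (1.0 + 2.0 ** theta_g)
        p_mat[:, si] = p

        # a cis effect on the landrace allele raises the gene's total too:
        # total expression scales with (tester + landrace)/2 = (1 + 2^theta)/2
        mu = lib[si] * rel * 2.0 ** (trans_slope * order_scaled[si]) \
            * (1.0 + 2.0 ** theta_g) / 2.0
        lam = rng.gamma(1.0 / config.nb_dispersion, mu * config.nb_dispersion)
        total = rng.poisson(lam)
        gene_totals[:, si] = total

        ase_total = rng.binomial(total, capture)
        land = _betabinom(rng, ase_total, p, config.bb_rho)
        b73 = ase_total - land

        land_snp = _thin_across_snps(rng, land, n_snps, max_snps)
        b73_snp = _thin_across_snps(rng, b73, n_snps, max_snps)
        # flatten to per-SNP vectors in snp order
        col = np.concatenate([np.arange(k) for k in n_snps]) if len(snps) else np.array([], int)
        land_v = land_snp[snp_gene, col]
        b73_v = b73_snp[snp_gene, col]

        het = alt_carrier[np.arange(len(snps)), fi, hap_g[snp_gene]]
        alt_true = np.where(het, land_v, 0)
        ref_true = b73_v + np.where(het, 0, land_v)
        e = config.seq_error_rate
        if e > 0:
            a2r = rng_err.binomial(alt_true, e)
            r2a = rng_err.binomial(ref_true, e)
            alt_obs = alt_true - a2r + r2a
            ref_obs = ref_true - r2a + a2r
        else:
            alt_obs, ref_obs = alt_true, ref_true

        covered = (alt_obs + ref_obs) > 0
        if covered.any():
            sub = snps.loc[covered]
            frame = pd.DataFrame(
                {
                    "sample": row["sample"],
                    "contig": genes["chrom"].to_numpy()[sub["gene_i"]],
                    "position": sub["position"].to_numpy(),
                    "variantID": [
                        f"{c}_{p}" for c, p in zip(
                            genes["chrom"].to_numpy()[sub["gene_i"]], sub["position"]
                        )
                    ],
                    "refAllele": sub["refAllele"].to_numpy(),
                    "altAllele": sub["altAllele"].to_numpy(),
                    "refCount": ref_obs[covered],
                    "altCount": alt_obs[covered],
                }
            )
            frame["totalCount"] = frame["refCount"] + frame["altCount"]
            snp_frames.append(frame)

        if read_frames is not None:
            gname = genes["gene"].to_numpy()
            recs = []
            for allele, counts in (("landrace", land_v * het), ("B73", b73_v)):
                nz = np.nonzero(counts)[0]
                for s_i in nz:
                    for _ in range(int(counts[s_i])):
                        recs.append(
                            (row["sample"], gname[snp_gene[s_i]], allele,
                             genes["chrom"].to_numpy()[snp_gene[s_i]],
                             int(snps["position"].iloc[s_i]))
                        )
            if recs:
                rf = pd.DataFrame(
                    recs, columns=["sample", "gene", "allele", "contig", "position"]
                )
                rf.insert(0, "read_id", [f"{row['sample']}_r{i}" for i in range(len(rf))])
                read_frames.append(rf)

    snp_counts = (
        pd.concat(snp_frames, ignore_index=True)
        if snp_frames
        else pd.DataFrame(
            columns=[
                "sample", "contig", "position", "variantID",
                "refAllele", "altAllele", "refCount", "altCount", "totalCount",
            ]
        )
    )
    totals_df = pd.DataFrame(gene_totals, index=genes["gene"], columns=meta["sample"])
    reads = (
        pd.concat(read_frames, ignore_index=True)
        if read_frames
        else (pd.DataFrame(columns=["read_id", "sample", "gene", "allele", "contig", "position"])
              if config.emit_read_assignments else None)
    )
    return totals_df, snp_counts, reads, p_mat


def write_fixture(cohort: SimCohort, directory: str) -> dict[str, str]:
    """Write the cohort as a plain-text fixture directory.

    Layout::

        metadata.tsv            sample metadata
        genes.gff3              gene + exon features (1-based inclusive)
        gene_totals.tsv         genes x samples count matrix
        snp_counts/<sample>.tsv ASEReadCounter-style per-sample tables
        reads.tsv               optional read assignments
        truth_genes.tsv         per-gene delta and DASE flag
        truth_haplotypes.tsv    per-plant inherited haplotype per segment
        truth_theta.tsv         long table of per-haplotype cis effects

    Returns a name -> path mapping.  Round-trips losslessly through the
    readers in :mod:`asepop.allelic_io`.
    """
    os.makedirs(directory, exist_ok=True)
    paths: dict[str, str] = {}

    p = os.path.join(directory, "metadata.tsv")
    cohort.metadata.to_csv(p, sep="\t", index=False)
    paths["metadata"] = p

    p = os.path.join(directory, "genes.gff3")
    with open(p, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in cohort.truth.genes.iterrows():
            attrs = f"ID={g['gene']}"
            fh.write(
                f"{g['chrom']}\tasepop\tgene\t{g['start']}\t{g['end']}\t.\t+\t.\t{attrs}\n"
            )
            fh.write(
                f"{g['chrom']}\tasepop\texon\t{g['start']}\t{g['end']}\t.\t+\t.\t"
                f"ID={g['gene']}.exon1;Parent={g['gene']}\n"
            )
    paths["annotation"] = p

    p = os.path.join(directory, "gene_totals.tsv")
    cohort.gene_totals.to_csv(p, sep="\t", index_label="gene")
    paths["gene_totals"] = p

    snp_dir = os.path.join(directory, "snp_counts")
    os.makedirs(snp_dir, exist_ok=True)
    cols = ["contig", "position", "variantID", "refAllele", "altAllele",
            "refCount", "altCount", "totalCount"]
    for sample in cohort.samples:
        sub = cohort.snp_counts[cohort.snp_counts["sample"] == sample]
        sp = os.path.join(snp_dir, f"{sample}.tsv")
        sub[cols].to_csv(sp, sep="\t", index=False)
    paths["snp_counts_dir"] = snp_dir

    if cohort.read_assignments is not None:
        p = os.path.join(directory, "reads.tsv")
        cohort.read_assignments.to_csv(p, sep="\t", index=False)
        paths["reads"] = p

    p = os.path.join(directory, "truth_genes.tsv")
    cohort.truth.genes.drop(columns=["chrom_i"]).to_csv(p, sep="\t", index=False)
    paths["truth_genes"] = p

    p = os.path.join(directory, "truth_haplotypes.tsv")
    cohort.truth.haplotypes.to_csv(p, sep="\t", index=False)
    paths["truth_haplotypes"] = p

    p = os.path.join(directory, "truth_theta.tsv")
    ng, nf, _ = cohort.truth.theta.shape
    fams = sorted(cohort.metadata["family"].unique())
    long = pd.DataFrame(
        {
            "gene": np.repeat(cohort.truth.genes["gene"].to_numpy(), nf * 2),
            "family": np.tile(np.repeat(fams, 2), ng),
            "haplotype": np.tile([0, 1], ng * nf),
            "theta": cohort.truth.theta.reshape(-1),
        }
    )
    long.to_csv(p, sep="\t", index=False)
    paths["truth_theta"] = p
    return paths
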