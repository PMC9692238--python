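"""Reading, filtering and aggregation of allelic count data.

The atomic observation is one sample's read counts for the reference (tester,
maternal) and alternate (landrace, paternal) allele at one exonic SNP, in the
tab-separated layout produced by GATK ASEReadCounter: ``contig, position,
variantID, refAllele, altAllele, refCount, altCount, totalCount`` with
1-based positions.

Three per-sample SNP filters guard the gene-level ASE ratio against known
biases before aggregation:

* both alleles detected — keeping SNPs where only the landrace allele was
  seen (while dismissing the apparently homozygous reference-only loci)
  would bias ratios toward the landrace allele;
* total coverage >= 10 reads — low-coverage sites suffer allele drop-out;
* |log2(ALT) - log2(REF)| < 2 — extreme ratios at high coverage are
  dominated by sequencing errors masquerading as rare non-reference alleles,
  which biases ratios toward the reference allele.

Counts of surviving SNPs are summed within genes (or reads counted once per
gene per allele when read-level assignments exist) and the per-gene,
per-sample ASE ratio is log2(landrace) - log2(tester), missing wherever
either allele has zero reads: a zero count carries no information about the
allelic ratio, unlike a ratio of zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

SNP_COLUMNS = [
    "contig", "position", "variantID", "refAllele", "altAllele",
    "refCount", "altCount", "totalCount",
]

#: population-by-elevation grouping used by the gene-level filters
GROUP_COLS = ["population", "elevation"]


class FormatError(ValueError):
    """Raised when an input file does not match the expected layout."""


# ---------------------------------------------------------------------------
# readers


def read_snp_counts(path: str, sample: Optional[str] = None) -> pd.DataFrame:
    """Read one ASEReadCounter-style TSV.

    Recomputes ``totalCount`` from the allele counts (with a warning) when
    the file's totals disagree; malformed rows are reported by line number.
    """
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    missing = [c for c in SNP_COLUMNS if c not in df.columns and c != "totalCount"]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    for col in ("refCount", "altCount"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            lines = [int(i) + 2 for i in bad[:10]]  # +2: header + 1-based
            raise FormatError(f"{path}: non-numeric {col} at line(s) {lines}")
        df[col] = df[col].astype(np.int64)
    if (df["refCount"] < 0).any() or (df["altCount"] < 0).any():
        bad = df.index[(df["refCount"] < 0) | (df["altCount"] < 0)]
        raise ValueError(f"{path}: negative counts at line(s) {[int(i)+2 for i in bad[:10]]}")
    recomputed = df["refCount"] + df["altCount"]
    if "totalCount" in df.columns:
        mismatch = df["totalCount"].astype(np.int64) != recomputed
        if mismatch.any():
            warnings.warn(
                f"{path}: totalCount != refCount+altCount in {int(mismatch.sum())} rows; "
                "totals recomputed from allele counts"
            )
    df["totalCount"] = recomputed
    if sample is not None:
        df.insert(0, "sample", sample)
    return df


def read_snp_counts_dir(directory: str) -> pd.DataFrame:
    """Read every ``<sample>.tsv`` in a directory into one long table."""
    import glob, os

    frames = []
    for path in sorted(glob.glob(os.path.join(directory, "*.tsv"))):
        sample = os.path.splitext(os.path.basename(path))[0]
        frames.append(read_snp_counts(path, sample=sample))
    if not frames:
        return pd.DataFrame(columns=["sample"] + SNP_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def read_metadata(path: str) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    if "sample" not in meta.columns:
        raise FormatError(f"{path}: metadata must contain a 'sample' column")
    if meta["sample"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids in metadata")
    return meta


def read_count_matrix(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def read_gff3_exons(path: str) -> pd.DataFrame:
    """Exon intervals per gene from a GFF3 file (1-based inclusive).

    Exon features are attributed to the gene named by their ``Parent`` (with
    trailing ``.exonN``/transcript suffixes stripped to the gene ID when the
    parent itself is the gene); gene features without exons contribute their
    full span.
    """
    rows = []
    genes_seen = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                continue
            contig, _src, ftype, start, end, _score, _strand, _frame, attrs = parts[:9]
            tags = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = tags.get("ID")
                if gid:
                    genes_seen[gid] = (contig, int(start), int(end))
            elif ftype == "exon":
                parent = tags.get("Parent") or tags.get("ID", "")
                gid = parent.split(",")[0]
                rows.append(
                    {"gene": gid, "contig": contig, "start": int(start), "end": int(end)}
                )
    exons = pd.DataFrame(rows, columns=["gene", "contig", "start", "end"])
    if exons.empty and genes_seen:
        exons = pd.DataFrame(
            [
                {"gene": g, "contig": c, "start": s, "end": e}
                for g, (c, s, e) in genes_seen.items()
            ]
        )
    return exons.sort_values(["contig", "start", "gene"]).reset_index(drop=True)


def read_bed_exons(path: str) -> pd.DataFrame:
    """Exon intervals from BED (0-based half-open, converted to 1-based inclusive)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
            gene = parts[3] if len(parts) > 3 else f"{contig}:{start}-{end}"
            rows.append({"gene": gene, "contig": contig, "start": start + 1, "end": end})
    return pd.DataFrame(rows, columns=["gene", "contig", "start", "end"])


# ---------------------------------------------------------------------------
# SNP -> gene assignment


def assign_snps_to_genes(snps: pd.DataFrame, exons: pd.DataFrame) -> pd.DataFrame:
    """Attach a ``gene`` column; drop SNPs in no exon or in exons of >1 gene.

    Intervals are 1-based inclusive on both ends.  The returned frame gains
    attribute-style metadata via ``.attrs``: ``n_unassigned`` and
    ``n_ambiguous`` tallies.
    """
    if exons.empty:
        raise ValueError("annotation contains zero exons")
    out = snps.copy()
    keys = out[["contig", "position"]].drop_duplicates().reset_index(drop=True)
    hit_genes: list[set] = [set() for _ in range(len(keys))]
    for contig, sub in keys.groupby("contig"):
        pos = sub["position"].to_numpy()
        order = np.argsort(pos)
        sorted_pos = pos[order]
        idx = sub.index.to_numpy()[order]
        ex = exons[exons["contig"] == contig]
        for _, e in ex.iterrows():
            lo = np.searchsorted(sorted_pos, e["start"], side="left")
            hi = np.searchsorted(sorted_pos, e["end"], side="right")
            for k in idx[lo:hi]:
                hit_genes[k].add(e["gene"])
    keys["gene"] = [sorted(g)[0] if len(g) == 1 else None for g in hit_genes]
    keys["n_hits"] = [len(g) for g in hit_genes]
    out = out.merge(keys, on=["contig", "position"], how="left")
    n_ambiguous = int((out["n_hits"] > 1).sum())
    n_unassigned = int((out["n_hits"] == 0).sum())
    out = out[out["n_hits"] == 1].drop(columns=["n_hits"]).reset_index(drop=True)
    out.attrs["n_ambiguous"] = n_ambiguous
    out.attrs["n_unassigned"] = n_unassigned
    return out


# ---------------------------------------------------------------------------
# SNP filters


@dataclass
class SnpFilterReport:
    """Per-filter drop tallies: exclusive (fails only that filter) and
    cumulative (dropped at that step when filters apply in order)."""

    n_input: int
    exclusive: dict = field(default_factory=dict)
    cumulative: dict = field(default_factory=dict)
    n_kept: int = 0

    def to_frame(self) -> pd.DataFrame:
        names = list(self.exclusive)
        return pd.DataFrame(
            {
                "filter": names,
                "exclusive_drops": [self.exclusive[n] for n in names],
                "cumulative_drops": [self.cumulative[n] for n in names],
            }
        )


def filter_ase_snps(
    snps: pd.DataFrame,
    min_total: int = 10,
    log2_cap: float = 2.0,
) -> tuple[pd.DataFrame, SnpFilterReport]:
    """Apply the three per-sample SNP filters.

    Keep a SNP (row) iff both alleles have >= 1 read, total coverage is at
    least ``min_total``, and |log2(alt) - log2(ref)| < ``log2_cap``.  Never
    raises: rows failing any test are dropped and tallied.
    """
    ref = snps["refCount"].to_numpy(dtype=float)
    alt = snps["altCount"].to_numpy(dtype=float)
    both = (ref >= 1) & (alt >= 1)
    total_ok = (ref + alt) >= min_total
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.abs(np.log2(alt) - np.log2(ref))
    ratio_ok = both & (ratio < log2_cap)

    keep = both & total_ok & ratio_ok
    report = SnpFilterReport(n_input=len(snps))
    fails = {
        "both_alleles": ~both,
        "min_total": ~total_ok,
        "log2_ratio": both & ~ratio_ok,
    }
    n_fail_total = (~keep)
    for name, f in fails.items():
        others = [o for o in fails.values() if o is not f]
        only = f & ~np.logical_or.reduce(others)
        report.exclusive[name] = int(only.sum())
    dropped = np.zeros(len(snps), dtype=bool)
    for name, f in fails.items():
        new = f & ~dropped
        report.cumulative[name] = int(new.sum())
        dropped |= f
    report.n_kept = int(keep.sum())
    return snps[keep].reset_index(drop=True), report


# ---------------------------------------------------------------------------
# gene-level aggregation


@dataclass
class GeneAllelicMatrix:
    """Paired gene x sample allelic count matrices and derived log2ASE."""

    landrace: pd.DataFrame   # paternal-allele read counts
    b73: pd.DataFrame        # maternal/tester-allele read counts
    log2ase: pd.DataFrame    # log2(landrace) - log2(b73); NaN where either is 0
    total: pd.DataFrame      # ASE-informative reads (landrace + b73)

    def subset_genes(self, genes: Iterable[str]) -> "GeneAllelicMatrix":
        idx = [g for g in genes if g in self.landrace.index]
        return GeneAllelicMatrix(
            self.landrace.loc[idx], self.b73.loc[idx],
            self.log2ase.loc[idx], self.total.loc[idx],
        )

    def subset_samples(self, samples: Iterable[str]) -> "GeneAllelicMatrix":
        cols = [s for s in samples if s in self.landrace.columns]
        return GeneAllelicMatrix(
            self.landrace[cols], self.b73[cols],
            self.log2ase[cols], self.total[cols],
        )


def _log2ase(landrace: pd.DataFrame, b73: pd.DataFrame) -> pd.DataFrame:
    with np.errstate(divide="ignore", invalid="ignore"):
        la = np.log2(landrace.to_numpy(dtype=float))
        lb = np.log2(b73.to_numpy(dtype=float))
        out = la - lb
    out[(landrace.to_numpy() == 0) | (b73.to_numpy() == 0)] = np.nan
    return pd.DataFrame(out, index=landrace.index, columns=landrace.columns)


def aggregate_gene_allelic_counts(
    table: pd.DataFrame,
    mode: str = "snp_sum",
    maternal_allele: str = "ref",
) -> GeneAllelicMatrix:
    """Aggregate filtered SNP counts (or read assignments) to gene level.

    ``mode="snp_sum"`` sums SNP-level allele counts within each gene; reads
    spanning several SNPs of a gene are counted once per SNP, so this mode
    can double-count such reads.  ``mode="read_assignment"`` expects a table
    with columns ``read_id, sample, gene, allele`` and counts each read once
    per gene per allele, which is exact.

    ``maternal_allele`` names which column carries the tester (maternal)
    allele in SNP tables; the default ``"ref"`` reflects a design where the
    maternal parent is the reference genome.
    """
    if mode == "snp_sum":
        if "gene" not in table.columns:
            raise ValueError("SNP table must carry a 'gene' column (run assign_snps_to_genes)")
        if maternal_allele == "ref":
            mat_col, pat_col = "refCount", "altCount"
        elif maternal_allele == "alt":
            mat_col, pat_col = "altCount", "refCount"
        else:
            raise ValueError(f"unknown maternal_allele {maternal_allele!r}")
        g = table.groupby(["gene", "sample"])[[pat_col, mat_col]].sum()
        landrace = g[pat_col].unstack(fill_value=0).sort_index(axis=0).sort_index(axis=1)
        b73 = g[mat_col].unstack(fill_value=0).reindex_like(landrace).fillna(0).astype(int)
    elif mode == "read_assignment":
        required = {"read_id", "sample", "gene", "allele"}
        if not required.issubset(table.columns):
            raise ValueError(f"read table must have columns {sorted(required)}")
        dedup = table.drop_duplicates(["read_id", "sample", "gene"])
        counts = (
            dedup.groupby(["gene", "sample", "allele"]).size().unstack("allele", fill_value=0)
        )
        for col in ("landrace", "B73"):
            if col not in counts.columns:
                counts[col] = 0
        landrace = counts["landrace"].unstack(fill_value=0).sort_index(axis=0).sort_index(axis=1)
        b73 = counts["B73"].unstack(fill_value=0).reindex_like(landrace).fillna(0).astype(int)
    else:
        raise ValueError(f"unknown aggregation mode {mode!r}")
    landrace = landrace.astype(int)
    b73 = b73.astype(int)
    return GeneAllelicMatrix(
        landrace=landrace,
        b73=b73,
        log2ase=_log2ase(landrace, b73),
        total=landrace + b73,
    )


# ---------------------------------------------------------------------------
# gene-level inclusion filters


def _group_qualifying_counts(
    values: pd.DataFrame, metadata: pd.DataFrame, min_reads: int
) -> pd.DataFrame:
    meta = metadata.set_index("sample").loc[values.columns]
    groups = meta[GROUP_COLS].astype(str).agg(":".join, axis=1)
    if groups.nunique() == 0:
        raise ValueError("no population-by-elevation groups found in metadata")
    qual = values >= min_reads
    out = {}
    for gname, cols in groups.groupby(groups).groups.items():
        if len(cols) == 0:
            raise ValueError(f"group {gname} has zero samples")
        out[gname] = qual[list(cols)].sum(axis=1)
    return pd.DataFrame(out)


def filter_genes_for_ase(
    matrix: GeneAllelicMatrix,
    metadata: pd.DataFrame,
    min_samples: int = 10,
    min_reads: int = 32,
) -> GeneAllelicMatrix:
    """Keep genes with >= ``min_samples`` samples of >= ``min_reads``
    ASE-informative reads in *each* population-by-elevation group.

    The all-group rule is stricter than the expression filter because a gene
    must be measurable in every group for its group contrast to be estimable.
    """
    per_group = _group_qualifying_counts(matrix.total, metadata, min_reads)
    if per_group.shape[1] == 0:
        raise ValueError("metadata defines no population-by-elevation groups")
    keep = (per_group >= min_samples).all(axis=1)
    return matrix.subset_genes(per_group.index[keep])


def filter_genes_for_expression(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    min_samples: int = 10,
    min_reads: int = 32,
) -> pd.DataFrame:
    """Keep genes with >= ``min_samples`` samples of >= ``min_reads`` reads
    in *at least one* population-by-elevation group (any-group rule)."""
    per_group = _group_qualifying_counts(counts, metadata, min_reads)
    keep = (per_group >= min_samples).any(axis=1)
    return counts.loc[per_group.index[keep]]


# ---------------------------------------------------------------------------
# TMM normalization


def _tmm_pair_factor(
    obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
    logratio_trim: float = 0.3, sum_trim: float = 0.05, a_cutoff: float = -1e10,
) -> float:
    pos = (obs > 0) & (ref > 0)
    obs, ref = obs[pos].astype(float), ref[pos].astype(float)
    if obs.size == 0:
        return 1.0
    m = np.log2((obs / lib_obs) / (ref / lib_ref))
    a = 0.5 * np.log2((obs / lib_obs) * (ref / lib_ref))
    w = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    fin = np.isfinite(m) & np.isfinite(a) & (a > a_cutoff)
    m, a, w = m[fin], a[fin], w[fin]
    n = m.size
    if n == 0:
        return 1.0
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    lo_m = int(np.floor(n * logratio_trim)) + 1
    hi_m = n + 1 - lo_m
    lo_a = int(np.floor(n * sum_trim)) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.nansum(m[keep] / w[keep]) / np.nansum(1.0 / w[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_normalization_factors(counts: pd.DataFrame) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors (geometric mean 1).

    Weighted TMM with a 30% two-sided trim on M-values and a 5% two-sided
    trim on A-values; the reference is the sample whose upper-quartile
    count fraction is closest to the mean across samples.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM requires at least 2 samples")
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    zero = lib == 0
    if zero.any():
        bad = list(counts.columns[zero])
        raise ValueError(f"sample(s) with all-zero counts: {bad}")
    f75 = np.array([np.quantile(x[:, i], 0.75) / lib[i] for i in range(x.shape[1])])
    ref_i = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [
            _tmm_pair_factor(x[:, i], x[:, ref_i], lib[i], lib[ref_i])
            for i in range(x.shape[1])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="norm.factor")


# ---------------------------------------------------------------------------
# validation utility


def ase_overdispersion_check(
    matrix: GeneAllelicMatrix,
    n_mc: int = 200,
    seed: int = 0,
    min_obs: int = 5,
) -> pd.DataFrame:
    """Compare observed among-sample variance of log2ASE per gene with a
    counting-only Monte-Carlo null.

    The null resamples each observation binomially at its observed total and
    the gene's pooled landrace fraction, so any excess of the observed
    variance over the null reflects biological or technical variation beyond
    read-counting noise.
    """
    rng = np.random.default_rng(seed)
    rows = []
    land = matrix.landrace.to_numpy(dtype=float)
    tot = matrix.total.to_numpy(dtype=float)
    for gi, gene in enumerate(matrix.landrace.index):
        mask = tot[gi] > 0
        if mask.sum() < min_obs:
            continue
        n = tot[gi, mask]
        p_hat = land[gi, mask].sum() / n.sum()
        obs = matrix.log2ase.to_numpy()[gi, mask]
        obs = obs[np.isfinite(obs)]
        if obs.size < min_obs:
            continue
        obs_var = float(np.var(obs, ddof=1))
        sims = rng.binomial(n.astype(int), p_hat, size=(n_mc, n.size))
        with np.errstate(divide="ignore", invalid="ignore"):
            sim_ratio = np.log2(sims) - np.log2(n - sims)
        sim_ratio[(sims == 0) | (sims == n)] = np.nan
        null_var = np.nanvar(sim_ratio, axis=1, ddof=1)
        rows.append(
            {
                "gene": gene,
                "observed_var": obs_var,
                "null_var": float(np.nanmean(null_var)),
            }
        )
    out = pd.DataFrame(rows, columns=["gene", "observed_var", "null_var"])
    out["excess"] = out["observed_var"] - out["null_var"]
    return out
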