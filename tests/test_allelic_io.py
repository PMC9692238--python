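"""SNP readers, bias filters, gene aggregation, inclusion filters, TMM."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from asepop import allelic_io
from asepop.allelic_io import (
    FormatError,
    aggregate_gene_allelic_counts,
    assign_snps_to_genes,
    filter_ase_snps,
    filter_genes_for_ase,
    filter_genes_for_expression,
    read_snp_counts,
    tmm_normalization_factors,
)


# ---------------------------------------------------------------------------
# readers


def test_read_snp_counts_well_formed(tmp_path, snp_frame):
    p = tmp_path / "s1.tsv"
    snp_frame.drop(columns="sample").head(3).to_csv(p, sep="\t", index=False)
    out = read_snp_counts(str(p), sample="s1")
    assert len(out) == 3
    assert list(out["sample"].unique()) == ["s1"]


def test_read_snp_counts_header_only(tmp_path):
    p = tmp_path / "empty.tsv"
    p.write_text("\t".join(allelic_io.SNP_COLUMNS) + "\n")
    out = read_snp_counts(str(p))
    assert out.empty


def test_read_snp_counts_missing_column(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text("contig\tposition\n1\t2\n")
    with pytest.raises(FormatError, match="missing required columns"):
        read_snp_counts(str(p))


def test_read_snp_counts_total_mismatch_recomputed(tmp_path, snp_frame):
    df = snp_frame.drop(columns="sample").copy()
    df.loc[0, "totalCount"] = 999  # inconsistent with 5 + 5
    p = tmp_path / "s1.tsv"
    df.to_csv(p, sep="\t", index=False)
    with pytest.warns(UserWarning, match="totals recomputed"):
        out = read_snp_counts(str(p))
    assert out.loc[0, "totalCount"] == 10


def test_read_snp_counts_negative_counts(tmp_path, snp_frame):
    df = snp_frame.drop(columns="sample").copy()
    df.loc[1, "refCount"] = -3
    p = tmp_path / "s1.tsv"
    df.to_csv(p, sep="\t", index=False)
    with pytest.raises(ValueError, match="negative counts"):
        read_snp_counts(str(p))


# ---------------------------------------------------------------------------
# SNP -> gene assignment (1-based inclusive intervals)


def _exons(*rows):
    return pd.DataFrame(rows, columns=["gene", "contig", "start", "end"])


def _snps(*positions, contig="chr1"):
    return pd.DataFrame(
        {
            "sample": "s1",
            "contig": contig,
            "position": positions,
            "refCount": 5,
            "altCount": 5,
        }
    )


@pytest.mark.parametrize("pos,assigned", [(100, True), (150, True), (50, True),
                                          (151, False), (49, False)])
def test_assign_inclusive_boundaries(pos, assigned):
    exons = _exons(("g1", "chr1", 50, 150))
    out = assign_snps_to_genes(_snps(pos), exons)
    assert (len(out) == 1) == assigned
    if assigned:
        assert out.loc[0, "gene"] == "g1"


def test_assign_ambiguous_overlap_dropped():
    exons = _exons(("g1", "chr1", 50, 150), ("g2", "chr1", 100, 200))
    out = assign_snps_to_genes(_snps(120, 160), exons)
    # 120 is in both genes -> dropped; 160 only in g2
    assert list(out["gene"]) == ["g2"]
    assert out.attrs["n_ambiguous"] == 1


def test_assign_zero_exons_is_error():
    with pytest.raises(ValueError, match="zero exons"):
        assign_snps_to_genes(_snps(100), _exons())


# ---------------------------------------------------------------------------
# per-sample SNP filters


def test_filter_boundary_table(snp_frame):
    kept, report = filter_ase_snps(snp_frame)
    assert list(kept["refCount"]) == [5, 4]
    assert list(kept["altCount"]) == [5, 6]
    assert report.n_input == 6
    assert report.n_kept == 2


def test_filter_monoallelic_dropped():
    df = _snps(1)
    df["refCount"], df["altCount"] = [0], [50]
    kept, _ = filter_ase_snps(df)
    assert kept.empty


def test_filter_ratio_boundary_exactly_two_dropped():
    """|log2(8) - log2(2)| == 2 exactly: not < 2, so dropped."""
    df = _snps(1)
    df["refCount"], df["altCount"] = [2], [8]
    kept, _ = filter_ase_snps(df)
    assert kept.empty


def test_filter_report_tallies_consistent(small_cohort):
    kept, report = filter_ase_snps(small_cohort.snp_counts)
    assert sum(report.cumulative.values()) == report.n_input - report.n_kept
    assert all(v >= 0 for v in report.exclusive.values())
    # exclusive drops never exceed cumulative attribution for a leading filter
    assert report.exclusive["both_alleles"] <= report.cumulative["both_alleles"]


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(st.integers(0, 200), st.integers(0, 200)),
        min_size=1,
        max_size=30,
    )
)
def test_filter_idempotent_and_shrinking(pairs):
    df = pd.DataFrame(
        {
            "sample": "s",
            "contig": "c",
            "position": np.arange(len(pairs)) + 1,
            "refCount": [r for r, _ in pairs],
            "altCount": [a for _, a in pairs],
        }
    )
    once, _ = filter_ase_snps(df)
    twice, _ = filter_ase_snps(once)
    assert len(once) <= len(df)
    pd.testing.assert_frame_equal(once, twice)


# ---------------------------------------------------------------------------
# aggregation


def _assigned_snps(rows):
    return pd.DataFrame(
        rows, columns=["sample", "gene", "refCount", "altCount"]
    )


def test_snp_sum_arithmetic():
    df = _assigned_snps([("s1", "g1", 4, 8), ("s1", "g1", 6, 2)])
    m = aggregate_gene_allelic_counts(df, mode="snp_sum")
    assert m.landrace.loc["g1", "s1"] == 10
    assert m.b73.loc["g1", "s1"] == 10
    assert m.log2ase.loc["g1", "s1"] == 0.0


def test_zero_allele_is_missing():
    df = _assigned_snps([("s1", "g1", 12, 0)])
    m = aggregate_gene_allelic_counts(df, mode="snp_sum")
    assert np.isnan(m.log2ase.loc["g1", "s1"])
    assert m.total.loc["g1", "s1"] == 12


def test_read_assignment_counts_each_read_once():
    """A read spanning 2 SNPs of one gene counts once in read_assignment
    mode but twice when SNP counts are summed."""
    reads = pd.DataFrame(
        {
            "read_id": ["r1", "r1", "r2"],
            "sample": "s1",
            "gene": "g1",
            "allele": ["landrace", "landrace", "B73"],
        }
    )
    m_read = aggregate_gene_allelic_counts(reads, mode="read_assignment")
    assert m_read.landrace.loc["g1", "s1"] == 1
    assert m_read.b73.loc["g1", "s1"] == 1
    # the same evidence seen as SNP-level counts: r1 contributes at 2 SNPs
    snp = _assigned_snps([("s1", "g1", 1, 1), ("s1", "g1", 0, 1)])
    m_snp = aggregate_gene_allelic_counts(snp, mode="snp_sum")
    assert m_snp.landrace.loc["g1", "s1"] == 2


def test_unknown_mode_rejected():
    with pytest.raises(ValueError, match="unknown aggregation mode"):
        aggregate_gene_allelic_counts(_assigned_snps([("s1", "g1", 1, 1)]), mode="nope")


def test_allele_label_swap_negates_log2ase():
    df = _assigned_snps(
        [("s1", "g1", 4, 8), ("s2", "g1", 3, 9), ("s1", "g2", 7, 7)]
    )
    m = aggregate_gene_allelic_counts(df, mode="snp_sum", maternal_allele="ref")
    m_swap = aggregate_gene_allelic_counts(df, mode="snp_sum", maternal_allele="alt")
    a, b = m.log2ase.to_numpy(), m_swap.log2ase.to_numpy()
    mask = np.isfinite(a)
    np.testing.assert_allclose(a[mask], -b[mask], atol=1e-12)


def test_null_cohort_log2ase_median_near_zero(small_cohort):
    """Per-sample log2ASE distributions center near zero in a null-ish
    simulation (theta small), mirroring the absence of reference bias."""
    kept, _ = filter_ase_snps(small_cohort.snp_counts)
    exons = small_cohort.truth.genes.rename(columns={"chrom": "contig"})[
        ["gene", "contig", "start", "end"]
    ]
    assigned = assign_snps_to_genes(kept, exons)
    m = aggregate_gene_allelic_counts(assigned, mode="snp_sum")
    dase = set(small_cohort.truth.genes.loc[small_cohort.truth.genes["is_dase"], "gene"])
    null_genes = [g for g in m.log2ase.index if g not in dase]
    med = m.log2ase.loc[null_genes].median(axis=0, skipna=True)
    assert np.nanmedian(np.abs(med)) < 0.25


# ---------------------------------------------------------------------------
# gene-level inclusion filters


def _meta4(n_per_group=12):
    rows = []
    i = 0
    for pop in ("Mexico", "SouthAmerica"):
        for elev in ("Highland", "Lowland"):
            for _ in range(n_per_group):
                rows.append({"sample": f"s{i}", "population": pop, "elevation": elev})
                i += 1
    return pd.DataFrame(rows)


def _matrix_from_totals(total):
    land = (total // 2).astype(int)
    b73 = total - land
    return allelic_io.GeneAllelicMatrix(
        landrace=land, b73=b73, log2ase=allelic_io._log2ase(land, b73),
        total=land + b73,
    )


def test_ase_filter_boundary_keep_and_drop():
    meta = _meta4(12)
    # gene keep: exactly 10 samples with >= 32 reads in each group
    tot_keep = pd.DataFrame(
        [np.tile([32] * 10 + [0, 0], 4)], index=["gkeep"], columns=meta["sample"]
    )
    # gene drop: 9 qualifying in the first group
    row = np.tile([32] * 10 + [0, 0], 4).astype(float)
    row[9] = 0
    tot_drop = pd.DataFrame([row], index=["gdrop"], columns=meta["sample"])
    total = pd.concat([tot_keep, tot_drop]).astype(int)
    m = _matrix_from_totals(total)
    out = filter_genes_for_ase(m, meta, min_samples=10, min_reads=32)
    assert list(out.landrace.index) == ["gkeep"]


def test_expression_filter_any_group_rule():
    meta = _meta4(12)
    row = np.zeros(48)
    row[:10] = 32  # qualifies in exactly one group
    counts = pd.DataFrame([row, np.zeros(48)], index=["gone", "gnone"],
                          columns=meta["sample"]).astype(int)
    out = filter_genes_for_expression(counts, meta, min_samples=10, min_reads=32)
    assert list(out.index) == ["gone"]


def test_filters_against_brute_force_tally(small_cohort):
    kept, _ = filter_ase_snps(small_cohort.snp_counts)
    exons = small_cohort.truth.genes.rename(columns={"chrom": "contig"})[
        ["gene", "contig", "start", "end"]
    ]
    m = aggregate_gene_allelic_counts(
        assign_snps_to_genes(kept, exons), mode="snp_sum"
    )
    meta = small_cohort.metadata
    meta_sub = meta[meta["sample"].isin(m.total.columns)]
    out = filter_genes_for_ase(m, meta_sub, min_samples=3, min_reads=16)
    # independent brute-force oracle
    groups = meta_sub.groupby(["population", "elevation"])["sample"].apply(list)
    expected = []
    for gene in m.total.index:
        ok = True
        for _, samples in groups.items():
            cols = [s for s in samples if s in m.total.columns]
            n_qual = int((m.total.loc[gene, cols] >= 16).sum())
            if n_qual < 3:
                ok = False
                break
        if ok:
            expected.append(gene)
    assert list(out.landrace.index) == expected


def test_expression_keepset_superset_of_ase_keepset(small_cohort):
    kept, _ = filter_ase_snps(small_cohort.snp_counts)
    exons = small_cohort.truth.genes.rename(columns={"chrom": "contig"})[
        ["gene", "contig", "start", "end"]
    ]
    m = aggregate_gene_allelic_counts(
        assign_snps_to_genes(kept, exons), mode="snp_sum"
    )
    meta = small_cohort.metadata
    meta_sub = meta[meta["sample"].isin(m.total.columns)]
    ase_keep = set(
        filter_genes_for_ase(m, meta_sub, min_samples=3, min_reads=16).landrace.index
    )
    expr_keep = set(
        filter_genes_for_expression(
            m.total, meta_sub, min_samples=3, min_reads=16
        ).index
    )
    assert expr_keep >= ase_keep


# ---------------------------------------------------------------------------
# TMM


def test_tmm_identical_samples_unit_factors(rng):
    a = rng.poisson(50, size=200)
    counts = pd.DataFrame({"s1": a, "s2": a})
    f = tmm_normalization_factors(counts)
    np.testing.assert_allclose(f.to_numpy(), [1.0, 1.0])


def test_tmm_doubled_library_unit_factors(rng):
    a = rng.poisson(50, size=500) + 1
    counts = pd.DataFrame({"s1": a, "s2": 2 * a})
    f = tmm_normalization_factors(counts)
    np.testing.assert_allclose(f.to_numpy(), [1.0, 1.0], atol=1e-8)


def test_tmm_geometric_mean_one(small_cohort):
    counts = small_cohort.gene_totals
    f = tmm_normalization_factors(counts)
    assert abs(np.log(f.to_numpy()).sum()) < 1e-10
    assert (f > 0).all()


def test_tmm_all_zero_sample_errors():
    counts = pd.DataFrame({"s1": [1, 2, 3], "s2": [0, 0, 0]})
    with pytest.raises(ValueError, match="s2"):
        tmm_normalization_factors(counts)


# ---------------------------------------------------------------------------
# overdispersion utility


def test_overdispersion_check_detects_extra_variance():
    """With bb_rho > 0 the observed among-sample log2ASE variance exceeds
    the binomial counting-only null for most genes."""
    import dataclasses
    from asepop.simdata import SimConfig, simulate_cohort

    cfg = SimConfig(
        n_families=20, n_genes=60, n_dase_genes=0, delta=0.0, tau=0.0,
        bb_rho=0.08, library_size_mean=200_000, seq_error_rate=0.0, seed=21,
    )
    cohort = simulate_cohort(cfg)
    kept, _ = filter_ase_snps(cohort.snp_counts)
    exons = cohort.truth.genes.rename(columns={"chrom": "contig"})[
        ["gene", "contig", "start", "end"]
    ]
    m = aggregate_gene_allelic_counts(assign_snps_to_genes(kept, exons), mode="snp_sum")
    res = allelic_io.ase_overdispersion_check(m, n_mc=100, seed=3)
    assert len(res) > 20
    assert (res["excess"] > 0).mean() > 0.8
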