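"""Classify identical-by-descent regions between two sibling F1 plants.

Siblings share the tester genome but each inherits one of the father's two
haplotypes per chromosome segment.  Where they inherited the same
haplotype, their heterozygous-SNP patterns coincide; elsewhere roughly
half the het sites are private.  Binning each chromosome into 20
equal-SNP blocks and fitting a two-component Gaussian mixture to the
shared-het fraction separates the two cases.
"""

from asepop.allelic_io import filter_ase_snps
from asepop.ibd import classify_ibd_pair
from asepop.simdata import SimConfig, simulate_cohort

cohort = simulate_cohort(SimConfig(
    n_families=4, n_genes=400, n_dase_genes=0, delta=0.0, tau=0.5,
    library_size_mean=800_000, snps_per_gene_mean=6.0,
    n_chromosomes=2, segments_per_chromosome=5, seq_error_rate=0.0, seed=3,
))
kept, _ = filter_ase_snps(cohort.snp_counts)
panel = cohort.snp_counts[["contig", "position"]].drop_duplicates()

fam = cohort.metadata.groupby("family").get_group("F001")
reps = fam.sort_values("site_tissue").drop_duplicates("plant")
a, b = list(reps.itertuples())[:2]
print(f"family F001: comparing {a.plant} vs {b.plant}")

bins = classify_ibd_pair(
    kept[kept["sample"] == a.sample],
    kept[kept["sample"] == b.sample],
    panel, n_bins=20,
)
print(bins.head(8).to_string(index=False))
print("\nbin classes:")
print(bins["class"].value_counts().to_string())
print("\nshared-het fraction by class (bimodal: ~0.5 not-IBD, ~1 IBD):")
print(bins.groupby("class")["f"].mean().round(3).to_string())
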