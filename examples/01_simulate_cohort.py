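"""Simulate a small F1 cohort and look at what it contains.

Every landrace parent is crossed to the same inbred tester, so each F1
plant carries one tester and one landrace allele at every locus.  The
simulator emits sample metadata, ASEReadCounter-style SNP count tables,
a gene x sample total-count matrix, and the ground truth (per-haplotype
cis effects, DASE genes, inherited haplotypes) that downstream examples
check their answers against.
"""

from asepop.simdata import SimConfig, simulate_cohort

cfg = SimConfig(
    n_families=12,          # F1 families (landrace fathers)
    n_genes=300,
    n_dase_genes=30,        # genes with a true highland-lowland cis shift
    delta=1.0,              # size of that shift, log2 units
    tau=0.3,                # SD of baseline per-haplotype cis effects
    bb_rho=0.01,            # allelic overdispersion beyond binomial
    library_size_mean=500_000,
    seed=1,
)
cohort = simulate_cohort(cfg)

print("samples:", len(cohort.metadata))
print(cohort.metadata.head(4).to_string(index=False))
print("\nSNP count rows:", len(cohort.snp_counts))
print(cohort.snp_counts.head(4).to_string(index=False))
print("\ngene totals shape:", cohort.gene_totals.shape)
truth = cohort.truth.genes
print("true DASE genes:", int(truth["is_dase"].sum()),
      "| mean delta among them:", truth.loc[truth["is_dase"], "delta"].mean())
# Each sample belongs to one of three site:tissues; Metepec has two field
# blocks (two sibling plants per family), Puerto Vallarta one.
print("\nsamples per site:tissue:")
print(cohort.metadata["site_tissue"].value_counts().to_string())
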