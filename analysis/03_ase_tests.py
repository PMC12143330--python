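"""SNV- and gene-level ASE testing on the simulated cohort.

Runs the two-tailed beta-binomial test per sample with BH FDR, aggregates
phased counts to gene haplotype totals, tests genes, and summarizes: how many
SNVs/genes show ASE, the monoallelic/biallelic/balanced split, and the
fraction of ASE gene-samples with at least a 2-fold allele difference.
"""

from pathlib import Path

from hapase.io import read_tpm, write_table
from hapase.pipeline import PipelineConfig, load_cohort
from hapase.ase import (
    aggregate_gene_haplotypes,
    filter_informative,
    gene_ase_test,
    snv_ase_test,
    tissue_dependence,
)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cfg = PipelineConfig()
    records = load_cohort(
        ROOT / "cohort" / "counts",
        ROOT / "cohort" / "phased.vcf",
        ROOT / "cohort" / "genes.bed",
    )
    filtered, _ = filter_informative(records, cfg.test)
    snv = snv_ase_test(filtered, cfg.test)
    gene_counts, _ = aggregate_gene_haplotypes(filtered)
    gene = gene_ase_test(gene_counts, cfg.test)
    kw = tissue_dependence(filtered)

    write_table(snv, ROOT / "snv_ase.tsv")
    write_table(gene, ROOT / "gene_ase.tsv")
    write_table(kw, ROOT / "tissue_dependence.tsv")

    n_ase_snv = snv.loc[snv["is_ase"], "snv_id"].nunique()
    n_ase_gene = gene.loc[gene["is_ase"], "gene_id"].nunique()
    mono = gene[gene["is_ase"] & (gene["expression_class"] == "monoallelic")]
    print(f"SNVs with ASE in >= 1 sample : {n_ase_snv:,} of {snv['snv_id'].nunique():,}")
    print(f"genes with ASE in >= 1 sample: {n_ase_gene:,} of {gene['gene_id'].nunique():,}")
    print(f"monoallelic ASE gene-samples : {len(mono):,}")
    print(
        "tissue-dependent read counts : "
        f"{(kw['p_value'] < 0.05).mean():.1%} of genes at p < 0.05"
    )


if __name__ == "__main__":
    main()
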