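metric	value
n_samples	6.0
n_informative_records	98.0
n_subthreshold_dropped	4.0
n_snvs_tested	17.0
n_ase_snvs	12.0
n_genes_assayed	5.0
n_ase_genes	3.0
reference_bias_median	0.2
frac_ase_gene_samples_fold_ge2	1.0
n_gene_samples_balanced	9.0
n_gene_samples_biallelic	12.0
n_gene_samples_monoallelic	6.0
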