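gene_id	class	effect	switch_tissue	n_snvs
g1	balanced	0.5		3
g2	biallelic_ase	0.8		4
g3	monoallelic_imprinted	1.0		4
g4	tissue_switching	0.83	kidney	4
g5	balanced	0.5		2
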