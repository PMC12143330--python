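gene_id	animal	a_on_hap1	expressed_founder	n_het_snvs
g1	A1	True		3
g1	A2	False		3
g2	A1	True		4
g2	A2	False		4
g3	A1	True	A	4
g3	A2	False	A	4
g4	A1	True		4
g4	A2	False		4
g5	A1	True		2
g5	A2	False		2
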