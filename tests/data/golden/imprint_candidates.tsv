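gene_id	tier	n_ase_snvs	n_animals	n_ase_samples	known_imprinted	per_animal_hap
g3	all-sample-consistent	4	2	6	False	A1=2;A2=2
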