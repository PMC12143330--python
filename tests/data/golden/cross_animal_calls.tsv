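gene_id	tissue	n_hap1_major	n_hap2_major	switching
g2	kidney	0	2	False
g2	liver	0	2	False
g2	spleen	0	2	False
g3	kidney	0	2	False
g3	liver	0	2	False
g3	spleen	0	2	False
g4	kidney	2	0	False
g4	liver	0	2	False
g4	spleen	0	2	False
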