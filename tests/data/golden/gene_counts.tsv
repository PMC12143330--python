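animal	tissue	gene_id	x	y	n_snvs	single_block
A1	kidney	g1	58	122	3	True
A1	kidney	g2	146	184	4	True
A1	kidney	g3	148	148	4	True
A1	kidney	g4	34	196	4	True
A1	kidney	g5	14	29	1	True
A1	liver	g1	58	122	3	True
A1	liver	g2	146	184	4	True
A1	liver	g3	148	148	4	True
A1	liver	g4	162	196	4	True
A1	liver	g5	14	29	1	True
A1	spleen	g1	58	122	3	True
A1	spleen	g2	146	184	4	True
A1	spleen	g3	148	148	4	True
A1	spleen	g4	162	196	4	True
A1	spleen	g5	14	29	1	True
A2	kidney	g1	64	122	3	True
A2	kidney	g2	38	184	4	True
A2	kidney	g3	0	148	4	True
A2	kidney	g4	162	196	4	True
A2	liver	g1	64	122	3	True
A2	liver	g2	38	184	4	True
A2	liver	g3	0	148	4	True
A2	liver	g4	34	196	4	True
A2	spleen	g1	64	122	3	True
A2	spleen	g2	38	184	4	True
A2	spleen	g3	0	148	4	True
A2	spleen	g4	34	196	4	True
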