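animal	tissue	gene_id	x	y	n_snvs	single_block	p_value	q_value	is_ase	hap1_ratio	major_hap	expression_class
A1	kidney	g1	58	122	3	True	0.6693554770912786	0.8366943463640982	False	0.47540983606557374	2	biallelic
A1	kidney	g2	146	184	4	True	5.486664446544535e-14	9.144440744240892e-14	True	0.7934782608695652	1	biallelic
A1	kidney	g3	148	148	4	True	7.596642027213313e-41	3.798321013606656e-40	True	1.0	1	monoallelic
A1	kidney	g4	34	196	4	True	3.3125626696151466e-18	8.281406674037866e-18	True	0.17346938775510204	2	biallelic
A1	kidney	g5	14	29	1	True	0.9999999999999771	0.9999999999999771	False	0.4827586206896552	2	biallelic
A1	liver	g1	58	122	3	True	0.6693554770912786	0.8366943463640982	False	0.47540983606557374	2	biallelic
A1	liver	g2	146	184	4	True	5.486664446544535e-14	9.144440744240892e-14	True	0.7934782608695652	1	biallelic
A1	liver	g3	148	148	4	True	7.596642027213313e-41	3.798321013606656e-40	True	1.0	1	monoallelic
A1	liver	g4	162	196	4	True	3.3125626696151466e-18	8.281406674037866e-18	True	0.826530612244898	1	biallelic
A1	liver	g5	14	29	1	True	0.9999999999999771	0.9999999999999771	False	0.4827586206896552	2	biallelic
A1	spleen	g1	58	122	3	True	0.6693554770912786	0.8366943463640982	False	0.47540983606557374	2	biallelic
A1	spleen	g2	146	184	4	True	5.486664446544535e-14	9.144440744240892e-14	True	0.7934782608695652	1	biallelic
A1	spleen	g3	148	148	4	True	7.596642027213313e-41	3.798321013606656e-40	True	1.0	1	monoallelic
A1	spleen	g4	162	196	4	True	3.3125626696151466e-18	8.281406674037866e-18	True	0.826530612244898	1	biallelic
A1	spleen	g5	14	29	1	True	0.9999999999999771	0.9999999999999771	False	0.4827586206896552	2	biallelic
A2	kidney	g1	64	122	3	True	0.6693554770912683	0.6693554770912683	False	0.5245901639344263	1	biallelic
A2	kidney	g2	38	184	4	True	5.486664446544535e-14	7.315552595392713e-14	True	0.20652173913043478	2	biallelic
A2	kidney	g3	0	148	4	True	7.596642027213313e-41	3.038656810885325e-40	True	0.0	2	monoallelic
A2	kidney	g4	162	196	4	True	3.3125626696151466e-18	6.625125339230293e-18	True	0.826530612244898	1	biallelic
A2	liver	g1	64	122	3	True	0.6693554770912683	0.6693554770912683	False	0.5245901639344263	1	biallelic
A2	liver	g2	38	184	4	True	5.486664446544535e-14	7.315552595392713e-14	True	0.20652173913043478	2	biallelic
A2	liver	g3	0	148	4	True	7.596642027213313e-41	3.038656810885325e-40	True	0.0	2	monoallelic
A2	liver	g4	34	196	4	True	3.3125626696151466e-18	6.625125339230293e-18	True	0.17346938775510204	2	biallelic
A2	spleen	g1	64	122	3	True	0.6693554770912683	0.6693554770912683	False	0.5245901639344263	1	biallelic
A2	spleen	g2	38	184	4	True	5.486664446544535e-14	7.315552595392713e-14	True	0.20652173913043478	2	biallelic
A2	spleen	g3	0	148	4	True	7.596642027213313e-41	3.038656810885325e-40	True	0.0	2	monoallelic
A2	spleen	g4	34	196	4	True	3.3125626696151466e-18	6.625125339230293e-18	True	0.17346938775510204	2	biallelic
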