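gene_id	A1:kidney	A1:liver	A1:spleen	A2:kidney	A2:liver	A2:spleen
g1	50.0	50.0	50.0	50.0	50.0	50.0
g2	200.0	200.0	200.0	200.0	200.0	200.0
g3	5.0	5.0	5.0	5.0	5.0	5.0
g4	30.0	30.0	30.0	30.0	30.0	30.0
g5	1200.0	1200.0	1200.0	1200.0	1200.0	1200.0
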