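chr1	10000	15000	g1
chr1	20000	25000	g2
chr1	30000	35000	g3
chr1	40000	45000	g4
chr1	50000	55000	g5
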