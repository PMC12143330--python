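contig	position	refAllele	altAllele	refCount	altCount	totalCount
chr1	10001	A	G	21	19	40
chr1	10401	A	G	22	20	42
chr1	10801	A	G	21	19	40
chr1	20001	A	G	9	36	45
chr1	20301	A	G	10	37	47
chr1	20601	A	G	9	36	45
chr1	20901	A	G	10	37	47
chr1	30001	A	G	0	37	37
chr1	30501	A	G	0	37	37
chr1	31001	A	G	0	37	37
chr1	31501	A	G	0	37	37
chr1	40001	A	G	40	8	48
chr1	40201	A	G	41	9	50
chr1	40401	A	G	40	8	48
chr1	40601	A	G	41	9	50
chr1	50001	A	G	4	3	7
chr1	50701	A	G	16	15	31
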