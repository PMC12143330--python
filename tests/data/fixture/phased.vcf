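##fileformat=VCFv4.2
##contig=<ID=chr1,length=60701>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	A1	A2
chr1	10001	chr1:10001	A	G	.	PASS	.	GT:PS	1|0:10	0|1:10
chr1	10401	chr1:10401	A	G	.	PASS	.	GT:PS	1|0:10	0|1:10
chr1	10801	chr1:10801	A	G	.	PASS	.	GT:PS	1|0:10	0|1:10
chr1	20001	chr1:20001	A	G	.	PASS	.	GT:PS	1|0:20	0|1:20
chr1	20301	chr1:20301	A	G	.	PASS	.	GT:PS	1|0:20	0|1:20
chr1	20601	chr1:20601	A	G	.	PASS	.	GT:PS	1|0:20	0|1:20
chr1	20901	chr1:20901	A	G	.	PASS	.	GT:PS	1|0:20	0|1:20
chr1	30001	chr1:30001	A	G	.	PASS	.	GT:PS	1|0:30	0|1:30
chr1	30501	chr1:30501	A	G	.	PASS	.	GT:PS	1|0:30	0|1:30
chr1	31001	chr1:31001	A	G	.	PASS	.	GT:PS	1|0:30	0|1:30
chr1	31501	chr1:31501	A	G	.	PASS	.	GT:PS	1|0:30	0|1:30
chr1	40001	chr1:40001	A	G	.	PASS	.	GT:PS	1|0:40	0|1:40
chr1	40201	chr1:40201	A	G	.	PASS	.	GT:PS	1|0:40	0|1:40
chr1	40401	chr1:40401	A	G	.	PASS	.	GT:PS	1|0:40	0|1:40
chr1	40601	chr1:40601	A	G	.	PASS	.	GT:PS	1|0:40	0|1:40
chr1	50001	chr1:50001	A	G	.	PASS	.	GT:PS	1|0:50	0|1:50
chr1	50701	chr1:50701	A	G	.	PASS	.	GT:PS	0/0:.	0/0:.
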