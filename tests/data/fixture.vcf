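##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##contig=<ID=chr1,length=301>
##contig=<ID=chr2,length=51>
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	sA	sB	sC
chr1	100	.	A	G	60	.	.	GT:GQ	0/0:20	0/1:4	1/1:30
chr1	250	.	C	T	55	.	.	GT:GQ	./.:.	0/0:9	0/1:5
chr1	300	.	G	A	45	.	.	GT:GQ	1/1:30	0/1:30	0/0:2
chr2	50	.	T	C	90	.	.	GT:GQ	0/1:8	1/1:7	0/0:50
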