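sample	status	country	group_rank1	group_rank2
sA	traditional	ESP	trad	trad_g1
sB	modern	NLD	modern	modern
sC	wild	PER	wild	wild
sD	SLC	MEX	semidom	semidom
sE	hybrid	FRA	hybrid	hybrid
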