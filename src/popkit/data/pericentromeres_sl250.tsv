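chrom	start	end
chr1	5488553	74024603
chr2	0	30493730
chr3	16493431	50407653
chr4	7406888	50551374
chr5	9881466	58473554
chr6	3861081	33077717
chr7	4056987	58629226
chr8	4670213	54625578
chr9	6225214	63773642
chr10	3775719	55840828
chr11	10947270	48379978
chr12	5879033	61255621
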