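#chrom	start	end	size	genes
chrX	52098738	52231295	132557	XAGE2, XAGE2B
chrX	52267361	52395914	128553	XAGE2, XAGE2B
chrY	3016123	3134221	118098
chrY	3179117	3359419	180302
chrY	4114366	4346934	232568
chrY	4466077	4593373	127296
chrY	4593411	4807708	214297
chrY	4834281	4935713	101432	PCDH11Y
chrY	4935714	5205540	269826	PCDH11Y
chrY	5274434	5421065	146631	PCDH11Y
chrY	6577215	6677618	100403
chrY	8214827	8334874	120047
chrY	9524503	9640365	115862	TTTY8, TTTY8B, TTTY7B, TTTY7, TTTY21, TTTY21B, TTTY2B, TTTY2, TTTY1, TTTY1B, TTTY22
chrY	15039955	15234829	194874
chrY	17559652	17661377	101725
chrY	18248698	18381734	133036
chrY	18390543	18560004	169461
chrY	19375294	19500106	124812
chrY	20228333	20599266	370933	XKRY, XKRY2, LINC00230A, LINC00230B, FAM41AY1, FAM41AY2
chrY	23247004	23361665	114661
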