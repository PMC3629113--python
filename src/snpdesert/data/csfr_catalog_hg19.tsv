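#chrom	start	end	size	genes	label
chr1	145883118	145989503	106385	GPR89C, PDZK1P1	isochore_border
chr2	110524226	110704031	179805	RGPD5, RGPD6, LIMS3, LIMS3-LOC440895, LIMS3 L	isochore
chr2	111191098	111347035	155937	LIMS3-LOC440895, LIMS3, LIMS3L, RGPD6, RGPD5	isochore_border
chr7	74765724	74866460	100736	GATSL2	isochore
chr9	39379250	39551456	172206	LOC653501, ZNF658B	unknown
chr9	39829606	39961804	132198	FAM75A2, FAM75A1, FAM74A1	unknown
chr9	41497718	41635419	137701	FAM75A5, FAM75A7, LOC653501, ZNF658B	unknown
chr9	42027732	42145811	118079		isochore_border
chr9	42743905	42847394	103489	LOC286297	isochore_border
chr9	44466205	44651655	185450		isochore_border
chr9	45128500	45250203	121703		isochore_border
chr9	65632583	65745692	113109		isochore_border
chr10	46799214	46907775	108561	FAM35B	isochore
chr10	48185336	48300420	115084	LOC642826, AGAP9, FAM25B, FAM25G, FAM25C, ANXA8, ANXA8 L1	isochore_border
chr16	33142890	33293778	150888	TP53TG3, TP53TG3C, TP53TG3B	isochore_border
chrX	52098738	52395914	297176	XAGE2, XAGE2B, XAGE1B, XAGE1A, XAGE1D, XAGE1C, XAGE1E	unknown
chrX	52445914	52568230	122316	XAGE1A, XAGE1C, XAGE1E, XAGE1D, XAGE1B	isochore_border
chrY	3016123	3134221	118098		isochore
chrY	3179117	3359419	180302		isochore_border
chrY	3833777	3966707	132930		unknown
chrY	3966708	4346934	380226		unknown
chrY	4466077	4593373	127296		unknown
chrY	4593411	4807708	214297		unknown
chrY	4834281	4935713	101432	PCDH11Y	isochore_border
chrY	5012892	5205540	192648	PCDH11Y	unknown
chrY	5274434	5421065	146631	PCDH11Y	isochore_border
chrY	6074690	6422524	347834	TTTY23, TTTY23B, TSPY2, TTTY1B, TTTY1, TTTY2B, TTTY2, TTTY21, TTTY21B, TTTY7B, TTTY7, TTTY8B, TTTY8	isochore
chrY	6482140	6677618	195478		isochore_border
chrY	7401836	7548914	147078		unknown
chrY	8214827	8334874	120047		isochore_border
chrY	9381846	9492957	111111	RBMY3AP	isochore
chrY	9524503	9768115	243612	TTTY8, TTTY8B, TTTY7B, TTTY7, TTTY21, TTTY21B, TTTY2B, TTTY2, TTTY1, TTTY1B, TTTY22, TTTY23, TTTY23B	isochore
chrY	14691127	14804076	112949	TTTY15	isochore_border
chrY	15039955	15234829	194874		unknown
chrY	18248698	18381734	133036		unknown
chrY	18390543	18560004	169461		isochore_border
chrY	19375294	19500106	124812		unknown
chrY	19563894	20143885	579991	FAM41AY1, FAM41AY2, LINC00230B, LINC00230A, XKRY, XKRY2, CDY2B, CDY2A	unknown
chrY	20193885	20834702	640817	XKRY, XKRY2, LINC00230A, LINC00230B, FAM41AY1, FAM41AY2, HSFY2, HSFY1, TTTY9B, TTTY9A	unknown
chrY	20837553	21080706	243153	TTTY9B, TTTY9A, HSFY2, HSFY1, NCRNA00185	unknown
chrY	22214221	22369679	155458		isochore_border
chrY	22419679	22564743	145064		isochore_border
chrY	22564778	22665261	100483	TTTY10	unknown
chrY	23241568	23361665	120097		isochore_border
chrY	23473201	23580342	107141	RBMY2EP	isochore_border
chrY	23634362	23838234	203872	RBMY1B, RBMY1A1, RBMY1E, RBMY1D, TTTY13	isochore_border
chrY	23993156	24359930	366774	RBMY1A1, RBMY1D, RBMY1B, RBMY1E, PRY, PRY2, TTTY6, TTTY6B, RBMY1F, RBMY1J	isochore_border
chrY	24500602	24620459	119857	RBMY1F, RBMY1J, TTTY6B, TTTY6	unknown
chrY	24620459	28160890	3540431	PRY, PRY2, TTTY17B, TTTY17C, TTTY17A, TTTY4C, TTTY4B, TTTY4, BPY2B, BPY2, BPY2C, DAZ1, DAZ4, DAZ3, DAZ2, TTTY3B, TTTY3, CDY1, CDY1B, CSPG4P1Y, GOLGA2P2Y, GOLGA2P3Y	isochore_border
chrY	28160891	28509481	348590		isochore_border
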