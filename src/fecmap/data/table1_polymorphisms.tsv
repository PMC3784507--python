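# Polymorphisms within the minimal FecL locus and staged allele sharing, as published.
# ref_pos: OAR11 v3.1 1-based bp ('.' = not available on OARv3.1); locus_pos: 1-based bp on the
# sequenced FecL locus. sharing is cumulative k/n: wild (+) chromosomes carrying the L allele over
# wild chromosomes tested. border=1: interval-border SNP, excluded from the minimal locus.
# associated=1: allele segregating with the mutation (k=0 after all panels).
# The delins end coordinate 13529 is printed as-is in the source table (visibly truncated).
id	ref_pos	locus_pos	ptype	wild_allele	mutant_allele	motif	wild_repeats	mutant_repeats	label	sharing	border	associated
g.36910171T>C	36910171	1	SNP	T	C	.	.	.	SNP T>C	0/93	1	0
g.36910432T>C	36910432	262	SNP	T	C	.	.	.	SNP T>C	1/5	0	0
g.36910438C>T	36910438	268	SNP	C	T	.	.	.	SNP C>T	1/5	0	0
g.36910484G>A	36910484	314	SNP	G	A	.	.	.	SNP G>A	1/5	0	0
g.36910629C>T	36910629	459	SNP	C	T	.	.	.	SNP C>T	1/43	0	0
g.36911198C>T	36911198	1038	SNP	C	T	.	.	.	SNP C>T	5/23	0	0
g.36912873C>T	36912873	2713	SNP	C	T	.	.	.	SNP C>T	3/19	0	0
locus:2778_2779delTT	36912938	2778	INDEL	TT	.	.	.	.	2778_2779del TT	11/19	0	0
g.36913274T>A	36913274	3114	SNP	T	A	.	.	.	SNP T>A	4/19	0	0
g.36913693T>C	36913693	3533	SNP	T	C	.	.	.	SNP T>C	4/167	0	0
g.36913712A>G	36913712	3551	SNP	A	G	.	.	.	SNP A>G	4/167	0	0
g.36913851A>G	36913851	3690	SNP	A	G	.	.	.	SNP A>G	4/125	0	0
g.36914601G>A	36914601	4440	SNP	G	A	.	.	.	SNP G>A	1/71	0	0
g.36914685T>G	36914685	4523	SNP	T	G	.	.	.	SNP T>G	7/71	0	0
g.36914775C>T	36914775	4613	SNP	C	T	.	.	.	SNP C>T	6/75	0	0
g.36914951G>A	36914951	4789	SNP	G	A	.	.	.	SNP G>A	1/19	0	0
g.36915281A>G	36915281	5118	SNP	A	G	.	.	.	SNP A>G	4/19	0	0
g.36934758T>C	36934758	24609	SNP	T	C	.	.	.	SNP T>C	17/19	0	0
g.36938224T>A	36938224	28075	SNP	T	A	.	.	.	SNP T>A	0/602	0	1
g.36954793T>G	36954793	43665	SNP	T	G	.	.	.	SNP T>G	1/40	0	0
locus:58415MsGT	36970424	58415	MICROSAT	.	.	GT	13	?	Ms GT(13_?)	11/13	0	0
g.36973492G>A	36973492	61488	SNP	G	A	.	.	.	SNP G>A	9/15	0	0
g.36973984T>C	36973984	61978	SNP	T	C	.	.	.	SNP T>C	9/13	0	0
g.36974191T>A	36974191	62185	SNP	T	A	.	.	.	SNP T>A	7/13	0	0
g.36974440C>T	36974440	62434	SNP	C	T	.	.	.	SNP C>T	25/30	0	0
g.36978101A>G	36978101	66090	SNP	A	G	.	.	.	SNP A>G	10/13	0	0
g.36978780T>C	36978780	66769	SNP	T	C	.	.	.	SNP T>C	10/13	0	0
g.36979857C>T	36979857	67846	SNP	C	T	.	.	.	SNP C>T	6/13	0	0
g.36980000G>T	36980000	67989	SNP	G	T	.	.	.	SNP G>T	6/13	0	0
g.36980361T>C	36980361	68350	SNP	T	C	.	.	.	SNP T>C	3/9	0	0
g.36980408A>G	36980408	68397	SNP	A	G	.	.	.	SNP A>G	5/9	0	0
g.36980459A>C	36980459	68448	SNP	A	C	.	.	.	SNP A>C	6/13	0	0
g.36980802G>A	36980802	68790	SNP	G	A	.	.	.	SNP G>A	6/13	0	0
g.36983172T>G	36983172	71223	SNP	T	G	.	.	.	SNP T>G	6/13	0	0
g.36983502G>A	36983502	71553	SNP	G	A	.	.	.	SNP G>A	6/13	0	0
g.36983554G>C	36983554	71605	SNP	G	C	.	.	.	SNP G>C	8/13	0	0
g.36983772T>C	36983772	71823	SNP	T	C	.	.	.	SNP T>C	8/13	0	0
g.36983838A>G	36983838	71889	SNP	A	G	.	.	.	SNP A>G	8/13	0	0
locus:90747MsACC	37002721	90747	MICROSAT	.	.	ACC	10	?	Ms ACC(10_?) AAC(11_?)	11/13	0	0
locus:97825MsTG	37009592	97825	MICROSAT	.	.	TG	19	20	Ms TG(19_20)	60/80	0	0
g.37013699G>A	37013699	102307	SNP	G	A	.	.	.	SNP G>A	1/19	0	0
g.37022949T>C	37022949	111585	SNP	T	C	.	.	.	SNP T>C	16/19	0	0
g.37034573A>G	37034573	123335	SNP	A	G	.	.	.	SNP A>G	0/602	0	1
locus:135142G>A	.	135142	SNP	G	A	.	.	.	SNP G>A	19/24	0	0
locus:135152delins	.	135152	INDEL	.	TGTACGAGT	.	.	.	135152_13529 delinsTGTACGAGT	10/22	0	0
g.37064535G>T	37064535	151388	SNP	G	T	.	.	.	SNP G>T	17/19	0	0
g.37065546T>C	37065546	152517	SNP	T	C	.	.	.	SNP T>C	9/13	0	0
locus:182887MsAC	37095901	182887	MICROSAT	.	.	AC	12	?	Ms AC(12_?)	3/13	0	0
g.37107627G>C	37107627	194639	SNP	G	C	.	.	.	SNP G>C	1/19	1	0
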