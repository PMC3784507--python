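# DBA-lectin-purified proteins present only in L/L follicular fluid, as published:
# protein name, HUGO symbol, UniProt accession, theoretical molecular weight (kDa).
protein	gene_symbol	accession	mw_kda
Hemicentin-1	HMCN1	Q96RW7	613
Prolow-density lipoprotein receptor-related protein 1	LRP1	Q07954	505
Versican	VCAN	P81282	370
Coagulation factor V	F5	Q28107	249
Inter-alpha-trypsin inhibitor heavy chain H1	ITIH1	Q0VCM5	101
Heparan-sulfate 6-O-sulfotransferase 2	H6ST2	Q96MM7	69
Clusterin	CLU	P17697	51
Inhibin, beta A	INHBA	P07995	48
Glia-derived nexin	SERPINE2	P07093	44
Inhibin, alpha	INHA	P07994	39
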