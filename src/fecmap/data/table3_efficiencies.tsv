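# qPCR primer pairs and amplification efficiencies E (per-cycle amplification factor,
# from the dilution-series slope via E = exp(-1/slope)).
gene	forward_primer	reverse_primer	efficiency
B4GALNT2	AAGATTGAGGTGCTGGTGGATG	TTAACGACGCCGCTGGTC	2.01
IGF2BP1	CAAGAAGGGGCAGCACATTAAAC	TGGAGTTTCAGGAGGAGCAATC	1.98
RPL19	AATGCCAATGCCAACTC	CCCTTTCGCTACCTATACC	1.95
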