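locus	chromosome	mean_noncoding_length_bp	treelength_my	inversion_count	printed_rate
CLTCL1	15	360	8890	5	1.58
CLTC	19	1310	9280	19	1.56
PCBD1	6	800	9150	5	0.68
HMGN2	23	1340	5400	4	0.55
EEF2	28	1210	9230	6	0.54
IRF2	4	600	9090	2	0.37
GH1	27	1030	9090	3	0.32
ALDOB	Z	1450	8850	4	0.31
TPM1	10	450	8090	1	0.28
FGB	4	2070	9360	4	0.21
TGFB2	3	560	9360	1	0.19
CRYAA	1	930	8740	0	0
EGR1	13	490	8970	0	0
MB	1	680	9190	0	0
MUSK	Z	510	8810	0	0
MYC	2	620	9240	0	0
RHO	12	1190	8990	0	0
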