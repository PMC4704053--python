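locus	ml_treatment	ml_control	reported_log2_ratio
MIR394	0.45	0.21	2.14
MIR812c	0.19	0.04	2.25
MIR812o	0.15	0.05	3.00
MIR812q	0.37	0.17	1.12
MIR812r	0.37	0.17	1.12
MIR1437a	0.76	0.35	2.17
MIR1437b	0.76	0.35	2.17
MIR1862d	0.47	0.18	1.38
MIR1862e	0.56	0.21	1.42
MIR2101	0.27	0.09	1.58
MIR2921	0.18	0.01	4.17
MIR5179	0.36	0.15	1.26
MIR5490	0.43	0.21	1.03
MIR5810	0.87	0.29	3.00
MIR5817	0.24	0.10	1.26
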